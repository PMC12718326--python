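"""Codon-level helpers shared by the simulators and the screen readout.

Translation uses the bacterial/archaeal code (NCBI table 11) throughout;
stop codons are TAA, TAG and TGA. Residue indices are 1-based, matching the
field convention for naming substitutions (e.g. V23E = residue 23).
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[11]

#: codon -> single-letter amino acid; '*' marks a stop
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))

DNA = "ACGT"
_DNA_SET = frozenset(DNA)


def translate_codon(codon: str) -> str:
    """Translate one codon; returns '*' for a stop."""
    return CODON_TO_AA[codon]


def translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def check_dna(seq: str, *, name: str = "sequence") -> str:
    """Uppercase and validate an A/C/G/T-only sequence."""
    seq = seq.upper()
    bad = set(seq) - _DNA_SET
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    return seq


def classify_substitution(ref_codon: str, mut_codon: str) -> str:
    """Classify a codon change as synonymous / missense / nonsense."""
    ref_aa = CODON_TO_AA[ref_codon]
    mut_aa = CODON_TO_AA[mut_codon]
    if mut_aa == ref_aa:
        return "synonymous"
    if mut_aa == "*":
        return "nonsense"
    return "missense"
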