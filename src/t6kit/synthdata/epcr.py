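"""Error-prone-PCR mutant library simulation and selection.

Emulates a screen in which a multi-gene coding locus (the RnfDGEA-style
cassette) is mutagenized at an average of three nucleotide substitutions per
clone, passaged on Rnf-selective media to remove non-functional complexes,
and then passed through two rounds of toxin (Bte2) antagonism alongside a
no-toxin control arm.

Per-clone substitution counts are Poisson(lambda); positions are uniform
over the locus (unique within a clone) and the alternate base is uniform
over the three non-reference bases. Amino acid changes are derived by codon
translation (table 11); a nonsense change anywhere renders the clone
non-functional. Clone-level indels are not simulated by default — the screen
analyses amino acid substitutions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._codon import (
    CODON_TO_AA,
    DNA,
    SENSE_CODONS,
    check_dna,
    classify_substitution,
)

ProteinMap = list[tuple[str, int, int]]  # (protein_id, cds_start, cds_end)


class LibraryExtinctError(RuntimeError):
    """Raised when a selection round leaves zero surviving abundance."""


@dataclass(frozen=True)
class MutagenesisParams:
    reference_cds: str
    lambda_mut: float = 3.0     # mean substitutions per clone (screen design)
    n_clones: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_cds",
                           check_dna(self.reference_cds, name="reference_cds"))
        if len(self.reference_cds) % 3:
            raise ValueError("reference_cds length must be divisible by 3")
        if self.lambda_mut < 0:
            raise ValueError("lambda_mut must be >= 0")
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")


@dataclass(frozen=True)
class AaChange:
    protein_id: str
    residue_index: int          # 1-based within the protein
    ref_aa: str
    alt_aa: str
    consequence: str            # synonymous | missense | nonsense


@dataclass
class MutantClone:
    clone_id: str
    substitutions: list[tuple[int, str, str]]   # (nt_position, ref, alt)
    aa_changes: list[AaChange]
    abundance: float = 0.0
    rnf_functional: bool = True
    bte2_resistant: bool = False


@dataclass
class SelectionRules:
    """Survival model for the dual selection.

    inactivating_residues: missense at any of these (protein, residue) pairs
        abolishes Rnf function (nonsense anywhere always does).
    resistance_alleles: (protein, residue, alt_aa) triples conferring toxin
        resistance, modelling rare surface substitutions such as RnfG V23E.
    s_sensitive / s_resistant: per-round survival under toxin antagonism.
    rnf_selection_kill: survival of non-functional clones on selective media.
    """

    inactivating_residues: set[tuple[str, int]] = field(default_factory=set)
    resistance_alleles: set[tuple[str, int, str]] = field(default_factory=set)
    s_sensitive: float = 0.01
    s_resistant: float = 1.0
    rnf_selection_kill: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s_sensitive", "s_resistant", "rnf_selection_kill"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


def make_toy_locus(protein_lengths: dict[str, int] | None = None,
                   seed: int = 0) -> tuple[str, ProteinMap]:
    """Generate a random multi-gene CDS locus tiled by in-frame proteins.

    ``protein_lengths`` maps protein_id -> residue count; defaults to a
    four-protein RnfDGEA-style cassette. Codons are uniform over the 61
    sense codons, so the reference is free of internal stops.
    """
    if protein_lengths is None:
        protein_lengths = {"rnfD": 110, "rnfG": 70, "rnfE": 75, "rnfA": 65}
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    protein_map: ProteinMap = []
    pos = 0
    for pid, n_res in protein_lengths.items():
        codons = rng.integers(0, len(SENSE_CODONS), size=n_res)
        cds = "".join(SENSE_CODONS[i] for i in codons)
        protein_map.append((pid, pos, pos + 3 * n_res))
        parts.append(cds)
        pos += 3 * n_res
    return "".join(parts), protein_map


def _check_protein_map(reference: str, protein_map: ProteinMap) -> None:
    pos = 0
    for pid, start, end in protein_map:
        if start != pos or end <= start or (end - start) % 3:
            raise ValueError(f"protein map does not tile the locus in frame at {pid}")
        pos = end
    if pos != len(reference):
        raise ValueError("protein map does not cover the full locus")


def _protein_at(protein_map: ProteinMap, nt_pos: int) -> tuple[str, int, int]:
    """(protein_id, cds_start, residue_index 1-based) for a locus position."""
    for pid, start, end in protein_map:
        if start <= nt_pos < end:
            return pid, start, (nt_pos - start) // 3 + 1
    raise ValueError(f"position {nt_pos} outside the protein map")


def classify_variant(reference: str, protein_map: ProteinMap,
                     nt_pos: int, alt_base: str) -> AaChange:
    """Consequence of a single substitution in reference codon context."""
    pid, start, residue = _protein_at(protein_map, nt_pos)
    codon_start = start + 3 * ((nt_pos - start) // 3)
    ref_codon = reference[codon_start:codon_start + 3]
    offset = nt_pos - codon_start
    mut_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
    return AaChange(pid, residue, CODON_TO_AA[ref_codon], CODON_TO_AA[mut_codon],
                    classify_substitution(ref_codon, mut_codon))


def _aa_changes(reference: str, protein_map: ProteinMap,
                substitutions: list[tuple[int, str, str]]) -> list[AaChange]:
    """Codon-aware amino acid changes: substitutions sharing a codon are
    applied jointly before translation."""
    by_codon: dict[int, list[tuple[int, str]]] = defaultdict(list)
    for pos, _ref, alt in substitutions:
        pid, start, _ = _protein_at(protein_map, pos)
        codon_start = start + 3 * ((pos - start) // 3)
        by_codon[codon_start].append((pos - codon_start, alt))
    changes = []
    for codon_start in sorted(by_codon):
        ref_codon = reference[codon_start:codon_start + 3]
        mut = list(ref_codon)
        for offset, alt in by_codon[codon_start]:
            mut[offset] = alt
        mut_codon = "".join(mut)
        pid, start, _ = _protein_at(protein_map, codon_start)
        residue = (codon_start - start) // 3 + 1
        changes.append(AaChange(pid, residue, CODON_TO_AA[ref_codon],
                                CODON_TO_AA[mut_codon],
                                classify_substitution(ref_codon, mut_codon)))
    return changes


def assign_phenotype(clone: MutantClone, rules: SelectionRules) -> None:
    """Set rnf_functional / bte2_resistant from the clone's aa changes."""
    functional = True
    resistant = False
    for ch in clone.aa_changes:
        if ch.consequence == "nonsense":
            functional = False
        elif ch.consequence == "missense":
            if (ch.protein_id, ch.residue_index) in rules.inactivating_residues:
                functional = False
            if (ch.protein_id, ch.residue_index, ch.alt_aa) in rules.resistance_alleles:
                resistant = True
    clone.rnf_functional = functional
    clone.bte2_resistant = resistant


@dataclass
class EpTruth:
    """Ground truth for a simulated error-prone-PCR library."""

    reference: str
    protein_map: ProteinMap
    clones: list[MutantClone]

    def mean_substitutions(self) -> float:
        return float(np.mean([len(c.substitutions) for c in self.clones]))

    def nonsense_free_fraction(self) -> float:
        free = sum(1 for c in self.clones
                   if all(ch.consequence != "nonsense" for ch in c.aa_changes))
        return free / len(self.clones)

    def expected_profile(self, abundances: np.ndarray | None = None,
                         mode: str = "codon_level") -> pd.Series:
        """True per-(protein, residue) amino-acid substitution frequency.

        codon_level sums abundance of clones whose (joint-codon) translation
        changes the residue; variant_level classifies each nucleotide
        substitution independently in reference codon context, as a
        per-allele variant caller would, and sums allele frequencies.
        """
        if abundances is None:
            abundances = np.array([c.abundance for c in self.clones])
        f: dict[tuple[str, int], float] = defaultdict(float)
        for clone, a in zip(self.clones, abundances):
            if a == 0:
                continue
            if mode == "codon_level":
                for ch in clone.aa_changes:
                    if ch.consequence != "synonymous":
                        f[(ch.protein_id, ch.residue_index)] += a
            elif mode == "variant_level":
                for pos, _ref, alt in clone.substitutions:
                    ch = classify_variant(self.reference, self.protein_map, pos, alt)
                    if ch.consequence != "synonymous":
                        f[(ch.protein_id, ch.residue_index)] += a
            else:
                raise ValueError(f"unknown mode {mode!r}")
        idx = pd.MultiIndex.from_tuples(sorted(f), names=["protein_id", "residue_index"])
        return pd.Series([f[k] for k in sorted(f)], index=idx, name="frequency")


def simulate_ep_library(
    params: MutagenesisParams,
    protein_map: ProteinMap,
    rules: SelectionRules | None = None,
) -> tuple[list[MutantClone], EpTruth]:
    """Draw an error-prone-PCR clone library; phenotypes come from ``rules``
    (a default SelectionRules with no special residues if omitted)."""
    reference = params.reference_cds
    _check_protein_map(reference, protein_map)
    rules = rules or SelectionRules()
    rng = np.random.default_rng(params.seed)
    L = len(reference)
    n_subs = rng.poisson(params.lambda_mut, size=params.n_clones)
    clones: list[MutantClone] = []
    width = len(str(params.n_clones))
    for i, k in enumerate(n_subs):
        k = int(min(k, L))
        positions = sorted(rng.choice(L, size=k, replace=False)) if k else []
        subs: list[tuple[int, str, str]] = []
        for pos in positions:
            ref = reference[pos]
            alt = DNA.replace(ref, "")[rng.integers(0, 3)]
            subs.append((int(pos), ref, alt))
        clone = MutantClone(
            clone_id=f"clone{i:0{width}d}",
            substitutions=subs,
            aa_changes=_aa_changes(reference, protein_map, subs),
            abundance=1.0 / params.n_clones,
        )
        assign_phenotype(clone, rules)
        clones.append(clone)
    return clones, EpTruth(reference, protein_map, clones)


def reachable_alt_aas(reference: str, protein_map: ProteinMap,
                      protein_id: str, residue_index: int) -> set[str]:
    """Amino acids reachable at a residue by one nucleotide substitution
    (excluding the reference aa and stops) — screen designs should pick
    resistance alleles from this set."""
    for pid, start, end in protein_map:
        if pid == protein_id:
            codon_start = start + 3 * (residue_index - 1)
            if not start <= codon_start < end:
                raise ValueError(f"residue {residue_index} outside {protein_id}")
            break
    else:
        raise ValueError(f"unknown protein {protein_id!r}")
    ref_codon = reference[codon_start:codon_start + 3]
    ref_aa = CODON_TO_AA[ref_codon]
    alts = set()
    for offset in range(3):
        for base in DNA:
            if base == ref_codon[offset]:
                continue
            mut = ref_codon[:offset] + base + ref_codon[offset + 1:]
            aa = CODON_TO_AA[mut]
            if aa not in ("*", ref_aa):
                alts.add(aa)
    return alts


def brute_force_stop_fraction(reference_cds: str) -> float:
    """q = fraction of all 3L single-nucleotide substitutions of the
    reference that create a stop codon, by exhaustive enumeration."""
    reference_cds = check_dna(reference_cds)
    L = len(reference_cds)
    if L % 3:
        raise ValueError("reference length must be divisible by 3")
    n_stop = 0
    for pos in range(L):
        codon_start = 3 * (pos // 3)
        ref_codon = reference_cds[codon_start:codon_start + 3]
        offset = pos - codon_start
        for alt in DNA:
            if alt == reference_cds[pos]:
                continue
            mut = ref_codon[:offset] + alt + ref_codon[offset + 1:]
            if CODON_TO_AA[mut] == "*" and CODON_TO_AA[ref_codon] != "*":
                n_stop += 1
    return n_stop / (3 * L)


ROUND_LABELS = frozenset({"rnf_selective", "bte2", "control"})


def apply_selection(
    clones: list[MutantClone],
    rules: SelectionRules,
    rounds: list[str],
    abundances: np.ndarray | None = None,
    seed: int | None = None,
    sample_cells: int | None = None,
) -> np.ndarray:
    """Pass a clone pool through selection rounds, returning new abundances.

    Each round multiplies clone abundance by its survival probability
    (rnf_selective: 1 or rnf_selection_kill; bte2: s_resistant or
    s_sensitive; control: 1) and renormalizes. With ``sample_cells`` set,
    each round additionally resamples a finite population multinomially
    (seeded), adding drift; the default is the deterministic expectation.
    """
    if abundances is None:
        abundances = np.array([c.abundance for c in clones], dtype=float)
    a = np.asarray(abundances, dtype=float).copy()
    if abs(a.sum() - 1.0) > 1e-9:
        raise ValueError(f"abundances sum to {a.sum()}, not 1")
    unknown = set(rounds) - ROUND_LABELS
    if unknown:
        raise ValueError(f"unknown selection round label(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed) if sample_cells is not None else None
    for label in rounds:
        if label == "rnf_selective":
            m = np.array([1.0 if c.rnf_functional else rules.rnf_selection_kill
                          for c in clones])
        elif label == "bte2":
            m = np.array([rules.s_resistant if c.bte2_resistant else rules.s_sensitive
                          for c in clones])
        else:  # control
            m = np.ones(len(clones))
        a = a * m
        total = a.sum()
        if total == 0:
            raise LibraryExtinctError(f"library extinct after round {label!r}")
        a = a / total
        if rng is not None:
            a = rng.multinomial(sample_cells, a) / sample_cells
            if a.sum() == 0:
                raise LibraryExtinctError(f"library extinct after round {label!r}")
    return a


def run_bte2_screen(
    clones: list[MutantClone],
    rules: SelectionRules,
    n_toxin_rounds: int = 2,
) -> dict[str, np.ndarray]:
    """Run the full screen design and return abundances per pool.

    input: library after the initial growth on Rnf-selective media;
    selected: input -> n rounds of toxin antagonism -> final Rnf selection;
    control: input -> n rounds of no-toxin competition -> final Rnf selection.
    """
    input_pool = apply_selection(clones, rules, ["rnf_selective"])
    selected = apply_selection(clones, rules,
                               ["bte2"] * n_toxin_rounds + ["rnf_selective"],
                               abundances=input_pool)
    control = apply_selection(clones, rules,
                              ["control"] * n_toxin_rounds + ["rnf_selective"],
                              abundances=input_pool)
    return {"input": input_pool, "selected": selected, "control": control}
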