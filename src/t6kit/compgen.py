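"""Comparative screen logic: ortholog filtering, toxin/Rnf/immunity
co-occurrence classification, pairwise global alignment and conservation.

The co-occurrence screen classifies each genome by (i) presence of a toxin
gene, (ii) presence of the Rnf complex — requiring BOTH diagnostic labels,
by default COG4657 (RnfA) and COG2878 (RnfB) — and (iii) whether a
candidate immunity gene sits adjacent (index +/- 1) to a toxin gene. The
default immunity predicate accepts an adjacent gene that either carries a
declared immunity label or is small (<= 400 aa) and free of toxin/Rnf
labels; the real criterion ("strongly predicted cognate immunity factor")
is a structure-level judgement this predicate stands in for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

DEFAULT_RNF_LABELS = frozenset({"COG4657", "COG2878"})
DEFAULT_TOXIN_LABELS = frozenset({"pfam20249"})
DEFAULT_IMMUNITY_LABELS = frozenset({"BTI2"})


# ---------------------------------------------------------------------------
# ortholog hit filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologHit:
    query_id: str
    target_id: str
    aligned_region_length: int  # amino acids
    has_ig_domain: bool
    target_genome_id: str

    def __post_init__(self) -> None:
        if self.aligned_region_length < 0:
            raise ValueError("aligned_region_length must be >= 0")


def filter_orthologs(hits: Iterable[OrthologHit], min_region_aa: int = 850,
                     require_ig: bool = True) -> list[OrthologHit]:
    """Retain bona fide toxin orthologs: aligned region >= ``min_region_aa``
    amino acids and, by default, the C-terminal Ig domain present."""
    return [h for h in hits
            if h.aligned_region_length >= min_region_aa
            and (h.has_ig_domain or not require_ig)]


# ---------------------------------------------------------------------------
# co-occurrence screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedGene:
    gene_id: str
    index: int
    labels: frozenset[str]
    length: int  # amino acids


@dataclass
class GenomeAnnotation:
    genome_id: str
    genes: list[AnnotatedGene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.genome_id}: duplicate gene ids")
        indices = sorted(g.index for g in self.genes)
        if indices != list(range(len(self.genes))):
            raise ValueError(f"{self.genome_id}: gene indices not consecutive from 0")

    def ordered(self) -> list[AnnotatedGene]:
        return sorted(self.genes, key=lambda g: g.index)


@dataclass(frozen=True)
class CooccurrenceRecord:
    genome_id: str
    has_toxin: bool
    has_rnf: bool
    immunity_adjacent: bool
    toxin_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.immunity_adjacent and not self.has_toxin:
            raise ValueError("immunity_adjacent requires has_toxin")


def default_immunity_rule(gene: AnnotatedGene,
                          toxin_labels: frozenset[str] = DEFAULT_TOXIN_LABELS,
                          rnf_labels: frozenset[str] = DEFAULT_RNF_LABELS,
                          immunity_labels: frozenset[str] = DEFAULT_IMMUNITY_LABELS,
                          max_length: int = 400) -> bool:
    if gene.labels & immunity_labels:
        return True
    return gene.length <= max_length and not (gene.labels & (toxin_labels | rnf_labels))


def screen_cooccurrence(
    annotations: Iterable[GenomeAnnotation],
    toxin_labels: Iterable[str] = DEFAULT_TOXIN_LABELS,
    rnf_labels: Iterable[str] = DEFAULT_RNF_LABELS,
    immunity_rule: Callable[[AnnotatedGene], bool] | None = None,
    window: int = 1,
) -> list[CooccurrenceRecord]:
    """One record per genome; ``has_rnf`` requires every diagnostic label."""
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no genome annotations supplied")
    toxin_labels = frozenset(toxin_labels)
    rnf_labels = frozenset(rnf_labels)
    if immunity_rule is None:
        immunity_rule = lambda g: default_immunity_rule(  # noqa: E731
            g, toxin_labels=toxin_labels, rnf_labels=rnf_labels)
    records = []
    for ann in annotations:
        genes = ann.ordered()
        all_labels: set[str] = set()
        for g in genes:
            all_labels |= g.labels
        toxin_genes = [g for g in genes if g.labels & toxin_labels]
        has_rnf = rnf_labels <= all_labels
        immunity = False
        for tg in toxin_genes:
            for nb in genes:
                if nb.index != tg.index and abs(nb.index - tg.index) <= window \
                        and immunity_rule(nb):
                    immunity = True
        records.append(CooccurrenceRecord(
            genome_id=ann.genome_id,
            has_toxin=bool(toxin_genes),
            has_rnf=has_rnf,
            immunity_adjacent=immunity,
            toxin_gene_ids=tuple(g.gene_id for g in toxin_genes),
        ))
    return records


def cooccurrence_table(records: Sequence[CooccurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome_id": [r.genome_id for r in records],
            "has_toxin": [r.has_toxin for r in records],
            "has_rnf": [r.has_rnf for r in records],
            "immunity_adjacent": [r.immunity_adjacent for r in records],
            "toxin_gene_ids": [",".join(r.toxin_gene_ids) for r in records],
        }
    )


# ---------------------------------------------------------------------------
# pairwise global alignment and conservation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentScoreScheme:
    """Affine-gap scoring: a gap of length k scores
    ``gap_open + (k - 1) * gap_extend`` (open charged on the first gapped
    column). Identity is computed over columns where both sequences are
    non-gap by default, or over all alignment columns."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -0.5
    identity_denominator: str = "columns_both_nongap"

    def __post_init__(self) -> None:
        if self.match < 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("require gap penalties <= 0 <= match")
        if self.identity_denominator not in ("columns_both_nongap", "alignment_columns"):
            raise ValueError(f"unknown identity_denominator "
                             f"{self.identity_denominator!r}")


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str
    identity_pct: float


def _identity(aligned_a: str, aligned_b: str, scheme: AlignmentScoreScheme) -> float:
    both = sum(1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-")
    ident = sum(1 for x, y in zip(aligned_a, aligned_b)
                if x == y and x != "-")
    denom = both if scheme.identity_denominator == "columns_both_nongap" \
        else len(aligned_a)
    if denom == 0:
        return 100.0 if aligned_a == aligned_b else 0.0
    return 100.0 * ident / denom


def global_align(seq_a: str, seq_b: str,
                 scheme: AlignmentScoreScheme | None = None) -> AlignmentResult:
    """Optimal global alignment under affine-gap scoring.

    Deterministic tie-breaking follows the underlying aligner's fixed
    enumeration order (diagonal moves preferred over gaps).
    """
    scheme = scheme or AlignmentScoreScheme()
    if len(seq_a) == 0 or len(seq_b) == 0:
        # degenerate: a single terminal gap run (or nothing at all)
        n = max(len(seq_a), len(seq_b))
        score = 0.0 if n == 0 else scheme.gap_open + (n - 1) * scheme.gap_extend
        aligned_a = seq_a or "-" * n
        aligned_b = seq_b or "-" * n
        return AlignmentResult(score, aligned_a, aligned_b,
                               _identity(aligned_a, aligned_b, scheme))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    a_row, b_row = _aligned_rows(best, seq_a, seq_b)
    return AlignmentResult(float(best.score), a_row, b_row,
                           _identity(a_row, b_row, scheme))


def _aligned_rows(alignment, seq_a: str, seq_b: str) -> tuple[str, str]:
    a_row: list[str] = []
    b_row: list[str] = []
    blocks_a, blocks_b = alignment.aligned
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        gap_a = sa - pa
        gap_b = sb - pb
        # unaligned stretches become gap columns (insertion then deletion)
        a_row.append(seq_a[pa:sa] + "-" * gap_b)
        b_row.append("-" * gap_a + seq_b[pb:sb])
        a_row.append(seq_a[sa:ea])
        b_row.append(seq_b[sb:eb])
        pa, pb = ea, eb
    a_row.append(seq_a[pa:] + "-" * (len(seq_b) - pb))
    b_row.append("-" * (len(seq_a) - pa) + seq_b[pb:])
    return "".join(a_row), "".join(b_row)


def pairwise_identity(seq_a: str, seq_b: str,
                      scheme: AlignmentScoreScheme | None = None) -> float:
    return global_align(seq_a, seq_b, scheme).identity_pct


def conservation_score(
    subunit_sequences: Mapping[str, Sequence[str]],
    scheme: AlignmentScoreScheme | None = None,
) -> tuple[dict[str, float], float]:
    """Mean pairwise percent identity per subunit and the unweighted mean
    across subunits (the overall similarity score). Subunits with fewer than
    two sequences are excluded with a warning."""
    per_subunit: dict[str, float] = {}
    for name, seqs in subunit_sequences.items():
        seqs = list(seqs)
        if len(seqs) < 2:
            warnings.warn(f"subunit {name!r} has {len(seqs)} sequence(s); excluded",
                          stacklevel=2)
            continue
        idents = [pairwise_identity(a, b, scheme) for a, b in combinations(seqs, 2)]
        per_subunit[name] = sum(idents) / len(idents)
    if not per_subunit:
        raise ValueError("no subunit with >= 2 sequences")
    overall = sum(per_subunit.values()) / len(per_subunit)
    return per_subunit, overall
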