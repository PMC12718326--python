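"""Simulation of a barcoded transposon (RB-Tn-seq) competition experiment.

The real screen used a library of ~3.2e5 uniquely barcoded mutants grown in
coculture with toxin-delivering antagonists at a population size at least
1,000-fold larger than the number of unique clones. The desk-scale stand-in
defaults to 5,000 barcodes over 500 genes with a 1,000-fold bottleneck;
every scale is a knob.

Selection acts multiplicatively: the expected post-selection frequency of
barcode *b* is proportional to ``initial_abundance(b) * w(gene(b), condition)``
where *w* is a per-(gene, condition) fitness multiplier (default 1). Read
counts are drawn by seeded multinomial sampling, optionally through a finite
cell bottleneck and with optional Dirichlet overdispersion on the
pre-selection frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._codon import DNA
from ..io import FastqRead
from .genome import INTERGENIC, GenomeModel

#: condition label that always exists and applies no selection
CONTROL_CONDITION = "control"


@dataclass(frozen=True)
class Insertion:
    barcode: str
    position: int
    gene_id: str  # or "intergenic"


@dataclass
class InsertionLibrary:
    """Barcoded transposon insertions plus ground-truth fitness multipliers."""

    insertions: list[Insertion]
    fitness: dict[tuple[str, str], float] = field(default_factory=dict)
    initial_abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        barcodes = [ins.barcode for ins in self.insertions]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes are not unique")
        if not self.initial_abundance:
            f = 1.0 / len(barcodes) if barcodes else 0.0
            self.initial_abundance = {b: f for b in barcodes}
        if set(self.initial_abundance) != set(barcodes):
            raise ValueError("initial_abundance keys do not match barcodes")
        total = sum(self.initial_abundance.values())
        if self.insertions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial abundances sum to {total}, not 1")
        for (gene, cond), w in self.fitness.items():
            if w < 0:
                raise ValueError(f"fitness w({gene},{cond}) = {w} < 0")

    @property
    def barcodes(self) -> list[str]:
        return [ins.barcode for ins in self.insertions]

    @property
    def conditions(self) -> set[str]:
        return {cond for (_, cond) in self.fitness} | {CONTROL_CONDITION}

    def w(self, gene_id: str, condition: str) -> float:
        return self.fitness.get((gene_id, condition), 1.0)


@dataclass
class TnTruth:
    """Ground truth paired with a simulated Tn-seq experiment."""

    condition: str
    gene_of: dict[str, str]                   # barcode -> gene_id / intergenic
    fitness: dict[tuple[str, str], float]
    expected_pre_freq: pd.Series              # barcode -> frequency
    expected_post_freq: pd.Series             # barcode -> frequency
    counts: pd.DataFrame                      # barcode x {pre, post}

    def per_gene_counts(self, sample: str) -> pd.Series:
        """Realized per-gene read totals (intergenic barcodes excluded)."""
        genes = self.counts.index.map(self.gene_of)
        s = self.counts[sample].groupby(genes).sum()
        return s.drop(INTERGENIC, errors="ignore")


def random_insertion_library(
    genome: GenomeModel,
    n_barcodes: int = 5000,
    fitness: dict[tuple[str, str], float] | None = None,
    barcode_length: int = 20,
    abundance_sigma: float = 0.5,
    seed: int = 0,
) -> InsertionLibrary:
    """Uniform random insertion positions, unique random barcodes, lognormal
    initial abundances (sigma on the log scale; 0 gives a uniform library)."""
    rng = np.random.default_rng(seed)
    if n_barcodes <= 0:
        raise ValueError("n_barcodes must be positive")
    barcodes: set[str] = set()
    while len(barcodes) < n_barcodes:
        chunk = rng.integers(0, 4, size=(n_barcodes - len(barcodes), barcode_length))
        for row in chunk:
            barcodes.add("".join(DNA[i] for i in row))
    ordered = sorted(barcodes)
    positions = rng.integers(0, genome.genome_length, size=n_barcodes)
    insertions = [
        Insertion(b, int(p), genome.locate(int(p)))
        for b, p in zip(ordered, positions)
    ]
    raw = np.exp(rng.normal(0.0, abundance_sigma, size=n_barcodes)) if abundance_sigma > 0 \
        else np.ones(n_barcodes)
    freq = raw / raw.sum()
    # exact renormalization to survive the 1e-9 conservation check
    abundance = {b: float(f) for b, f in zip(ordered, freq)}
    return InsertionLibrary(insertions, fitness or {}, abundance)


def simulate_tn_experiment(
    library: InsertionLibrary,
    condition: str,
    depth: int,
    bottleneck: int | None = None,
    seed: int = 0,
    overdispersion: float | None = None,
) -> tuple[pd.DataFrame, TnTruth]:
    """Simulate pre/post-selection barcode counts for one competition.

    Parameters
    ----------
    depth : reads sequenced per sample.
    bottleneck : number of cells surviving the competition (default
        1000 x number of barcodes, mirroring the screen's >=1,000-fold excess);
        a warning is issued if set below the number of barcodes.
    overdispersion : optional Dirichlet concentration applied to the
        pre-selection frequencies (mean-preserving; larger = tighter).

    Returns a (counts, truth) pair: counts is a barcode x {pre, post}
    DataFrame; identical seeds give bit-identical counts.
    """
    if not library.insertions:
        raise ValueError("empty insertion library")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if condition not in library.conditions:
        raise ValueError(
            f"unknown condition {condition!r}; known: {sorted(library.conditions)}")
    n = len(library.insertions)
    if bottleneck is None:
        bottleneck = 1000 * n
    if bottleneck < n:
        warnings.warn(
            f"bottleneck {bottleneck} < number of barcodes {n}; "
            "expect severe drift", stacklevel=2)

    rng = np.random.default_rng(seed)
    barcodes = library.barcodes
    f0 = np.array([library.initial_abundance[b] for b in barcodes])
    f0 = f0 / f0.sum()
    if overdispersion is not None:
        f_pre = rng.dirichlet(overdispersion * n * f0)
    else:
        f_pre = f0
    gene_of = {ins.barcode: ins.gene_id for ins in library.insertions}
    w = np.array([library.w(gene_of[b], condition) for b in barcodes])
    post_weight = f_pre * w
    if post_weight.sum() == 0:
        raise ValueError("all barcodes have zero post-selection weight")
    f_post = post_weight / post_weight.sum()

    pre_counts = rng.multinomial(depth, f_pre)
    cells = rng.multinomial(bottleneck, f_post)
    post_counts = rng.multinomial(depth, cells / cells.sum())

    counts = pd.DataFrame({"pre": pre_counts, "post": post_counts},
                          index=pd.Index(barcodes, name="barcode"))
    truth = TnTruth(
        condition=condition,
        gene_of=gene_of,
        fitness=dict(library.fitness),
        expected_pre_freq=pd.Series(f_pre, index=counts.index),
        expected_post_freq=pd.Series(f_post, index=counts.index),
        counts=counts,
    )
    return counts, truth


def barcode_reads(
    counts: pd.DataFrame,
    sample: str,
    left_flank: str = "GATGTCCACGAGGTCTCT",
    right_flank: str = "CGTACGCTGCAGGTCGAC",
    quality: int = 30,
    n_junk: int = 0,
    seed: int = 0,
) -> list[FastqRead]:
    """Emit amplicon-style reads for a counted sample: each read carries its
    barcode at a fixed offset (= len(left_flank)) between constant flanks.
    ``n_junk`` appends unassignable reads of random sequence."""
    rng = np.random.default_rng(seed)
    reads: list[FastqRead] = []
    i = 0
    for barcode, c in counts[sample].items():
        for _ in range(int(c)):
            seq = left_flank + barcode + right_flank
            reads.append(FastqRead(f"{sample}_read{i}", seq, [quality] * len(seq)))
            i += 1
    bclen = len(counts.index[0]) if len(counts.index) else 20
    total = len(left_flank) + bclen + len(right_flank)
    for j in range(n_junk):
        seq = "".join(DNA[k] for k in rng.integers(0, 4, size=total))
        reads.append(FastqRead(f"{sample}_junk{j}", seq, [quality] * total))
    return reads
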