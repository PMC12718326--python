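"""Synthetic genome annotation tables for the co-occurrence screen.

Each genome is an ordered gene list with functional labels. The rule is a
joint distribution over (toxin presence, Rnf presence, immunity adjacency):
toxin and Rnf are independent Bernoulli draws and the probability that a
toxin gene has an adjacent immunity gene is conditioned on Rnf status — the
default makes immunity certain in Rnf-lacking toxin carriers, mirroring the
observed invariant co-occurrence pattern.

Background genes are given lengths > 400 aa and neutral labels so that the
default adjacency predicate classifies exactly the planted immunity genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..compgen import (
    DEFAULT_IMMUNITY_LABELS,
    DEFAULT_RNF_LABELS,
    DEFAULT_TOXIN_LABELS,
    AnnotatedGene,
    CooccurrenceRecord,
    GenomeAnnotation,
)


@dataclass(frozen=True)
class AnnotationRule:
    p_toxin: float = 0.8
    p_rnf: float = 0.6
    #: P(immunity adjacent | toxin present), keyed by Rnf presence
    p_immunity_given_rnf: dict[bool, float] = field(
        default_factory=lambda: {True: 0.3, False: 1.0})

    def __post_init__(self) -> None:
        probs = [self.p_toxin, self.p_rnf, *self.p_immunity_given_rnf.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


def simulate_annotations(
    n_genomes: int,
    rule: AnnotationRule | None = None,
    seed: int = 0,
    n_background: int = 8,
) -> tuple[list[GenomeAnnotation], list[CooccurrenceRecord]]:
    """Generate genomes plus the true co-occurrence record for each."""
    if n_genomes < 0:
        raise ValueError("n_genomes must be >= 0")
    rule = rule or AnnotationRule()
    rng = np.random.default_rng(seed)
    toxin_label = next(iter(DEFAULT_TOXIN_LABELS))
    immunity_label = next(iter(DEFAULT_IMMUNITY_LABELS))
    genomes: list[GenomeAnnotation] = []
    truth: list[CooccurrenceRecord] = []
    for gi in range(n_genomes):
        has_toxin = bool(rng.random() < rule.p_toxin)
        has_rnf = bool(rng.random() < rule.p_rnf)
        immunity = bool(has_toxin and
                        rng.random() < rule.p_immunity_given_rnf[has_rnf])
        genes: list[tuple[frozenset[str], int]] = []
        for _ in range(n_background):
            genes.append((frozenset({f"COG{rng.integers(5000, 6000)}"}),
                          int(rng.integers(401, 1000))))
        if has_rnf:
            for lab in sorted(DEFAULT_RNF_LABELS):
                genes.insert(int(rng.integers(0, len(genes) + 1)),
                             (frozenset({lab}), int(rng.integers(401, 700))))
        if has_toxin:
            toxin_block: list[tuple[frozenset[str], int]] = [
                (frozenset({toxin_label}), int(rng.integers(900, 1200)))]
            if immunity:
                imm = (frozenset({immunity_label}), int(rng.integers(80, 300)))
                toxin_block = [imm, toxin_block[0]] if rng.random() < 0.5 \
                    else [toxin_block[0], imm]
            at = int(rng.integers(0, len(genes) + 1))
            genes[at:at] = toxin_block
        annotated = [
            AnnotatedGene(gene_id=f"g{gi}_{i:03d}", index=i, labels=labels,
                          length=length)
            for i, (labels, length) in enumerate(genes)
        ]
        genome_id = f"genome{gi:04d}"
        genomes.append(GenomeAnnotation(genome_id, annotated))
        toxin_ids = tuple(g.gene_id for g in annotated
                          if g.labels & DEFAULT_TOXIN_LABELS)
        truth.append(CooccurrenceRecord(
            genome_id=genome_id, has_toxin=has_toxin, has_rnf=has_rnf,
            immunity_adjacent=immunity, toxin_gene_ids=toxin_ids))
    return genomes, truth
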