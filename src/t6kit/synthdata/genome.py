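"""A minimal gene-model container for Tn-seq simulation and analysis.

Coordinates are 0-based half-open internally; an insertion at position ``p``
belongs to gene ``g`` iff ``start <= p < end``. Strand is carried but ignored
for membership. On-disk gene tables are 1-based inclusive and converted at
the boundary.
"""

from __future__ import annotations

import bisect
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..io import read_table, write_table

INTERGENIC = "intergenic"


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int
    end: int
    strand: str = "+"
    essential: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length / 1000.0


@dataclass
class GenomeModel:
    genes: list[Gene]
    genome_length: int
    _starts: list[int] = field(init=False, repr=False)
    _sorted: list[Gene] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if not (0 <= g.start < g.end <= self.genome_length):
                raise ValueError(f"gene {g.gene_id}: bad interval [{g.start}, {g.end})")
            if g.strand not in "+-":
                raise ValueError(f"gene {g.gene_id}: bad strand {g.strand!r}")
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        for strand in "+-":
            ordered = sorted((g for g in self.genes if g.strand == strand),
                             key=lambda g: g.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"genes {a.gene_id} and {b.gene_id} overlap on strand {strand}")
        self._sorted = sorted(self.genes, key=lambda g: (g.start, g.gene_id))
        self._starts = [g.start for g in self._sorted]

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def lengths_kb(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length_kb for g in self.genes})

    def locate(self, position: int) -> str:
        """Gene id containing ``position``, or ``"intergenic"``."""
        if not (0 <= position < self.genome_length):
            raise ValueError(f"position {position} outside genome [0, {self.genome_length})")
        i = bisect.bisect_right(self._starts, position)
        # walk left over genes starting at or before `position`
        for g in reversed(self._sorted[:i]):
            if g.end > position:
                return g.gene_id
        return INTERGENIC

    # -- on-disk representation (1-based inclusive) --------------------------

    def to_table(self, path: str | os.PathLike, seed: int | None = None) -> None:
        df = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "start": [g.start + 1 for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "essential": [int(g.essential) for g in self.genes],
            }
        )
        df.attrs["genome_length"] = self.genome_length
        write_table(df, path, seed=seed)

    @classmethod
    def from_table(cls, path: str | os.PathLike, genome_length: int) -> "GenomeModel":
        df = read_table(path, required=["gene_id", "start", "end", "strand"])
        genes = [
            Gene(str(r.gene_id), int(r.start) - 1, int(r.end), str(r.strand),
                 bool(getattr(r, "essential", 0)))
            for r in df.itertuples(index=False)
        ]
        return cls(genes, genome_length)


def random_genome(n_genes: int = 500, mean_gene_length: int = 1000,
                  intergenic: int = 200, seed: int = 0,
                  essential_fraction: float = 0.0) -> GenomeModel:
    """Lay out ``n_genes`` non-overlapping genes separated by intergenic gaps.

    Gene lengths are uniform in [0.5, 1.5] x ``mean_gene_length``, rounded to
    whole codons, alternating strands.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(mean_gene_length // 2, 3 * mean_gene_length // 2 + 1,
                           size=n_genes)
    lengths = (lengths // 3) * 3
    essential = rng.random(n_genes) < essential_fraction
    genes = []
    pos = intergenic
    width = len(str(n_genes))
    for i, (L, ess) in enumerate(zip(lengths, essential)):
        genes.append(Gene(f"gene{i:0{width}d}", pos, pos + int(L),
                          "+" if i % 2 == 0 else "-", bool(ess)))
        pos += int(L) + intergenic
    return GenomeModel(genes, genome_length=pos)
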