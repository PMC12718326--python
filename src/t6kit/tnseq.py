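"""RB-Tn-seq analysis: barcode tallying through rank fold enrichment.

Pipeline: reads per barcode are tallied for each sample; the summed reads
over all insertions per coding sequence are recorded; per-gene sums are
normalized by gene length (kb) and by the per-sample median of the
length-normalized abundances (so the median gene has normalized abundance
1); fold enrichment is the ratio of normalized abundances between the
selected and control samples, ranked descending.

A pseudocount (default alpha = 0.5 raw counts) keeps fold enrichment finite
for zero-count genes. Barcode matching is exact by default with an optional
one-mismatch rescue.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import FastqRead, read_table, write_table
from .synthdata.genome import INTERGENIC, GenomeModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TnseqNormConfig:
    pseudocount: float = 0.5            # alpha, on the raw summed-count scale
    barcode_match: str = "exact"        # "exact" | "one-mismatch"
    barcode_offset: int = 18            # barcode window start within each read
    barcode_length: int = 20

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.barcode_match not in ("exact", "one-mismatch"):
            raise ValueError(f"unknown barcode_match {self.barcode_match!r}")
        if self.barcode_offset < 0 or self.barcode_length <= 0:
            raise ValueError("bad barcode window")


@dataclass
class BarcodeMap:
    """barcode -> (insertion position, gene_id or 'intergenic')."""

    entries: dict[str, tuple[int, str]]

    def __post_init__(self) -> None:
        lengths = {len(b) for b in self.entries}
        if len(lengths) > 1:
            raise ValueError("barcodes have mixed lengths")

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def gene_of(self, barcode: str) -> str:
        return self.entries[barcode][1]

    def position_of(self, barcode: str) -> int:
        return self.entries[barcode][0]

    @classmethod
    def from_library(cls, library) -> "BarcodeMap":
        return cls({ins.barcode: (ins.position, ins.gene_id)
                    for ins in library.insertions})

    @classmethod
    def from_table(cls, path: str | os.PathLike) -> "BarcodeMap":
        df = read_table(path, required=["barcode", "position", "gene_id"])
        return cls({str(r.barcode): (int(r.position), str(r.gene_id))
                    for r in df.itertuples(index=False)})

    def to_table(self, path: str | os.PathLike, seed: int | None = None) -> None:
        df = pd.DataFrame(
            [(b, p, g) for b, (p, g) in self.entries.items()],
            columns=["barcode", "position", "gene_id"],
        )
        write_table(df, path, seed=seed)


@dataclass
class BarcodeCounts:
    counts: dict[str, dict[str, int]]            # sample -> barcode -> reads
    unassigned: dict[str, int] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts)

    def total_reads(self, sample: str) -> int:
        return sum(self.counts[sample].values()) + self.unassigned.get(sample, 0)

    def to_frame(self, barcodes: Iterable[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.counts).fillna(0).astype(int)
        if barcodes is not None:
            df = df.reindex(list(barcodes), fill_value=0)
        df.index.name = "barcode"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   unassigned: dict[str, int] | None = None) -> "BarcodeCounts":
        return cls({s: df[s].to_dict() for s in df.columns}, unassigned or {})


def _one_mismatch_lookup(window: str, bc_map: BarcodeMap) -> str | None:
    hits = set()
    for i, base in enumerate(window):
        for alt in "ACGT":
            if alt == base:
                continue
            cand = window[:i] + alt + window[i + 1:]
            if cand in bc_map:
                hits.add(cand)
    if len(hits) == 1:
        return hits.pop()
    return None  # ambiguous or absent


def tally_barcodes(
    reads_by_sample: Mapping[str, Iterable[FastqRead]],
    bc_map: BarcodeMap,
    cfg: TnseqNormConfig | None = None,
) -> BarcodeCounts:
    """Tally reads per barcode per sample.

    Each read increments exactly one barcode or the sample's unassigned
    tally, so assigned + unassigned equals the input read count. Reads too
    short for the barcode window are counted unassigned (and logged).
    """
    cfg = cfg or TnseqNormConfig()
    lo, hi = cfg.barcode_offset, cfg.barcode_offset + cfg.barcode_length
    out: dict[str, dict[str, int]] = {}
    unassigned: dict[str, int] = {}
    for sample, reads in reads_by_sample.items():
        tally: dict[str, int] = {}
        miss = short = 0
        for read in reads:
            seq = read.sequence
            if len(seq) < hi:
                short += 1
                miss += 1
                continue
            window = seq[lo:hi]
            barcode = window if window in bc_map else None
            if barcode is None and cfg.barcode_match == "one-mismatch":
                barcode = _one_mismatch_lookup(window, bc_map)
            if barcode is None:
                miss += 1
            else:
                tally[barcode] = tally.get(barcode, 0) + 1
        if short:
            logger.info("sample %s: %d reads shorter than the barcode window",
                        sample, short)
        out[sample] = tally
        unassigned[sample] = miss
    return BarcodeCounts(out, unassigned)


def aggregate_per_gene(
    counts: BarcodeCounts | pd.DataFrame,
    bc_map: BarcodeMap,
    genome: GenomeModel,
) -> pd.DataFrame:
    """Summed read count per (gene, sample); intergenic barcodes are excluded
    from gene sums. Every gene of the genome appears (zero-filled)."""
    df = counts.to_frame() if isinstance(counts, BarcodeCounts) else counts
    unknown = [b for b in df.index if b not in bc_map]
    if unknown:
        raise ValueError(
            f"{len(unknown)} counted barcode(s) absent from the map "
            f"(e.g. {unknown[0]!r}); tally should have left them unassigned")
    genes = pd.Index([bc_map.gene_of(b) for b in df.index])
    sums = df.groupby(genes).sum()
    sums = sums.drop(INTERGENIC, errors="ignore")
    sums = sums.reindex(genome.gene_ids, fill_value=0)
    sums.index.name = "gene_id"
    return sums


def normalize(S: pd.DataFrame, genome: GenomeModel,
              cfg: TnseqNormConfig | None = None) -> pd.DataFrame:
    """Length- and median-normalized abundances per sample:
    N_g = ((S_g + alpha) / L_g[kb]) / median_genes((S + alpha) / L[kb])."""
    cfg = cfg or TnseqNormConfig()
    if S.shape[0] == 0:
        raise ValueError("no genes to normalize")
    lengths_kb = genome.lengths_kb().reindex(S.index)
    if lengths_kb.isna().any():
        missing = S.index[lengths_kb.isna()][:3].tolist()
        raise ValueError(f"genes absent from genome model: {missing}")
    per_kb = (S + cfg.pseudocount).div(lengths_kb, axis=0)
    return per_kb / per_kb.median(axis=0)


def fold_enrichment(
    N: pd.DataFrame,
    selected: str,
    control: str,
    S: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene fold enrichment FE = N(selected) / N(control), sorted
    descending with rank 1..n (ties broken by gene_id)."""
    for sample in (selected, control):
        if sample not in N.columns:
            raise ValueError(f"sample {sample!r} missing from normalized table")
    if N[[selected, control]].isna().any().any():
        raise ValueError("gene missing from a sample")
    table = pd.DataFrame({
        "N_sel": N[selected],
        "N_ctrl": N[control],
    })
    if S is not None:
        table.insert(0, "S_sel", S[selected])
        table.insert(1, "S_ctrl", S[control])
    table["FE"] = table["N_sel"] / table["N_ctrl"]
    # lexicographic pre-sort + stable descending FE sort = deterministic ties
    table = table.sort_index().sort_values("FE", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def insertion_density(
    bc_map: BarcodeMap,
    genome: GenomeModel,
    counts: BarcodeCounts | pd.DataFrame | None = None,
    sample: str | None = None,
    min_count: int = 0,
) -> pd.Series:
    """Distinct insertion sites per kb per gene; with ``counts``/``sample``
    given, only barcodes with count >= min_count are counted as observed."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    observed: dict[str, set[int]] = {g: set() for g in genome.gene_ids}
    if counts is not None and sample is not None:
        df = counts.to_frame() if isinstance(counts, BarcodeCounts) else counts
        barcodes = df.index[df[sample] >= min_count]
    else:
        barcodes = list(bc_map.entries)
    for b in barcodes:
        if b not in bc_map:
            continue
        pos, gene = bc_map.entries[b]
        if gene != INTERGENIC and gene in observed:
            observed[gene].add(pos)
    lengths_kb = genome.lengths_kb()
    return pd.Series({g: len(sites) / lengths_kb[g]
                      for g, sites in observed.items()}, name="sites_per_kb")


def run_tnseq(
    reads_by_sample: Mapping[str, Iterable[FastqRead]],
    bc_map: BarcodeMap,
    genome: GenomeModel,
    selected: str,
    control: str,
    cfg: TnseqNormConfig | None = None,
) -> pd.DataFrame:
    """Full pipeline: tally -> aggregate -> normalize -> fold enrichment."""
    cfg = cfg or TnseqNormConfig()
    counts = tally_barcodes(reads_by_sample, bc_map, cfg)
    S = aggregate_per_gene(counts, bc_map, genome)
    N = normalize(S, genome, cfg)
    return fold_enrichment(N, selected, control, S=S)


def enrichment_from_counts(
    counts: pd.DataFrame,
    bc_map: BarcodeMap,
    genome: GenomeModel,
    selected: str,
    control: str,
    cfg: TnseqNormConfig | None = None,
) -> pd.DataFrame:
    """Pipeline entry for pre-tallied barcode counts (barcode x sample)."""
    S = aggregate_per_gene(counts, bc_map, genome)
    N = normalize(S, genome, cfg)
    return fold_enrichment(N, selected, control, S=S)


def write_enrichment(table: pd.DataFrame, path: str | os.PathLike,
                     seed: int | None = None) -> None:
    write_table(table.reset_index(), path, seed=seed)


def plot_rank_enrichment(table: pd.DataFrame, path: str | os.PathLike,
                         highlight: Iterable[str] = ()) -> None:
    """Rank vs fold-enrichment scatter (log y), optional highlighted genes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["rank"], table["FE"], s=8, c="0.6", label="genes")
    hl = [g for g in highlight if g in table.index]
    if hl:
        sub = table.loc[hl]
        ax.scatter(sub["rank"], sub["FE"], s=24, c="crimson", label="highlighted")
        ax.legend(frameon=False)
    ax.set_yscale("log")
    ax.set_xlabel("rank")
    ax.set_ylabel("fold enrichment (selected / control)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
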