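"""Mutant-screen readout from targeted long reads.

Stages: subsample reads per sample (the real screen used a random 50-60k
subset); align each read to the mutagenized locus; keep only alignments
covering both ends of the target (the full-length filter, removing
truncated amplicons); tally per-position alternate alleles across reads
(variant calling); sum, per residue, the frequencies of alternate alleles
causing amino acid substitutions; and compare toxin-selected frequencies to
the mean over control samples (differential enrichment).

Two calling modes are provided. ``variant_level`` (default) classifies each
nucleotide allele in reference codon context and sums allele frequencies —
the per-allele summation the screen used. ``codon_level`` extracts each
read's codon, translates it, and tallies non-reference amino acids
read-wise, which phases two substitutions within one codon.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._codon import CODON_TO_AA, check_dna
from .io import FastqRead
from .synthdata.epcr import ProteinMap, classify_variant

logger = logging.getLogger(__name__)

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}
NOCALL = 4  # gap / deleted / uncalled position within a read's span
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class TargetLocus:
    """The mutagenized reference locus with its in-frame CDS segments.

    The reference is the full amplicon; the protein map may leave
    non-coding flanks (vector / primer sequence around the mutagenized
    cassette), whose variants are classified non-coding and excluded from
    substitution profiles. CDS segments must be ordered, non-overlapping
    and of whole-codon length.
    """

    reference: str
    protein_map: ProteinMap

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference",
                           check_dna(self.reference, name="locus reference"))
        prev_end = 0
        for pid, start, end in self.protein_map:
            if not (prev_end <= start < end <= len(self.reference)):
                raise ValueError(f"CDS segment {pid} out of order or out of bounds")
            if (end - start) % 3:
                raise ValueError(f"CDS segment {pid} is not whole codons")
            prev_end = end

    @classmethod
    def from_cds(cls, cds: str, protein_map: ProteinMap,
                 left_flank: str = "", right_flank: str = "") -> "TargetLocus":
        """Build an amplicon locus from a bare CDS and CDS-relative map,
        optionally adding non-coding flanks."""
        off = len(left_flank)
        shifted = [(pid, start + off, end + off) for pid, start, end in protein_map]
        return cls(left_flank + cds + right_flank, shifted)

    def __len__(self) -> int:
        return len(self.reference)

    def residues(self) -> list[tuple[str, int]]:
        """All (protein_id, residue_index) pairs of the locus."""
        out = []
        for pid, start, end in self.protein_map:
            out.extend((pid, r) for r in range(1, (end - start) // 3 + 1))
        return out


@dataclass(frozen=True)
class MutselConfig:
    subsample_n: int = 55_000       # reads retained per sample
    subsample_seed: int = 0         # analysis-arm seed, independent of simulation
    clip_tolerance: int = 20        # bases; "covering both ends" slack
    min_variant_reads: int = 3
    epsilon: float | None = None    # enrichment floor; default 1/subsample_n
    calling_mode: str = "variant_level"
    min_identity: float = 0.6       # alignment identity floor for keeping a read
    error_rate: float = 0.0         # expected per-base substitution error of reads

    def __post_init__(self) -> None:
        if self.subsample_n <= 0:
            raise ValueError("subsample_n must be positive")
        if self.clip_tolerance < 0:
            raise ValueError("clip_tolerance must be >= 0")
        if self.calling_mode not in ("variant_level", "codon_level"):
            raise ValueError(f"unknown calling_mode {self.calling_mode!r}")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @property
    def eps(self) -> float:
        return self.epsilon if self.epsilon is not None else 1.0 / self.subsample_n

    @property
    def noise_floor(self) -> float:
        """Alleles below 3x the expected error rate are treated as noise."""
        return 3.0 * self.error_rate


@dataclass
class AlignedRead:
    read_id: str
    ref_start: int              # 0-based half-open span on the locus
    ref_end: int
    calls: np.ndarray           # uint8 codes over [ref_start, ref_end); 4 = no-call
    left_clip: int = 0
    right_clip: int = 0


# ---------------------------------------------------------------------------
# subsampling and alignment
# ---------------------------------------------------------------------------

def subsample_reads(reads: list[FastqRead], cfg: MutselConfig) -> list[FastqRead]:
    """Uniform sample without replacement, deterministic under subsample_seed;
    if fewer reads than requested, all are returned with a warning."""
    if len(reads) <= cfg.subsample_n:
        if len(reads) < cfg.subsample_n:
            warnings.warn(
                f"only {len(reads)} reads available; subsample_n={cfg.subsample_n}",
                stacklevel=2)
        return list(reads)
    rng = np.random.default_rng(cfg.subsample_seed)
    idx = rng.choice(len(reads), size=cfg.subsample_n, replace=False)
    return [reads[i] for i in sorted(idx)]


def _repair_cigar(ops: list[tuple[int, str]],
                  window: int = 20) -> list[tuple[int, str]]:
    """Collapse balanced insertion/deletion pairs separated by short aligned
    runs into direct base comparisons.

    Unit-cost edit alignment can tie two nearby substitutions with an
    I/D pair; under affine-gap scoring the substitution representation is
    strictly better, and keeping it avoids spurious no-calls.
    """
    changed = True
    while changed:
        changed = False
        for i, (n1, op1) in enumerate(ops):
            if op1 not in "ID":
                continue
            j = i + 1
            mid = 0
            while j < len(ops) and ops[j][1] in "=XM" and mid <= window:
                mid += ops[j][0]
                j += 1
            if j >= len(ops) or mid > window:
                continue
            n2, op2 = ops[j]
            if op2 not in "ID" or op2 == op1:
                continue
            m = min(n1, n2)
            repl: list[tuple[int, str]] = []
            if n1 > m:
                repl.append((n1 - m, op1))
            repl.append((mid + m, "M"))
            if n2 > m:
                repl.append((n2 - m, op2))
            ops[i:j + 1] = repl
            changed = True
            break
    return ops


def _align_one(read: FastqRead, locus: TargetLocus,
               cfg: MutselConfig) -> AlignedRead | None:
    seq = read.sequence
    if not seq:
        return None
    result = edlib.align(seq, locus.reference, mode="HW", task="path")
    if result["editDistance"] < 0:
        return None
    identity = 1.0 - result["editDistance"] / max(len(seq), 1)
    if identity < cfg.min_identity:
        return None
    start, end_incl = result["locations"][0]
    ref_end = end_incl + 1
    calls = np.full(ref_end - start, NOCALL, dtype=np.uint8)
    qpos = 0
    rpos = 0
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(result["cigar"])]
    for n, op in _repair_cigar(ops):
        if op in "=XM":
            for k in range(n):
                calls[rpos + k] = _BASE_CODE.get(seq[qpos + k], NOCALL)
            qpos += n
            rpos += n
        elif op == "I":     # extra read bases: consume query only
            qpos += n
        elif op == "D":     # missing read bases: reference positions are no-call
            rpos += n
    return AlignedRead(read.read_id, start, ref_end, calls)


def align_reads(reads: list[FastqRead], locus: TargetLocus,
                cfg: MutselConfig | None = None) -> list[AlignedRead]:
    """Semi-global alignment of each read within the locus (edit-distance
    based, banded); reads below the identity floor are discarded and the
    count logged."""
    cfg = cfg or MutselConfig()
    if not len(locus):
        raise ValueError("empty locus")
    out = []
    dropped = 0
    for read in reads:
        aln = _align_one(read, locus, cfg)
        if aln is None:
            dropped += 1
        else:
            out.append(aln)
    if dropped:
        logger.info("discarded %d unalignable read(s)", dropped)
    return out


def filter_full_length(alignments: list[AlignedRead], locus: TargetLocus,
                       cfg: MutselConfig | None = None) -> list[AlignedRead]:
    """Keep alignments covering both ends of the target within the clip
    tolerance t: ref_start <= t, ref_end >= L - t, clips <= t."""
    cfg = cfg or MutselConfig()
    t = cfg.clip_tolerance
    L = len(locus)
    return [a for a in alignments
            if a.ref_start <= t and a.ref_end >= L - t
            and a.left_clip <= t and a.right_clip <= t]


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def _pileup(alignments: list[AlignedRead], L: int) -> np.ndarray:
    """(L, 5) base-call counts; column 4 counts no-calls (excluded from
    coverage)."""
    mat = np.zeros((L, 5), dtype=np.int64)
    for a in alignments:
        pos = np.arange(a.ref_start, a.ref_end)
        np.add.at(mat, (pos, a.calls), 1)
    return mat


def call_variants(alignments: list[AlignedRead], locus: TargetLocus,
                  cfg: MutselConfig | None = None) -> pd.DataFrame:
    """Per-position alternate-allele calls across reads.

    Frequency uses covering reads (non-gap, non-no-call at the position) as
    the denominator; a site with zero coverage yields no call rather than
    frequency 0. Alleles need >= min_variant_reads support and a frequency
    above the noise floor (3x the configured error rate).
    """
    cfg = cfg or MutselConfig()
    if not alignments:
        raise ValueError("no alignments to call variants from")
    L = len(locus)
    mat = _pileup(alignments, L)
    coverage = mat[:, :4].sum(axis=1)
    ref_codes = np.array([_BASE_CODE[b] for b in locus.reference])
    rows = []
    for pos in np.nonzero(coverage)[0]:
        ref_code = ref_codes[pos]
        for alt_code in range(4):
            if alt_code == ref_code:
                continue
            n_alt = int(mat[pos, alt_code])
            if n_alt < cfg.min_variant_reads:
                continue
            freq = n_alt / coverage[pos]
            if freq < cfg.noise_floor:
                continue
            alt = "ACGT"[alt_code]
            if any(start <= pos < end for _, start, end in locus.protein_map):
                ch = classify_variant(locus.reference, list(locus.protein_map),
                                      int(pos), alt)
                rows.append((int(pos), locus.reference[pos], alt, n_alt,
                             int(coverage[pos]), freq, ch.protein_id,
                             ch.residue_index, ch.ref_aa, ch.alt_aa,
                             ch.consequence))
            else:
                rows.append((int(pos), locus.reference[pos], alt, n_alt,
                             int(coverage[pos]), freq, None, None, None, None,
                             "non_coding"))
    return pd.DataFrame(
        rows,
        columns=["position", "ref", "alt", "n_alt", "coverage", "frequency",
                 "protein_id", "residue_index", "ref_aa", "alt_aa", "consequence"],
    )


# ---------------------------------------------------------------------------
# amino acid substitution frequencies
# ---------------------------------------------------------------------------

def _profile_variant_level(calls: pd.DataFrame) -> pd.DataFrame:
    coding = calls[calls["consequence"].isin(["missense", "nonsense"])]
    prof = (coding.groupby(["protein_id", "residue_index", "alt_aa"],
                           as_index=False)["frequency"].sum())
    prof["residue_index"] = prof["residue_index"].astype(int)
    return prof


def _profile_codon_level(alignments: list[AlignedRead], locus: TargetLocus,
                         cfg: MutselConfig) -> pd.DataFrame:
    counts: dict[tuple[str, int, str], int] = {}
    denom: dict[tuple[str, int], int] = {}
    for pid, start, end in locus.protein_map:
        n_res = (end - start) // 3
        for r in range(n_res):
            denom[(pid, r + 1)] = 0
    for a in alignments:
        for pid, start, end in locus.protein_map:
            lo = max(start, a.ref_start)
            hi = min(end, a.ref_end)
            first = (lo - start + 2) // 3
            last = (hi - start) // 3
            for r in range(first, last):
                c0 = start + 3 * r
                codes = a.calls[c0 - a.ref_start: c0 - a.ref_start + 3]
                if (codes >= 4).any():
                    continue
                codon = "".join("ACGT"[c] for c in codes)
                denom[(pid, r + 1)] += 1
                aa = CODON_TO_AA[codon]
                ref_aa = CODON_TO_AA[locus.reference[c0:c0 + 3]]
                if aa != ref_aa:
                    key = (pid, r + 1, aa)
                    counts[key] = counts.get(key, 0) + 1
    rows = []
    for (pid, res, aa), n in sorted(counts.items()):
        if n < cfg.min_variant_reads:
            continue
        freq = n / denom[(pid, res)]
        if freq < cfg.noise_floor:
            continue
        rows.append((pid, res, aa, freq))
    return pd.DataFrame(rows, columns=["protein_id", "residue_index", "alt_aa",
                                       "frequency"])


def aa_substitution_frequencies(
    source: pd.DataFrame | list[AlignedRead],
    locus: TargetLocus,
    cfg: MutselConfig | None = None,
) -> pd.DataFrame:
    """Per-(protein, residue, alt_aa) substitution frequencies for one
    sample. ``source`` is a variant-call table (variant_level mode) or the
    retained alignments (codon_level mode). Synonymous alleles never
    contribute."""
    cfg = cfg or MutselConfig()
    if cfg.calling_mode == "variant_level":
        if not isinstance(source, pd.DataFrame):
            source = call_variants(source, locus, cfg)
        return _profile_variant_level(source)
    if isinstance(source, pd.DataFrame):
        raise TypeError("codon_level mode needs alignments, not a call table")
    return _profile_codon_level(source, locus, cfg)


def profile_per_residue(profile: pd.DataFrame) -> pd.Series:
    """Collapse a profile to total substitution frequency per residue."""
    if profile.empty:
        return pd.Series(dtype=float, name="frequency",
                         index=pd.MultiIndex.from_tuples(
                             [], names=["protein_id", "residue_index"]))
    return profile.groupby(["protein_id", "residue_index"])["frequency"].sum()


# ---------------------------------------------------------------------------
# differential enrichment
# ---------------------------------------------------------------------------

def differential_enrichment(
    profile_selected: pd.DataFrame,
    profiles_control: list[pd.DataFrame],
    cfg: MutselConfig | None = None,
) -> pd.DataFrame:
    """Per-residue enrichment of the toxin-selected pool over the mean of
    the control pools: E = f_sel / max(mean(f_ctrl), eps). Residues whose
    control mean is below eps while f_sel is observed are flagged
    ``selected_only`` — substitutions detected only after toxin selection.
    Sorted by E descending."""
    cfg = cfg or MutselConfig()
    if not profiles_control:
        raise ValueError("at least one control profile is required")
    f_sel = profile_per_residue(profile_selected)
    ctrl = [profile_per_residue(p) for p in profiles_control]
    universe = f_sel.index
    for c in ctrl:
        universe = universe.union(c.index)
    f_sel = f_sel.reindex(universe, fill_value=0.0)
    f_ctrl = sum(c.reindex(universe, fill_value=0.0) for c in ctrl) / len(ctrl)
    eps = cfg.eps
    E = f_sel / np.maximum(f_ctrl, eps)
    table = pd.DataFrame({
        "f_sel": f_sel,
        "f_ctrl_mean": f_ctrl,
        "E": E,
        "selected_only": (f_ctrl < eps) & (f_sel > 0),
    })
    return table.sort_index().sort_values("E", ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def sample_profile(reads: list[FastqRead], locus: TargetLocus,
                   cfg: MutselConfig | None = None) -> pd.DataFrame:
    """subsample -> align -> full-length filter -> profile, for one sample."""
    cfg = cfg or MutselConfig()
    subset = subsample_reads(reads, cfg)
    alignments = filter_full_length(align_reads(subset, locus, cfg), locus, cfg)
    if not alignments:
        raise ValueError("no full-length alignments survive filtering")
    if cfg.calling_mode == "variant_level":
        return aa_substitution_frequencies(
            call_variants(alignments, locus, cfg), locus, cfg)
    return aa_substitution_frequencies(alignments, locus, cfg)


def run_mutsel(
    reads_selected: list[FastqRead],
    reads_controls: dict[str, list[FastqRead]],
    locus: TargetLocus,
    cfg: MutselConfig | None = None,
) -> pd.DataFrame:
    cfg = cfg or MutselConfig()
    prof_sel = sample_profile(reads_selected, locus, cfg)
    prof_ctrl = [sample_profile(r, locus, cfg) for r in reads_controls.values()]
    return differential_enrichment(prof_sel, prof_ctrl, cfg)


def plot_substitution_profile(profile: pd.DataFrame, locus: TargetLocus,
                              path: str, sample: str = "") -> None:
    """Per-position substitution frequency bars, one panel per protein."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per_res = profile_per_residue(profile)
    pids = [pid for pid, _, _ in locus.protein_map]
    fig, axes = plt.subplots(len(pids), 1, figsize=(8, 1.8 * len(pids)),
                             squeeze=False)
    for ax, (pid, start, end) in zip(axes[:, 0], locus.protein_map):
        n_res = (end - start) // 3
        y = np.zeros(n_res)
        if not per_res.empty and pid in per_res.index.get_level_values(0):
            sub = per_res.loc[pid]
            y[np.asarray(sub.index, dtype=int) - 1] = sub.to_numpy()
        ax.bar(np.arange(1, n_res + 1), 100 * y, width=1.0, color="steelblue")
        ax.set_ylabel(f"{pid}\nalt aa (%)")
    axes[-1, 0].set_xlabel("residue")
    if sample:
        axes[0, 0].set_title(sample)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
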