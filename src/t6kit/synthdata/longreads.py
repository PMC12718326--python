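"""Long-read simulation for the targeted amplicon readout.

Stands in for a nanopore-style readout of the mutagenized locus: reads are
sampled from clones proportional to abundance, per-base substitution /
insertion / deletion errors are injected, and a configurable fraction of
reads is truncated (loses one terminal segment), which is what the
downstream "covering both ends" full-length filter removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._codon import DNA
from ..io import FastqRead
from .epcr import MutantClone


@dataclass(frozen=True)
class ReadErrorModel:
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    truncation_prob: float = 0.0
    min_truncation: int = 50    # shortest lost terminal segment, > clip tolerance
    quality: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("sub_rate + ins_rate + del_rate must be < 1")
        if not 0.0 <= self.truncation_prob <= 1.0:
            raise ValueError("truncation_prob outside [0, 1]")


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    clone_id: str
    truncated: bool


def random_flanks(length: int = 30, seed: int = 0) -> tuple[str, str]:
    """Random non-coding amplicon flanks (vector/primer stand-ins)."""
    rng = np.random.default_rng(seed)
    draw = rng.integers(0, 4, size=2 * length)
    flat = "".join(DNA[i] for i in draw)
    return flat[:length], flat[length:]


def clone_sequence(reference: str, clone: MutantClone) -> str:
    seq = list(reference)
    for pos, ref, alt in clone.substitutions:
        if seq[pos] != ref:
            raise ValueError(f"{clone.clone_id}: reference mismatch at {pos}")
        seq[pos] = alt
    return "".join(seq)


def _corrupt(seq: str, model: ReadErrorModel, rng: np.random.Generator) -> str:
    """Apply per-base substitution/insertion/deletion errors."""
    if model.sub_rate == model.ins_rate == model.del_rate == 0:
        return seq
    out: list[str] = []
    u = rng.random(len(seq))
    for base, x in zip(seq, u):
        if x < model.del_rate:
            continue
        if x < model.del_rate + model.sub_rate:
            out.append(DNA.replace(base, "")[rng.integers(0, 3)])
        else:
            out.append(base)
        if rng.random() < model.ins_rate:
            out.append(DNA[rng.integers(0, 4)])
    return "".join(out)


def simulate_long_reads(
    reference: str,
    clones: list[MutantClone],
    abundances: np.ndarray,
    model: ReadErrorModel,
    depth: int,
    left_flank: str = "",
    right_flank: str = "",
) -> tuple[list[FastqRead], list[ReadTruth]]:
    """Sample ``depth`` reads from the clone pool.

    ``reference`` is the mutagenized CDS the clones' substitutions refer to;
    optional non-coding flanks (vector/primer sequence) are prepended /
    appended to every source amplicon. A truncated read loses a uniformly
    chosen terminal segment (left or right) of length uniform in
    [min_truncation, L // 2]. Errors are applied after truncation.
    Deterministic for a fixed model seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    a = np.asarray(abundances, dtype=float)
    if a.min() < 0 or a.sum() <= 0:
        raise ValueError("invalid abundance vector")
    a = a / a.sum()
    rng = np.random.default_rng(model.seed)
    L = len(left_flank) + len(reference) + len(right_flank)
    source = rng.choice(len(clones), size=depth, p=a)
    seq_cache: dict[int, str] = {}
    reads: list[FastqRead] = []
    truth: list[ReadTruth] = []
    width = len(str(depth))
    for i, ci in enumerate(source):
        ci = int(ci)
        if ci not in seq_cache:
            seq_cache[ci] = (left_flank + clone_sequence(reference, clones[ci])
                             + right_flank)
        seq = seq_cache[ci]
        truncated = bool(rng.random() < model.truncation_prob)
        if truncated:
            cut = int(rng.integers(model.min_truncation, L // 2 + 1))
            seq = seq[cut:] if rng.random() < 0.5 else seq[:-cut]
        seq = _corrupt(seq, model, rng)
        rid = f"read{i:0{width}d}"
        reads.append(FastqRead(rid, seq, [model.quality] * len(seq)))
        truth.append(ReadTruth(rid, clones[ci].clone_id, truncated))
    return reads, truth
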