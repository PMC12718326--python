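"""Run configuration and deterministic seed derivation.

All randomness in the toolkit flows through a single global seed: every
stochastic operation derives its own stream seed from ``(global_seed, tag)``
where the tag names the operation (e.g. ``"tnseq/replicate3"``). No module
reads ambient entropy.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

_KNOWN_BLOCKS = frozenset({
    "seed", "outdir", "log_level",
    "tnseq", "mutsel", "synthdata", "compete", "compgen",
})


def derive_seed(global_seed: int, tag: str) -> int:
    """Derive a per-operation seed (< 2**31) from the global seed and a tag."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def rng_for(global_seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, tag))


@dataclass
class RunConfig:
    """Top-level configuration: a global seed plus per-module parameter blocks."""

    seed: int = 0
    outdir: str = "t6kit_out"
    log_level: str = "INFO"
    tnseq: dict[str, Any] = field(default_factory=dict)
    mutsel: dict[str, Any] = field(default_factory=dict)
    synthdata: dict[str, Any] = field(default_factory=dict)
    compete: dict[str, Any] = field(default_factory=dict)
    compgen: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        unknown = set(data) - _KNOWN_BLOCKS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def digest(self) -> str:
        """Stable SHA-256 hash of the configuration."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def seed_for(self, tag: str) -> int:
        return derive_seed(self.seed, tag)


def file_checksum(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
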