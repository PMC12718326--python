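"""Competition and growth statistics.

The core quantity is the competitive index

    C.I. = (CFU_f recipient / CFU_i recipient) / (CFU_f donor / CFU_i donor)

where 1 means no differential fitness. Toxin-delivery-dependent relative
competitiveness is the C.I. against a toxin-delivering antagonist divided
by the C.I. against a T6SS-inactivated control strain. Growth yields are
recovered CFU normalized by input CFU, reported as ratios to a reference
strain. Outcome proportions (e.g. the fraction of allelic-exchange events
resolving to a deletion) carry exact Clopper–Pearson binomial intervals.

Zero final CFUs are censoring events (plating detection limits): they are
reported as flagged zeros / missing values rather than silently substituted;
``censor_zeros`` provides the optional detection-limit substitution mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CompetitionRecord:
    donor_id: str
    recipient_id: str
    cfu_i_donor: float
    cfu_i_recipient: float
    cfu_f_donor: float
    cfu_f_recipient: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.cfu_i_donor <= 0 or self.cfu_i_recipient <= 0:
            raise ValueError("initial CFUs must be positive")
        if self.cfu_f_donor < 0 or self.cfu_f_recipient < 0:
            raise ValueError("final CFUs must be non-negative")

    def swapped(self) -> "CompetitionRecord":
        """Donor and recipient roles exchanged."""
        return CompetitionRecord(
            donor_id=self.recipient_id, recipient_id=self.donor_id,
            cfu_i_donor=self.cfu_i_recipient, cfu_i_recipient=self.cfu_i_donor,
            cfu_f_donor=self.cfu_f_recipient, cfu_f_recipient=self.cfu_f_donor,
            condition=self.condition,
        )


@dataclass(frozen=True)
class CompetitionResult:
    ci: float | None            # None = undefined (donor extinct)
    recipient_extinct: bool = False
    donor_extinct: bool = False


@dataclass(frozen=True)
class YieldRecord:
    strain_id: str
    medium: str
    cfu_input: float
    cfu_recovered: float

    def __post_init__(self) -> None:
        if self.cfu_input <= 0:
            raise ValueError("CFU_input must be positive")
        if self.cfu_recovered < 0:
            raise ValueError("CFU_recovered must be non-negative")

    @property
    def normalized_yield(self) -> float:
        return self.cfu_recovered / self.cfu_input


def competitive_index(rec: CompetitionRecord) -> CompetitionResult:
    """C.I. with extinction flags; donor extinction makes the C.I. undefined
    (reported missing, never infinity)."""
    if rec.cfu_f_donor == 0:
        return CompetitionResult(ci=None, donor_extinct=True,
                                 recipient_extinct=rec.cfu_f_recipient == 0)
    ci = (rec.cfu_f_recipient / rec.cfu_i_recipient) / (rec.cfu_f_donor / rec.cfu_i_donor)
    return CompetitionResult(ci=ci, recipient_extinct=rec.cfu_f_recipient == 0)


def relative_competitiveness(ci_toxin: float, ci_control: float) -> tuple[float, float]:
    """(ratio, percent of control) for a toxin-arm C.I. vs a no-toxin C.I."""
    if ci_control <= 0:
        raise ValueError("control C.I. must be positive")
    if ci_toxin < 0:
        raise ValueError("C.I. must be non-negative")
    ratio = ci_toxin / ci_control
    return ratio, 100.0 * ratio


def normalized_yield(rec: YieldRecord, reference: YieldRecord
                     ) -> tuple[float, float | None]:
    """(normalized yield of ``rec``, yield ratio vs ``reference``); the ratio
    is None when the reference strain recovered nothing."""
    y = rec.normalized_yield
    ref = reference.normalized_yield
    return y, (y / ref if ref > 0 else None)


def censor_zeros(rec: CompetitionRecord, detection_limit: float) -> CompetitionRecord:
    """Detection-limit substitution mode: replace zero final CFUs by
    ``detection_limit`` (1 / lowest plated dilution volume)."""
    if detection_limit <= 0:
        raise ValueError("detection_limit must be positive")
    return replace(
        rec,
        cfu_f_donor=rec.cfu_f_donor or detection_limit,
        cfu_f_recipient=rec.cfu_f_recipient or detection_limit,
    )


def outcome_proportion(successes: int, trials: int, level: float = 0.95
                       ) -> tuple[float, tuple[float, float]]:
    """Proportion with an exact Clopper–Pearson interval.

    Interior points use the two-sided construction (alpha/2 in each tail);
    at the boundaries (0 or all successes) the whole alpha goes to the one
    informative side, so e.g. the upper bound at 0/n is 1 - alpha**(1/n).
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    alpha = 1.0 - level
    p = successes / trials
    if successes == 0:
        return p, (0.0, 1.0 - alpha ** (1.0 / trials))
    if successes == trials:
        return p, (alpha ** (1.0 / trials), 1.0)
    lo = float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return p, (lo, hi)


def summarize_ci(values: Sequence[float], method: str = "geometric") -> float:
    """Replicate summary for C.I. values; geometric mean by default (C.I. is
    a ratio quantity), arithmetic as an option. Zeros are invalid for the
    geometric mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values")
    if method == "arithmetic":
        return float(arr.mean())
    if method == "geometric":
        if (arr <= 0).any():
            raise ValueError("geometric mean requires positive C.I. values")
        return float(math.exp(np.log(arr).mean()))
    raise ValueError(f"unknown method {method!r}")
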