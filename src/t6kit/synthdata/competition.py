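"""CFU competition record simulation.

Generates inputs for the competitive-index arithmetic: both populations
grow by ``growth_factor``; the recipient is additionally reduced by
``kill_factor`` (toxin-mediated killing). Optional lognormal noise on the
final CFUs; deterministic at noise_sd = 0, where the downstream C.I. is
exactly 1 / kill_factor.
"""

from __future__ import annotations

import numpy as np

from ..compete import CompetitionRecord


def simulate_competition(
    cfu_i_donor: float,
    cfu_i_recipient: float,
    kill_factor: float = 1.0,
    growth_factor: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    donor_id: str = "donor",
    recipient_id: str = "recipient",
    condition: str = "toxin",
) -> CompetitionRecord:
    if cfu_i_donor <= 0 or cfu_i_recipient <= 0:
        raise ValueError("initial CFUs must be positive")
    if kill_factor <= 0 or growth_factor <= 0:
        raise ValueError("kill_factor and growth_factor must be positive")
    cfu_f_donor = cfu_i_donor * growth_factor
    cfu_f_recipient = cfu_i_recipient * growth_factor / kill_factor
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cfu_f_donor *= float(np.exp(rng.normal(0.0, noise_sd)))
        cfu_f_recipient *= float(np.exp(rng.normal(0.0, noise_sd)))
    return CompetitionRecord(
        donor_id=donor_id,
        recipient_id=recipient_id,
        cfu_i_donor=cfu_i_donor,
        cfu_i_recipient=cfu_i_recipient,
        cfu_f_donor=cfu_f_donor,
        cfu_f_recipient=cfu_f_recipient,
        condition=condition,
    )
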