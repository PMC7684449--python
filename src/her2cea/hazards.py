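"""Probability-scale conversions between risk horizons, medians, and cycles.

All conversions assume a constant hazard within the stated horizon, so a
multi-year probability ``p`` over ``y`` years maps to the per-year probability
``1 - (1 - p)**(1/y)``, and a median survival of ``m`` months maps to the
annual death probability ``1 - 2**(-12/m)`` (exponential survival).  Relative
risks act multiplicatively on the probability scale.
"""

from __future__ import annotations

import math
from typing import Sequence

__all__ = [
    "multiyear_prob_to_annual",
    "median_survival_to_annual_prob",
    "apply_rr",
    "normalize_competing",
]


def multiyear_prob_to_annual(p: float, years: float) -> float:
    """Convert a ``years``-horizon probability to a 1-year probability."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability {p} must lie in [0, 1) (p = 1 implies infinite hazard)")
    if years <= 0:
        raise ValueError(f"years must be positive, got {years}")
    return 1.0 - (1.0 - p) ** (1.0 / years)


def median_survival_to_annual_prob(median_months: float) -> float:
    """Annual death probability implied by an exponential median survival."""
    if median_months <= 0:
        raise ValueError(f"median survival must be positive, got {median_months}")
    return 1.0 - 2.0 ** (-12.0 / median_months)


def apply_rr(p_ref: float, rr: float) -> float:
    """Scale a reference probability by a relative risk, capped at 1."""
    if not 0.0 <= p_ref < 1.0:
        raise ValueError(f"reference probability {p_ref} must lie in [0, 1)")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    return min(rr * p_ref, 1.0)


def normalize_competing(event_probs: Sequence[float]) -> list[float]:
    """Make a set of competing per-cycle exit probabilities jointly feasible.

    If the probabilities already sum to at most 1 they pass through unchanged.
    Otherwise each is converted to a rate ``-ln(1 - p)``, and the combined
    exit probability ``1 - exp(-sum of rates)`` is allocated proportionally to
    the rates, which preserves the ratios between events.
    """
    probs = [float(p) for p in event_probs]
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"competing probability {p} outside [0, 1]")
    if sum(probs) <= 1.0:
        return probs
    if any(p == 1.0 for p in probs):
        raise ValueError("cannot combine a certain event (p = 1) with other competing events")
    rates = [-math.log1p(-p) for p in probs]
    total_rate = sum(rates)
    total_exit = -math.expm1(-total_rate)
    return [total_exit * r / total_rate for r in rates]
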