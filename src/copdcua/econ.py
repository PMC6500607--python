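"""Health-economic primitives.

Discounting of future costs/outcomes, conversion between per-period
probabilities and instantaneous rates, cost-utility ratios (CUR), incremental
cost-utility ratios (ICUR), and classification of an ICUR against
willingness-to-pay multiples of per-capita GDP (WHO convention: <1x very
cost-effective, 1-3x cost-effective, >3x not cost-effective).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "DiscountSettings",
    "WTPThreshold",
    "CUAResult",
    "Dominance",
    "IncrementalResult",
    "prob_to_rate",
    "rate_to_prob",
    "annualize",
    "semiannualize",
    "present_value",
    "discount_factor",
    "cur",
    "icur",
    "classify_wtp",
]


@dataclass(frozen=True)
class DiscountSettings:
    """Annual discount rate ``rate`` with the sensitivity range [low, high].

    Default 5%/year with a 0-8% sensitivity band, the convention for Chinese
    pharmacoeconomic evaluations.
    """

    rate: float = 0.05
    low: float = 0.0
    high: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"discount rate must lie in [0, 1], got {self.rate}")
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ValueError(
                f"discount range must satisfy 0 <= low <= high <= 1, got [{self.low}, {self.high}]"
            )


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness-to-pay threshold anchored at per-capita GDP (Yuan)."""

    gdp_per_capita: float = 78951.15
    lower_multiple: float = 1.0
    upper_multiple: float = 3.0

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0:
            raise ValueError("gdp_per_capita must be positive")
        if not (0 < self.lower_multiple <= self.upper_multiple):
            raise ValueError("WTP multiples must satisfy 0 < lower <= upper")


def prob_to_rate(p0: float, t0: float) -> float:
    """Instantaneous event rate implied by probability ``p0`` over ``t0`` years.

    r = -ln(1 - p0) / t0, assuming a constant hazard over the interval.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"probability must lie in [0, 1], got {p0}")
    if p0 == 1.0:
        raise ValueError("probability 1 implies an infinite rate")
    if t0 <= 0:
        raise ValueError(f"duration must be positive, got {t0}")
    return -math.log1p(-p0) / t0


def rate_to_prob(r: float, t: float) -> float:
    """Event probability over ``t`` years at constant rate ``r``: P = 1 - exp(-r t)."""
    if r < 0:
        raise ValueError(f"rate must be nonnegative, got {r}")
    if t < 0:
        raise ValueError(f"duration must be nonnegative, got {t}")
    return -math.expm1(-r * t)


def annualize(p_semiannual: float) -> float:
    """Convert a semiannual probability to an annual one.

    Equivalent to rate_to_prob(prob_to_rate(p, 0.5), 1) = 1 - (1 - p)^2 under
    the constant-hazard assumption.
    """
    if not (0.0 <= p_semiannual < 1.0):
        raise ValueError(f"semiannual probability must lie in [0, 1), got {p_semiannual}")
    if p_semiannual == 0.0:
        return 0.0
    return rate_to_prob(prob_to_rate(p_semiannual, 0.5), 1.0)


def semiannualize(p_annual: float) -> float:
    """Inverse of :func:`annualize`: the semiannual probability whose
    constant-hazard annualization equals ``p_annual`` (1 - sqrt(1 - p))."""
    if not (0.0 <= p_annual < 1.0):
        raise ValueError(f"annual probability must lie in [0, 1), got {p_annual}")
    return 1.0 - math.sqrt(1.0 - p_annual)


def discount_factor(rate: float, year: int) -> float:
    """(1 + i)^-t weight for an amount falling due at the end of year ``t`` (t >= 1)."""
    if 1.0 + rate <= 0:
        raise ValueError(f"discount rate {rate} makes (1 + i) non-positive")
    return (1.0 + rate) ** (-year)


def present_value(
    stream: Iterable[Tuple[int, float]],
    settings: DiscountSettings | float = DiscountSettings(),
) -> float:
    """Present value of amounts F_t due at the end of years t = 1, 2, ...:

        P = sum_t F_t (1 + i)^-t

    ``settings`` may be a :class:`DiscountSettings` or a bare rate.
    """
    rate = settings.rate if isinstance(settings, DiscountSettings) else float(settings)
    total = 0.0
    for year, amount in stream:
        if year < 1 or year != int(year):
            raise ValueError(f"years must be integers >= 1, got {year}")
        if not math.isfinite(amount):
            raise ValueError(f"amount at year {year} is not finite")
        total += amount * discount_factor(rate, int(year))
    return total


@dataclass(frozen=True)
class CUAResult:
    """Per-arm cost-utility totals.

    ``cost`` and ``qaly`` are the discounted totals used by CUR/ICUR.
    ``life_years`` follows the same convention as ``cost`` (discounted for a
    simulated trace; as-printed when built from published totals);
    ``life_years_undiscounted`` is carried alongside when known.
    """

    arm: str
    cost: float
    qaly: float
    life_years: float
    life_years_undiscounted: Optional[float] = None

    @property
    def cur(self) -> Optional[float]:
        """Cost-utility ratio C/U (Yuan per QALY); None when no QALYs accrued."""
        if self.qaly == 0:
            return None
        return self.cost / self.qaly


def cur(total_cost: float, total_qaly: float) -> float:
    """CUR = C / U, the cost of one unit of utility (Yuan per QALY)."""
    if total_qaly <= 0:
        raise ZeroDivisionError("CUR undefined for non-positive total QALYs")
    return total_cost / total_qaly


class Dominance(Enum):
    A_DOMINANT = "A dominant"        # A cheaper and at least as effective
    B_DOMINANT = "B dominant"        # B cheaper and at least as effective
    TRADEOFF = "trade-off"           # one arm costlier but more effective
    EQUIVALENT = "equivalent"        # identical cost and effect


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison of arm A against arm B.

    ``icur`` = delta_cost / delta_effect (Yuan per incremental QALY); it is
    None when the effect difference is zero (undefined, signalled rather than
    +/-inf so downstream sweeps can handle sign crossings).
    """

    arm_a: str
    arm_b: str
    delta_cost: float
    delta_effect: float
    icur: Optional[float]
    dominance: Dominance
    effect_label: str = "QALY"
    wtp_category: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.icur is not None


def _dominance(delta_cost: float, delta_effect: float) -> Dominance:
    if delta_cost == 0 and delta_effect == 0:
        return Dominance.EQUIVALENT
    if delta_cost <= 0 and delta_effect >= 0:
        return Dominance.A_DOMINANT
    if delta_cost >= 0 and delta_effect <= 0:
        return Dominance.B_DOMINANT
    return Dominance.TRADEOFF


def icur(
    cost_a: float,
    effect_a: float,
    cost_b: float,
    effect_b: float,
    arm_a: str = "A",
    arm_b: str = "B",
    effect_label: str = "QALY",
) -> IncrementalResult:
    """ICUR = (cost_A - cost_B) / (effect_A - effect_B) = dC / dU."""
    for v in (cost_a, effect_a, cost_b, effect_b):
        if not math.isfinite(v):
            raise ValueError("ICUR inputs must be finite")
    d_cost = cost_a - cost_b
    d_eff = effect_a - effect_b
    ratio = d_cost / d_eff if d_eff != 0 else None
    return IncrementalResult(
        arm_a=arm_a,
        arm_b=arm_b,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icur=ratio,
        dominance=_dominance(d_cost, d_eff),
        effect_label=effect_label,
    )


def classify_wtp(icur_value: float, threshold: WTPThreshold = WTPThreshold()) -> str:
    """WHO willingness-to-pay category for an ICUR.

    < 1x GDP per capita: "very cost-effective"; between 1x and 3x inclusive:
    "cost-effective"; above 3x: "not cost-effective".
    """
    if not math.isfinite(icur_value):
        raise ValueError("ICUR must be finite to classify")
    low = threshold.lower_multiple * threshold.gdp_per_capita
    high = threshold.upper_multiple * threshold.gdp_per_capita
    if icur_value < low:
        return "very cost-effective"
    if icur_value <= high:
        return "cost-effective"
    return "not cost-effective"


def round_yuan(value: float) -> int:
    """Round to integer Yuan, half away from zero (presentation only)."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)
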