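"""Three-state Markov cohort engine for stable COPD.

States: GOLD 1-2 (mild/moderate airflow limitation), GOLD 3-4
(severe/very severe), and death (absorbing).  The cycle length is one year
over a 40-year horizon for a closed cohort (default 100 000 persons).

Acute exacerbations (AE) are transient within-cycle events, not states: an
AE lasts about half a month, so each person-year in a living state carries a
probability of a mild AE (outpatient) and of a severe AE (hospitalization).
AEs contribute episode costs, depress the cycle's utility for the AE
duration (mild x0.85, severe x0.30 of the stable utility), and severe AEs
carry a case-fatality applied before the annual all-cause transition.

Rewards (cost, QALY, life years) accrue on start-of-cycle occupancy and are
discounted by (1+i)^-k for cycle k = 1..K; an optional half-cycle correction
averages start- and end-of-cycle occupancy instead.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .econ import (
    CUAResult,
    DiscountSettings,
    IncrementalResult,
    WTPThreshold,
    classify_wtp,
    discount_factor,
    icur,
)

__all__ = [
    "STATES",
    "StateCosts",
    "CostSet",
    "UtilitySet",
    "AEProbs",
    "AESet",
    "ArmParameters",
    "SimulationSettings",
    "ParameterError",
    "CohortTrace",
    "build_transition_matrix",
    "effective_transition_matrix",
    "cycle_reward",
    "run_cohort",
    "summarize",
    "compare_arms",
]

STATES: Tuple[str, ...] = ("gold12", "gold34", "dead")
LIVING: Tuple[str, ...] = ("gold12", "gold34")


class ParameterError(ValueError):
    """A model parameter violates its constraints."""


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class StateCosts:
    """Annual costs for one disease state (Yuan): stable-period annual cost,
    plus per-episode costs of a mild AE (outpatient/community) and a severe
    AE (hospitalization)."""

    stable: float
    mild_ae: float
    severe_ae: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ParameterError(f"cost {f.name} must be >= 0, got {v}")


@dataclass(frozen=True)
class CostSet:
    gold12: StateCosts
    gold34: StateCosts


@dataclass(frozen=True)
class UtilitySet:
    """Stable-state utilities and AE utility multipliers.

    During an AE the utility is scaled: mild AE to 85% of the stable value,
    severe AE (inpatient) to 30%.
    """

    gold12: float
    gold34: float
    mild_multiplier: float = 0.85
    severe_multiplier: float = 0.30

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check_prob(getattr(self, f.name), f"utility field {f.name}")


@dataclass(frozen=True)
class AEProbs:
    """Annual probabilities of experiencing a mild vs a severe AE in a state.

    The defaults derived from the trial sum to exactly 1 per state: every
    person-year experiences one AE, mild or severe.  An overall incidence
    scaling (``ArmParameters.ae_incidence``) can relax that.
    """

    mild: float
    severe: float

    def __post_init__(self) -> None:
        _check_prob(self.mild, "mild AE probability")
        _check_prob(self.severe, "severe AE probability")
        if self.mild + self.severe > 1.0 + 1e-12:
            raise ParameterError(
                f"mild + severe AE probabilities exceed 1: {self.mild} + {self.severe}"
            )


@dataclass(frozen=True)
class AESet:
    gold12: AEProbs
    gold34: AEProbs


@dataclass(frozen=True)
class ArmParameters:
    """All model inputs for one treatment arm."""

    name: str
    costs: CostSet
    utilities: UtilitySet
    ae: AESet
    progression: float                   # annual GOLD 1-2 -> GOLD 3-4
    mortality_gold12: float = 0.0286     # annual all-cause, GOLD 1-2
    mortality_gold34: float = 0.126      # annual all-cause, GOLD 3-4
    severe_ae_fatality: float = 0.032    # case-fatality among hospitalized AEs
    apply_ae_fatality: bool = True       # switch to avoid double counting
    ae_duration: float = 0.5 / 12.0      # AE lasts about half a month
    ae_incidence: float = 1.0            # scaling of annual AE probabilities

    def __post_init__(self) -> None:
        _check_prob(self.progression, f"{self.name}: progression")
        _check_prob(self.mortality_gold12, f"{self.name}: mortality_gold12")
        _check_prob(self.mortality_gold34, f"{self.name}: mortality_gold34")
        _check_prob(self.severe_ae_fatality, f"{self.name}: severe_ae_fatality")
        if not (0.0 <= self.ae_duration <= 1.0):
            raise ParameterError(f"{self.name}: ae_duration must be a year fraction")
        if self.ae_incidence < 0:
            raise ParameterError(f"{self.name}: ae_incidence must be >= 0")
        for state in LIVING:
            probs: AEProbs = getattr(self.ae, state)
            if self.ae_incidence * (probs.mild + probs.severe) > 1.0 + 1e-12:
                raise ParameterError(
                    f"{self.name}/{state}: scaled AE probabilities exceed 1"
                )
        if self.progression + self.mortality_gold12 > 1.0 + 1e-12:
            raise ParameterError(
                f"{self.name}/gold12: progression {self.progression} + mortality "
                f"{self.mortality_gold12} exceeds 1"
            )


@dataclass(frozen=True)
class SimulationSettings:
    """Cohort simulation controls."""

    cohort_size: float = 100_000.0
    cycles: int = 40
    discount: DiscountSettings = field(default_factory=DiscountSettings)
    initial_distribution: Tuple[float, float] = (0.5, 0.5)  # (GOLD 1-2, GOLD 3-4)
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ParameterError("cohort size must be positive")
        if self.cycles < 1:
            raise ParameterError("number of cycles must be >= 1")
        f12, f34 = self.initial_distribution
        if f12 < 0 or f34 < 0 or abs(f12 + f34 - 1.0) > 1e-9:
            raise ParameterError(
                f"initial distribution must be nonnegative and sum to 1, got {self.initial_distribution}"
            )


def build_transition_matrix(arm: ArmParameters) -> np.ndarray:
    """Annual 3x3 transition matrix over (GOLD 1-2, GOLD 3-4, death).

    GOLD 1-2 may stay, progress, or die; GOLD 3-4 may stay or die (no
    recovery to GOLD 1-2); death is absorbing.  Every row sums to 1.
    """
    stay12 = 1.0 - arm.progression - arm.mortality_gold12
    stay34 = 1.0 - arm.mortality_gold34
    if stay12 < -1e-12:
        raise ParameterError(
            f"{arm.name}/gold12: transition probabilities sum above 1"
        )
    matrix = np.array(
        [
            [max(stay12, 0.0), arm.progression, arm.mortality_gold12],
            [0.0, stay34, arm.mortality_gold34],
            [0.0, 0.0, 1.0],
        ]
    )
    return matrix


def _case_fatality(arm: ArmParameters, state: str) -> float:
    """Within-cycle probability of dying of a severe AE in ``state``."""
    if not arm.apply_ae_fatality:
        return 0.0
    probs: AEProbs = getattr(arm.ae, state)
    return arm.ae_incidence * probs.severe * arm.severe_ae_fatality


def effective_transition_matrix(arm: ArmParameters) -> np.ndarray:
    """Annual transition matrix with severe-AE case-fatality folded in.

    Severe-AE deaths occur within the cycle before the all-cause transition:
    row_s -> (1 - cf_s) * T[s] + cf_s * e_death for living states s.
    """
    matrix = build_transition_matrix(arm)
    for idx, state in enumerate(LIVING):
        cf = _case_fatality(arm, state)
        matrix[idx] = (1.0 - cf) * matrix[idx]
        matrix[idx, 2] += cf
    return matrix


def cycle_reward(
    occupancy: Sequence[float], arm: ArmParameters
) -> Tuple[float, float, float]:
    """Undiscounted (cost, QALY, life-year) accruals for one cycle.

    For each living state s with occupancy N_s, annual AE probabilities
    (p_mild, p_severe) and AE duration fraction d:

      cost  += N_s (stable_s + p_mild mild_cost_s + p_severe severe_cost_s)
      QALY  += N_s u_s [(1-d) + d (p_mild m_mild + p_severe m_severe
                                   + (1 - p_mild - p_severe))]
      LY    += N_s
    """
    cost = qaly = life_years = 0.0
    d = arm.ae_duration
    for n, state in zip(occupancy, LIVING):
        if n < 0:
            raise ParameterError(f"negative occupancy in state {state}")
        probs: AEProbs = getattr(arm.ae, state)
        p_mild = arm.ae_incidence * probs.mild
        p_severe = arm.ae_incidence * probs.severe
        costs: StateCosts = getattr(arm.costs, state)
        cost += n * (
            costs.stable + p_mild * costs.mild_ae + p_severe * costs.severe_ae
        )
        u = getattr(arm.utilities, state)
        ae_weight = (
            p_mild * arm.utilities.mild_multiplier
            + p_severe * arm.utilities.severe_multiplier
            + (1.0 - p_mild - p_severe)
        )
        qaly += n * u * ((1.0 - d) + d * ae_weight)
        life_years += n
    return cost, qaly, life_years


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of a cohort run.

    ``frame`` columns: cycle (1..K), start-of-cycle occupancy (gold12,
    gold34, dead), undiscounted cycle cost/qaly/life_years, and their
    discounted counterparts (disc_*).
    """

    arm: str
    cohort_size: float
    frame: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def total_disc_cost(self) -> float:
        return float(self.frame["disc_cost"].sum())

    @property
    def total_disc_qaly(self) -> float:
        return float(self.frame["disc_qaly"].sum())


def run_cohort(arm: ArmParameters, settings: SimulationSettings) -> CohortTrace:
    """Propagate the cohort through K annual cycles and accrue rewards."""
    matrix = effective_transition_matrix(arm)
    occ = np.array(
        [
            settings.cohort_size * settings.initial_distribution[0],
            settings.cohort_size * settings.initial_distribution[1],
            0.0,
        ]
    )
    rate = settings.discount.rate
    rows: List[dict] = []
    for k in range(1, settings.cycles + 1):
        occ_next = occ @ matrix
        basis = 0.5 * (occ + occ_next) if settings.half_cycle_correction else occ
        cost, qaly, life_years = cycle_reward(basis[:2], arm)
        df = discount_factor(rate, k)
        rows.append(
            {
                "cycle": k,
                "gold12": occ[0],
                "gold34": occ[1],
                "dead": occ[2],
                "cost": cost,
                "qaly": qaly,
                "life_years": life_years,
                "disc_cost": cost * df,
                "disc_qaly": qaly * df,
                "disc_life_years": life_years * df,
            }
        )
        occ = occ_next
    return CohortTrace(arm=arm.name, cohort_size=settings.cohort_size,
                       frame=pd.DataFrame(rows))


def summarize(trace: CohortTrace) -> CUAResult:
    """Totals over the trace: discounted cost, QALYs and life years (with the
    undiscounted life years carried alongside)."""
    f = trace.frame
    return CUAResult(
        arm=trace.arm,
        cost=float(f["disc_cost"].sum()),
        qaly=float(f["disc_qaly"].sum()),
        life_years=float(f["disc_life_years"].sum()),
        life_years_undiscounted=float(f["life_years"].sum()),
    )


def compare_arms(
    results: Sequence[CUAResult],
    threshold: WTPThreshold = WTPThreshold(),
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    effect: str = "qaly",
) -> List[IncrementalResult]:
    """Pairwise incremental comparisons between arm results.

    ``effect`` selects the effectiveness measure: "qaly" (cost per
    incremental QALY) or "life_years" (cost per incremental life year).
    Default pairs: every later arm compared against every earlier one, in
    input order.  Each defined ratio gets a WTP category.
    """
    if len(results) < 2:
        raise ValueError("need at least two arm results to compare")
    if effect not in ("qaly", "life_years"):
        raise ValueError(f"unknown effect measure {effect!r}")
    by_arm: Dict[str, CUAResult] = {r.arm: r for r in results}
    if pairs is None:
        labels = [r.arm for r in results]
        pairs = [
            (labels[j], labels[i])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    out: List[IncrementalResult] = []
    for a, b in pairs:
        ra, rb = by_arm[a], by_arm[b]
        eff_a = ra.qaly if effect == "qaly" else ra.life_years
        eff_b = rb.qaly if effect == "qaly" else rb.life_years
        result = icur(
            ra.cost, eff_a, rb.cost, eff_b,
            arm_a=a, arm_b=b,
            effect_label="QALY" if effect == "qaly" else "life year",
        )
        if result.icur is not None:
            result = dataclasses.replace(
                result, wtp_category=classify_wtp(result.icur, threshold)
            )
        out.append(result)
    return out
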