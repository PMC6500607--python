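"""Estimate Markov-model parameters from patient-level trial records.

Cost and utility cells are filled with (weighted) sample means; semiannual
event proportions are converted to annual probabilities under a constant
hazard (P = 1 - e^{-rt}, r = -ln(1-p0)/t0); and post-treatment utilities are
compared across arms with a one-way analysis of covariance using the
baseline utility as covariate (single shared slope).

Mortality and severe-AE case-fatality are not estimable from a one-year
trial; they enter through ``defaults`` and are marked literature-derived in
the report.

All estimators honour the record ``weight`` column (1 for sampled rows,
fractional event probabilities for expectation-mode synthetic data), which
lets a point-mass trial reproduce its generating configuration exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .econ import DiscountSettings, WTPThreshold, annualize
from .markov import (
    AEProbs,
    AESet,
    ArmParameters,
    CostSet,
    StateCosts,
    UtilitySet,
)
from .trial import Cell, TrialConfig

__all__ = [
    "EstimationError",
    "AncovaResult",
    "EstimationReport",
    "estimate_costs",
    "estimate_utilities",
    "estimate_probabilities",
    "fit_arm_parameters",
    "scenario_from_estimate",
]

_STATES = ("gold12", "gold34")

#: defaults for fields a one-year trial cannot identify; mortality and
#: case-fatality have no fallback and must be supplied explicitly
_OPTIONAL_DEFAULTS = {
    "mild_ae_utility_multiplier": 0.85,
    "severe_ae_utility_multiplier": 0.30,
    "ae_duration_years": 0.5 / 12.0,
    "ae_incidence": 1.0,
    "apply_ae_fatality": True,
}
_REQUIRED_DEFAULTS = ("mortality_gold12", "mortality_gold34", "severe_ae_fatality")


class EstimationError(ValueError):
    """Estimation cannot proceed (missing cells or defaults)."""


def _wmean(values: pd.Series, weights: pd.Series) -> float:
    total = float(weights.sum())
    if total == 0:
        return math.nan
    return float((values * weights).sum() / total)


def _patients(records: pd.DataFrame) -> pd.DataFrame:
    """One row per patient with arm and baseline stratum."""
    return (
        records[["patient_id", "arm", "stratum"]]
        .drop_duplicates("patient_id")
        .set_index("patient_id")
    )


def estimate_costs(
    records: pd.DataFrame,
) -> Tuple[Dict[str, Dict[str, Dict[str, float]]], List[str]]:
    """Per-arm, per-state cost estimates.

    Stable annual cost = 2 x mean semiannual stable cost (the windows are
    26 weeks); AE costs are per-episode means, since the engine multiplies
    them by annual AE probabilities.  Returns (estimates, missing-cell
    flags); a missing cell requires a user-supplied value downstream.
    """
    out: Dict[str, Dict[str, Dict[str, float]]] = {}
    missing: List[str] = []
    for (arm, stratum), group in records.groupby(["arm", "stratum"], sort=False):
        cell = out.setdefault(arm, {}).setdefault(stratum, {})
        stable = group[group["record"] == "stable_cost"]
        if stable.empty:
            missing.append(f"{arm}/{stratum}/stable")
            cell["stable"] = math.nan
        else:
            cell["stable"] = 2.0 * _wmean(stable["value"], stable["weight"])
        ae = group[group["record"] == "ae"]
        for severity in ("mild", "severe"):
            sub = ae[ae["severity"] == severity]
            key = f"{severity}_ae"
            if sub.empty or sub["weight"].sum() == 0:
                missing.append(f"{arm}/{stratum}/{key}")
                cell[key] = math.nan
            else:
                cell[key] = _wmean(sub["value"], sub["weight"])
    return out, missing


@dataclass(frozen=True)
class AncovaResult:
    """Covariance-adjusted comparison of post-treatment utility across arms."""

    adjusted_means: Mapping[str, float]
    f_statistic: float
    p_value: float
    covariate_slope: Optional[float]
    grand_baseline_mean: float
    adjusted: bool            # False when the covariate was degenerate
    warning: Optional[str] = None


def _ancova(utilities: pd.DataFrame) -> AncovaResult:
    """One-way ANCOVA of month-6 utility on arm with baseline covariate."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    wide = utilities.pivot_table(
        index=["patient_id", "arm"], columns="when", values="value"
    ).reset_index()
    wide = wide.dropna(subset=["baseline", "month6"])
    grand = float(wide["baseline"].mean())
    arms = list(dict.fromkeys(wide["arm"]))

    if float(wide["baseline"].var(ddof=0)) == 0.0 or len(arms) < 2:
        groups = [wide.loc[wide["arm"] == a, "month6"].to_numpy() for a in arms]
        if len(arms) >= 2 and all(len(g) > 1 for g in groups):
            f_stat, p_val = sps.f_oneway(*groups)
        else:
            f_stat, p_val = math.nan, math.nan
        return AncovaResult(
            adjusted_means={a: float(np.mean(g)) for a, g in zip(arms, groups)},
            f_statistic=float(f_stat),
            p_value=float(p_val),
            covariate_slope=None,
            grand_baseline_mean=grand,
            adjusted=False,
            warning="degenerate baseline covariate; unadjusted comparison reported",
        )

    model = smf.ols("month6 ~ baseline + C(arm)", data=wide).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_stat = float(table.loc["C(arm)", "F"])
    p_val = float(table.loc["C(arm)", "PR(>F)"])
    pred = pd.DataFrame({"arm": arms, "baseline": grand})
    adjusted = dict(zip(arms, map(float, model.predict(pred))))
    return AncovaResult(
        adjusted_means=adjusted,
        f_statistic=f_stat,
        p_value=p_val,
        covariate_slope=float(model.params["baseline"]),
        grand_baseline_mean=grand,
        adjusted=True,
    )


def estimate_utilities(
    records: pd.DataFrame,
) -> Tuple[Dict[str, Dict[str, float]], AncovaResult]:
    """Post-treatment (month 6) cell means as stable-state utilities, plus
    the covariance-adjusted across-arm comparison (strata pooled)."""
    utilities = records[records["record"] == "utility"]
    if utilities.empty:
        raise EstimationError("no utility records present")
    means: Dict[str, Dict[str, float]] = {}
    for (arm, stratum), group in utilities.groupby(["arm", "stratum"], sort=False):
        post = group[group["when"] == "month6"]
        means.setdefault(arm, {})[stratum] = _wmean(post["value"], post["weight"])
    return means, _ancova(utilities)


def estimate_probabilities(
    records: pd.DataFrame,
) -> Tuple[
    Dict[str, Dict[str, Tuple[float, float]]],
    Dict[str, float],
    List[dict],
]:
    """Annual AE probabilities per arm/state and annual progression per arm.

    Semiannual proportions (event weight over observed person-window weight,
    with window presence taken from the stable-cost records) are annualized
    per severity under a constant hazard.  Should the annualized
    mild + severe estimates exceed 1 by sampling noise they are renormalized
    to sum to 1 (logged in the conversion records).  Progression pools both
    windows with the window-2 at-risk weight reduced by window-1 events.
    """
    patients = _patients(records)
    ae_out: Dict[str, Dict[str, Tuple[float, float]]] = {}
    progression: Dict[str, float] = {}
    log: List[dict] = []

    ae = records[records["record"] == "ae"]
    stable = records[records["record"] == "stable_cost"]
    for arm in dict.fromkeys(patients["arm"]):
        ae_out[arm] = {}
        for stratum in _STATES:
            n = int(((patients["arm"] == arm) & (patients["stratum"] == stratum)).sum())
            # observed person-windows (one AE opportunity each)
            windows = stable[(stable["arm"] == arm) & (stable["stratum"] == stratum)]
            denom = float(windows["weight"].sum())
            if n == 0 or denom == 0:
                log.append(dict(arm=arm, quantity=f"ae_{stratum}",
                                note="empty cell", semiannual=math.nan,
                                annual=math.nan))
                ae_out[arm][stratum] = (math.nan, math.nan)
                continue
            annuals = {}
            for severity in ("mild", "severe"):
                sub = ae[(ae["arm"] == arm) & (ae["stratum"] == stratum)
                         & (ae["severity"] == severity)]
                p_semi = float(sub["weight"].sum()) / denom
                annuals[severity] = annualize(min(p_semi, 1.0 - 1e-15))
                log.append(dict(arm=arm, quantity=f"{severity}_ae_{stratum}",
                                semiannual=p_semi, annual=annuals[severity],
                                note=""))
            total = annuals["mild"] + annuals["severe"]
            if total > 1.0:
                annuals = {k: v / total for k, v in annuals.items()}
                log.append(dict(arm=arm, quantity=f"ae_{stratum}",
                                semiannual=math.nan, annual=total,
                                note=f"mild+severe {total:.6f} > 1; renormalized"))
            ae_out[arm][stratum] = (annuals["mild"], annuals["severe"])

    prog = records[records["record"] == "progression"]
    for arm in dict.fromkeys(patients["arm"]):
        ids = patients[(patients["arm"] == arm)
                       & (patients["stratum"] == "gold12")].index
        n = len(ids)
        if n == 0:
            progression[arm] = math.nan
            log.append(dict(arm=arm, quantity="progression", note="empty cell",
                            semiannual=math.nan, annual=math.nan))
            continue
        sub = prog[prog["arm"] == arm]
        w1 = sub[sub["when"] == "w1"].set_index("patient_id")["weight"]
        w1_weights = w1.reindex(ids).fillna(0.0)
        events = float(sub["weight"].sum())
        at_risk = n + float((1.0 - w1_weights).sum())
        p_semi = events / at_risk if at_risk > 0 else math.nan
        progression[arm] = annualize(min(p_semi, 1.0 - 1e-15))
        log.append(dict(arm=arm, quantity="progression", semiannual=p_semi,
                        annual=progression[arm], note=""))

    return ae_out, progression, log


@dataclass(frozen=True)
class EstimationReport:
    """Fitted parameters with their provenance.

    ``cells``: per-cell n/mean/SD table; ``ancova``: the adjusted utility
    comparison; ``conversions``: every semiannual->annual conversion
    performed; ``defaults_used``: fields taken from literature defaults
    rather than the data; ``missing``: empty cells needing user input.
    """

    arms: Mapping[str, ArmParameters]
    cells: pd.DataFrame
    ancova: AncovaResult
    conversions: Tuple[dict, ...]
    defaults_used: Tuple[str, ...]
    missing: Tuple[str, ...]

    def to_text(self) -> str:
        lines = ["Parameter estimation report", "=" * 29, ""]
        for name, arm in self.arms.items():
            lines.append(f"[{name}]")
            lines.append(f"  stable cost gold12/gold34: "
                         f"{arm.costs.gold12.stable:.2f} / {arm.costs.gold34.stable:.2f} Yuan")
            lines.append(f"  utilities gold12/gold34:   "
                         f"{arm.utilities.gold12:.4f} / {arm.utilities.gold34:.4f}")
            lines.append(f"  AE gold12 (mild, severe):  "
                         f"({arm.ae.gold12.mild:.4f}, {arm.ae.gold12.severe:.4f})")
            lines.append(f"  AE gold34 (mild, severe):  "
                         f"({arm.ae.gold34.mild:.4f}, {arm.ae.gold34.severe:.4f})")
            lines.append(f"  progression:               {arm.progression:.4f}")
            lines.append("")
        lines.append(f"ANCOVA arm effect: F = {self.ancova.f_statistic:.4f}, "
                     f"p = {self.ancova.p_value:.4f} "
                     f"({'adjusted' if self.ancova.adjusted else 'unadjusted'})")
        for arm, mean in self.ancova.adjusted_means.items():
            lines.append(f"  adjusted mean {arm}: {mean:.4f}")
        if self.defaults_used:
            lines.append("")
            lines.append("Literature defaults (not estimated from data): "
                         + ", ".join(self.defaults_used))
        if self.missing:
            lines.append("Missing cells requiring user-supplied values: "
                         + ", ".join(self.missing))
        return "\n".join(lines)


def fit_arm_parameters(
    records: pd.DataFrame,
    defaults: Mapping[str, object],
) -> Tuple[Dict[str, ArmParameters], EstimationReport]:
    """Assemble full ArmParameters per arm from the record table.

    ``defaults`` must provide mortality_gold12, mortality_gold34 and
    severe_ae_fatality (unobservable in a one-year trial); the AE utility
    multipliers, AE duration and incidence scaling may be overridden and
    otherwise take the model's standard values.
    """
    for key in _REQUIRED_DEFAULTS:
        if key not in defaults:
            raise EstimationError(f"missing required default {key!r}")
    merged = {**_OPTIONAL_DEFAULTS, **dict(defaults)}

    costs, missing = estimate_costs(records)
    utilities, ancova = estimate_utilities(records)
    ae, progression, log = estimate_probabilities(records)
    if missing:
        raise EstimationError(
            "empty cost cells, supply values or larger data: " + ", ".join(missing)
        )

    from .trial import trial_moments

    arms: Dict[str, ArmParameters] = {}
    for arm in costs:
        arms[arm] = ArmParameters(
            name=arm,
            costs=CostSet(
                gold12=StateCosts(stable=costs[arm]["gold12"]["stable"],
                                  mild_ae=costs[arm]["gold12"]["mild_ae"],
                                  severe_ae=costs[arm]["gold12"]["severe_ae"]),
                gold34=StateCosts(stable=costs[arm]["gold34"]["stable"],
                                  mild_ae=costs[arm]["gold34"]["mild_ae"],
                                  severe_ae=costs[arm]["gold34"]["severe_ae"]),
            ),
            utilities=UtilitySet(
                gold12=utilities[arm]["gold12"],
                gold34=utilities[arm]["gold34"],
                mild_multiplier=float(merged["mild_ae_utility_multiplier"]),
                severe_multiplier=float(merged["severe_ae_utility_multiplier"]),
            ),
            ae=AESet(gold12=AEProbs(*ae[arm]["gold12"]),
                     gold34=AEProbs(*ae[arm]["gold34"])),
            progression=progression[arm],
            mortality_gold12=float(merged["mortality_gold12"]),
            mortality_gold34=float(merged["mortality_gold34"]),
            severe_ae_fatality=float(merged["severe_ae_fatality"]),
            apply_ae_fatality=bool(merged["apply_ae_fatality"]),
            ae_duration=float(merged["ae_duration_years"]),
            ae_incidence=float(merged["ae_incidence"]),
        )

    report = EstimationReport(
        arms=arms,
        cells=trial_moments(records),
        ancova=ancova,
        conversions=tuple(log),
        defaults_used=tuple(sorted(set(_REQUIRED_DEFAULTS) | set(_OPTIONAL_DEFAULTS))),
        missing=tuple(missing),
    )
    return arms, report


def scenario_from_estimate(
    records: pd.DataFrame,
    base: "Scenario",
) -> "Scenario":
    """Scenario whose arm parameters are re-estimated from ``records``.

    Simulation settings, WTP threshold, shared defaults and the
    trial-generating SDs are carried over from ``base``; the fitted means
    and probabilities replace the arm blocks, and enrollment counts come
    from the records.  The result serializes to a parameter file directly
    loadable by the cohort engine.
    """
    from .config import Scenario  # deferred to avoid an import cycle

    first = next(iter(base.arms.values()))
    defaults = {
        "mortality_gold12": first.mortality_gold12,
        "mortality_gold34": first.mortality_gold34,
        "severe_ae_fatality": first.severe_ae_fatality,
        "apply_ae_fatality": first.apply_ae_fatality,
        "mild_ae_utility_multiplier": first.utilities.mild_multiplier,
        "severe_ae_utility_multiplier": first.utilities.severe_multiplier,
        "ae_duration_years": first.ae_duration,
        "ae_incidence": first.ae_incidence,
    }
    arms, report = fit_arm_parameters(records, defaults)

    patients = _patients(records)
    strata = {
        arm: (
            int(((patients["arm"] == arm) & (patients["stratum"] == "gold12")).sum()),
            int(((patients["arm"] == arm) & (patients["stratum"] == "gold34")).sum()),
        )
        for arm in arms
    }
    initial = {
        arm: (n12 / (n12 + n34), n34 / (n12 + n34))
        for arm, (n12, n34) in strata.items()
    }

    cells = report.cells.set_index(["arm", "stratum", "quantity"])

    def cell(arm: str, stratum: str, quantity: str, mean: float) -> Cell:
        try:
            sd = float(cells.loc[(arm, stratum, quantity), "sd"])
        except KeyError:
            sd = 0.0
        return Cell(mean, 0.0 if math.isnan(sd) else sd)

    cost_cells = {
        arm: {
            st: {
                "stable": cell(arm, st, "stable_cost_annual",
                               arms[arm].costs.__getattribute__(st).stable),
                "mild_ae": cell(arm, st, "mild_ae_cost",
                                getattr(arms[arm].costs, st).mild_ae),
                "severe_ae": cell(arm, st, "severe_ae_cost",
                                  getattr(arms[arm].costs, st).severe_ae),
            }
            for st in _STATES
        }
        for arm in arms
    }
    utility_cells = {
        arm: {
            st: {
                visit: cell(arm, st, f"utility_{visit}",
                            float(cells.loc[(arm, st, f"utility_{visit}"), "mean"]))
                for visit in ("baseline", "month3", "month6")
            }
            for st in _STATES
        }
        for arm in arms
    }
    trial_config = TrialConfig(
        strata=strata,
        costs=cost_cells,
        utilities=utility_cells,
        ae_annual={arm: {st: (arms[arm].ae.__getattribute__(st).mild,
                              getattr(arms[arm].ae, st).severe)
                         for st in _STATES}
                   for arm in arms},
        progression_annual={arm: arms[arm].progression for arm in arms},
    )
    return Scenario(
        arms=arms,
        initial_distributions=initial,
        cohort_size=base.cohort_size,
        cycles=base.cycles,
        discount=base.discount,
        half_cycle_correction=base.half_cycle_correction,
        wtp=base.wtp,
        trial=trial_config,
    )
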