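"""One-way (univariate) sensitivity analysis with tornado summaries.

Each sweep perturbs exactly one model parameter over its assigned range
while all others stay at baseline, reruns both arms of a comparison through
the cohort engine, and records the resulting ICUR.  Range rules follow the
evaluation's convention: costs +/-30% of baseline, utilities and
probabilities +/-20% (clamped to [0, 1]), and the discount rate swept over
its absolute recommended band (0-8%).

Because the mild/severe AE probabilities of a state form a unit-sum split,
an AE probability is swept together with its complement (the companion
severity is adjusted to keep the state's total AE probability at baseline),
keeping every grid point a valid parameterization.

The engine is fully deterministic, so repeated runs on identical inputs are
bit-identical, and crossings of willingness-to-pay multiples are located by
linear interpolation between adjacent grid points.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import Scenario, scenario_get, scenario_set
from .econ import IncrementalResult, WTPThreshold
from .markov import compare_arms, run_cohort, summarize

__all__ = [
    "SensitivitySpec",
    "TornadoResult",
    "make_specs",
    "apply_spec",
    "pair_icur",
    "one_way",
    "tornado",
    "find_crossings",
    "tornado_plot",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivitySpec:
    """One parameter sweep: dotted path, baseline and [low, high] bounds.

    ``rule`` records which range rule produced the bounds; ``clamped`` marks
    bounds cut back to the valid domain.  ``complement_path`` names a second
    parameter co-adjusted to keep a probability pair's sum at baseline.
    """

    path: str
    baseline: float
    low: float
    high: float
    rule: str
    clamped: bool = False
    complement_path: Optional[str] = None
    complement_baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.low <= self.baseline <= self.high):
            raise ValueError(
                f"{self.path}: bounds must bracket the baseline, got "
                f"[{self.low}, {self.high}] around {self.baseline}"
            )


def _relative_spec(path: str, baseline: float, fraction: float, rule: str,
                   clamp_unit: bool, **kwargs) -> SensitivitySpec:
    low = baseline * (1.0 - fraction)
    high = baseline * (1.0 + fraction)
    clamped = False
    if clamp_unit:
        if low < 0.0:
            low, clamped = 0.0, True
        if high > 1.0:
            high, clamped = 1.0, True
        if clamped:
            logger.info("sensitivity bounds for %s clamped to [%g, %g]",
                        path, low, high)
    return SensitivitySpec(path=path, baseline=baseline, low=low, high=high,
                           rule=rule, clamped=clamped, **kwargs)


def make_specs(
    scenario: Scenario,
    arms: Optional[Sequence[str]] = None,
    include_discount: bool = True,
) -> List[SensitivitySpec]:
    """Build the standard sweep set: every cost (+/-30%), stable utility
    (+/-20%), AE/transition/mortality probability (+/-20%, clamped), and the
    discount rate over its absolute band."""
    specs: List[SensitivitySpec] = []
    for arm in (arms if arms is not None else scenario.arm_names):
        for state in ("gold12", "gold34"):
            for category in ("stable", "mild_ae", "severe_ae"):
                path = f"{arm}.costs.{state}.{category}"
                specs.append(_relative_spec(path, scenario_get(scenario, path),
                                            0.30, "cost +/-30%", False))
            path = f"{arm}.utilities.{state}"
            specs.append(_relative_spec(path, scenario_get(scenario, path),
                                        0.20, "utility +/-20%", True))
            for severity, other in (("mild", "severe"), ("severe", "mild")):
                path = f"{arm}.ae.{state}.{severity}"
                comp = f"{arm}.ae.{state}.{other}"
                specs.append(_relative_spec(
                    path, scenario_get(scenario, path), 0.20,
                    "probability +/-20%", True,
                    complement_path=comp,
                    complement_baseline=scenario_get(scenario, comp),
                ))
        for field in ("progression", "mortality_gold12", "mortality_gold34",
                      "severe_ae_fatality"):
            path = f"{arm}.{field}"
            specs.append(_relative_spec(path, scenario_get(scenario, path),
                                        0.20, "probability +/-20%", True))
    if include_discount:
        specs.append(SensitivitySpec(
            path="discount.rate",
            baseline=scenario.discount.rate,
            low=scenario.discount.low,
            high=scenario.discount.high,
            rule="discount absolute range",
        ))
    return specs


def apply_spec(scenario: Scenario, spec: SensitivitySpec, value: float) -> Scenario:
    """New scenario with the spec's parameter set to ``value`` (and its
    complement, if any, co-adjusted to preserve the pair total)."""
    if spec.complement_path is None:
        return scenario_set(scenario, spec.path, value)
    total = spec.baseline + spec.complement_baseline
    complement = min(max(total - value, 0.0), 1.0)
    # apply the decreasing member first so the pair never transiently sums >1
    if value <= spec.baseline:
        out = scenario_set(scenario, spec.path, value)
        return scenario_set(out, spec.complement_path, complement)
    out = scenario_set(scenario, spec.complement_path, complement)
    return scenario_set(out, spec.path, value)


def pair_icur(scenario: Scenario, pair: Tuple[str, str]) -> IncrementalResult:
    """Run both arms of (A, B) through the cohort engine and return the
    incremental result of A against B."""
    a, b = pair
    results = [
        summarize(run_cohort(scenario.arms[arm], scenario.settings_for(arm)))
        for arm in (a, b)
    ]
    return compare_arms(results, scenario.wtp, pairs=[(a, b)])[0]


def _grid(spec: SensitivitySpec, size: int) -> np.ndarray:
    """Evaluation grid over [low, high] always containing the exact baseline."""
    if size < 3:
        raise ValueError("grid size must be >= 3")
    half = size // 2
    lower = np.linspace(spec.low, spec.baseline, half + 1)
    upper = np.linspace(spec.baseline, spec.high, size - half)
    return np.concatenate([lower, upper[1:]])


def one_way(
    scenario: Scenario,
    spec: SensitivitySpec,
    pair: Tuple[str, str],
    grid_size: int = 21,
) -> pd.DataFrame:
    """ICUR curve along one parameter's grid.

    Columns: value, icur (NaN where undefined), defined, error (simulation
    failures are recorded per point, not fatal).
    """
    rows = []
    for value in _grid(spec, grid_size):
        row = {"value": float(value), "icur": np.nan, "defined": False, "error": ""}
        try:
            result = pair_icur(apply_spec(scenario, spec, float(value)), pair)
            if result.icur is not None:
                row.update(icur=result.icur, defined=True)
        except Exception as exc:  # recorded, not fatal
            row["error"] = str(exc)
            logger.warning("one-way sweep of %s failed at %g: %s",
                           spec.path, value, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def find_crossings(curve: pd.DataFrame, level: float) -> List[float]:
    """Parameter values where the ICUR curve crosses ``level``, by linear
    interpolation between adjacent defined grid points."""
    values = curve["value"].to_numpy()
    icurs = curve["icur"].to_numpy()
    crossings: List[float] = []
    for i in range(len(values) - 1):
        y0, y1 = icurs[i], icurs[i + 1]
        if np.isnan(y0) or np.isnan(y1):
            continue
        if (y0 - level) == 0.0:
            crossings.append(float(values[i]))
        elif (y0 - level) * (y1 - level) < 0:
            t = (level - y0) / (y1 - y0)
            crossings.append(float(values[i] + t * (values[i + 1] - values[i])))
    return crossings


@dataclass(frozen=True)
class TornadoResult:
    """One-way results for a comparison pair, one row per parameter.

    ``frame`` columns: path, rule, low/baseline/high parameter values, ICUR
    at each bound and at baseline, range (|high - low| ICUR span), crossing
    flags for 1x/2x/3x WTP, and a sign-change/undefined flag.  Rows are
    sorted by range, widest first.
    """

    pair: Tuple[str, str]
    baseline_icur: Optional[float]
    threshold: WTPThreshold
    frame: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def robustly_cost_effective(self) -> bool:
        """True when the baseline and every endpoint ICUR sit below 1x GDP
        (and none are undefined or negative with dominance reversal)."""
        gdp = self.threshold.gdp_per_capita
        cols = self.frame[["icur_low", "icur_high"]].to_numpy().ravel()
        if self.baseline_icur is None or np.isnan(cols).any():
            return False
        return bool((cols < gdp).all() and self.baseline_icur < gdp)


def tornado(
    scenario: Scenario,
    specs: Sequence[SensitivitySpec],
    pair: Tuple[str, str],
    threshold: Optional[WTPThreshold] = None,
) -> TornadoResult:
    """Evaluate every spec at its bounds and summarize the induced ICUR
    ranges; the base parameter object is never mutated."""
    threshold = threshold if threshold is not None else scenario.wtp
    base = pair_icur(scenario, pair)
    base_icur = base.icur
    gdp = threshold.gdp_per_capita

    rows = []
    for spec in specs:
        endpoint_icurs = {}
        for bound_name, bound in (("low", spec.low), ("high", spec.high)):
            try:
                res = pair_icur(apply_spec(scenario, spec, bound), pair)
                endpoint_icurs[bound_name] = res.icur
            except Exception as exc:
                logger.warning("tornado endpoint %s=%g failed: %s",
                               spec.path, bound, exc)
                endpoint_icurs[bound_name] = None
        vals = [v for v in (endpoint_icurs["low"], endpoint_icurs["high"], base_icur)
                if v is not None]
        lo_icur = endpoint_icurs["low"]
        hi_icur = endpoint_icurs["high"]
        span = (abs(hi_icur - lo_icur)
                if lo_icur is not None and hi_icur is not None else np.nan)
        crosses = {
            m: bool(vals and min(vals) <= m * gdp <= max(vals))
            for m in (1, 2, 3)
        }
        sign_change = (
            lo_icur is None or hi_icur is None or base_icur is None
            or min(vals) < 0 <= max(vals)
        )
        rows.append({
            "path": spec.path,
            "rule": spec.rule,
            "low": spec.low,
            "baseline": spec.baseline,
            "high": spec.high,
            "icur_low": np.nan if lo_icur is None else lo_icur,
            "icur_baseline": np.nan if base_icur is None else base_icur,
            "icur_high": np.nan if hi_icur is None else hi_icur,
            "range": span,
            "crosses_1x": crosses[1],
            "crosses_2x": crosses[2],
            "crosses_3x": crosses[3],
            "sign_change_or_undefined": sign_change,
        })
    frame = pd.DataFrame(rows).sort_values(
        "range", ascending=False, kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return TornadoResult(pair=pair, baseline_icur=base_icur,
                         threshold=threshold, frame=frame)


def tornado_plot(result: TornadoResult, path: str | Path, top: int = 15) -> None:
    """Horizontal-bar tornado diagram of the widest-ranging parameters."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.frame.dropna(subset=["range"]).head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(frame) + 1.5))
    lows = frame[["icur_low", "icur_high"]].min(axis=1)
    highs = frame[["icur_low", "icur_high"]].max(axis=1)
    ax.barh(frame["path"], highs - lows, left=lows, color="#4878d0")
    if result.baseline_icur is not None:
        ax.axvline(result.baseline_icur, color="black", lw=1, label="baseline ICUR")
    gdp = result.threshold.gdp_per_capita
    for m, style in ((1, "--"), (3, ":")):
        ax.axvline(m * gdp, color="crimson", lw=1, ls=style, label=f"{m}x GDP")
    ax.set_xlabel(f"ICUR, {result.pair[0]} vs {result.pair[1]} (Yuan/QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
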