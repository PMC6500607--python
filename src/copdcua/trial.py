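"""Synthetic three-arm trial generator.

Emulates the patient-level structure the analysis assumes: three treatment
arms (Western medicine, TCM, combined; 79/79/78 patients), a fixed GOLD
stratum split per arm, SF-6D utilities at baseline / month 3 / month 6,
semiannual stable-period costs, and acute-exacerbation (AE) events with
severity and episode cost over two 26-week observation windows.

Distributions
-------------
* Utilities: normal, moment-matched after truncation to the attainable
  SF-6D band [0.296, 1], so the configured cell mean/SD are the moments of
  the generated values.  Each utility is back-filled to the SF-6D
  classification whose score is nearest (ties to the less severe state), so
  the classification->utility scoring path can be exercised end to end.
* Costs: gamma, moment-matched (cell SDs often exceed means, which rules
  out normal draws without severe truncation distortion).
* AE events: at most one per patient per semiannual window; the semiannual
  mild/severe probabilities are the constant-hazard semiannualization of
  the configured annual values.
* Progression GOLD 1-2 -> 3-4: one semiannual Bernoulli per window while
  still at risk.

``point_mass=True`` switches to expectation mode: every drawn quantity is
replaced by its expectation — costs and utilities at their cell means, and
event rows (AE, progression) emitted with fractional ``weight`` equal to
their per-window probability instead of Bernoulli draws.  Weight-aware
estimators then recover the generating configuration exactly, which makes
the generator usable as its own closed-form oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .econ import semiannualize
from . import sf6d

__all__ = [
    "UTILITY_FLOOR",
    "VISITS",
    "WINDOWS",
    "TrialConfig",
    "generate_trial",
    "trial_moments",
    "write_trial_csv",
    "read_trial_csv",
]

UTILITY_FLOOR = 0.296          # score of the all-worst SF-6D state
VISITS: Tuple[str, ...] = ("baseline", "month3", "month6")
WINDOWS: Tuple[str, ...] = ("w1", "w2")
STRATA: Tuple[str, ...] = ("gold12", "gold34")

RECORD_COLUMNS = [
    "patient_id", "arm", "stratum", "record", "when",
    "severity", "value", "weight",
    "pf", "rl", "sf", "pain", "mh", "vit",
]


@dataclass(frozen=True)
class Cell:
    """Mean/SD of one generating cell."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"SD must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class TrialConfig:
    """Generating configuration for the synthetic trial.

    ``strata`` gives (GOLD 1-2, GOLD 3-4) patient counts per arm; stratum
    assignment is deterministic (stratified), not sampled.  ``costs`` cells
    are keyed [arm][stratum][category] with categories ``stable`` (annual
    Yuan; patients record half per window), ``mild_ae`` and ``severe_ae``
    (per-episode Yuan).  ``utilities`` cells are keyed [arm][stratum][visit].
    ``ae_annual`` holds annual (mild, severe) AE probabilities per
    arm/stratum and ``progression_annual`` the annual GOLD 1-2 -> 3-4
    probability per arm; both are semiannualized for per-window draws.
    """

    strata: Mapping[str, Tuple[int, int]]
    costs: Mapping[str, Mapping[str, Mapping[str, Cell]]]
    utilities: Mapping[str, Mapping[str, Mapping[str, Cell]]]
    ae_annual: Mapping[str, Mapping[str, Tuple[float, float]]]
    progression_annual: Mapping[str, float]
    point_mass: bool = False
    scale: int = 1               # multiplies every stratum count

    def __post_init__(self) -> None:
        for arm, (n12, n34) in self.strata.items():
            if n12 < 0 or n34 < 0 or n12 + n34 <= 0:
                raise ValueError(f"arm {arm}: invalid stratum counts ({n12}, {n34})")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    @property
    def arms(self) -> Tuple[str, ...]:
        return tuple(self.strata)

    def arm_size(self, arm: str) -> int:
        n12, n34 = self.strata[arm]
        return self.scale * (n12 + n34)

    def scaled(self, factor: int) -> "TrialConfig":
        return replace(self, scale=self.scale * factor)


# ---------------------------------------------------------------------------
# moment-matched samplers
# ---------------------------------------------------------------------------

def _truncnorm_spec(cell: Cell, lo: float = UTILITY_FLOOR, hi: float = 1.0):
    """(mu, sigma) of the untruncated normal whose [lo, hi]-truncation has
    the cell's mean and SD; None for a point mass."""
    if cell.sd == 0.0:
        return None
    if not (lo < cell.mean < hi):
        raise ValueError(f"cell mean {cell.mean} outside the open interval ({lo}, {hi})")

    def gap(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - cell.mean, math.sqrt(float(v)) - cell.sd]

    sol = optimize.fsolve(gap, [cell.mean, math.log(cell.sd)], full_output=False)
    mu, sigma = float(sol[0]), math.exp(float(sol[1]))
    return mu, sigma


def _draw_utilities(cell: Cell, size: int, rng: np.random.Generator,
                    point_mass: bool) -> np.ndarray:
    if point_mass or cell.sd == 0.0:
        return np.full(size, min(max(cell.mean, UTILITY_FLOOR), 1.0))
    mu, sigma = _truncnorm_spec(cell)
    a, b = (UTILITY_FLOOR - mu) / sigma, (1.0 - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _draw_costs(cell: Cell, size: int, rng: np.random.Generator,
                point_mass: bool) -> np.ndarray:
    if point_mass or cell.sd == 0.0 or cell.mean == 0.0:
        return np.full(size, max(cell.mean, 0.0))
    shape = (cell.mean / cell.sd) ** 2
    scale = cell.sd**2 / cell.mean
    return rng.gamma(shape, scale, size=size)


# ---------------------------------------------------------------------------
# nearest-score SF-6D back-fill
# ---------------------------------------------------------------------------

def nearest_classifications(utilities: np.ndarray) -> List[sf6d.SF6DClassification]:
    """Batched nearest-achievable-score search; identical tie-breaking to
    :func:`copdcua.sf6d.nearest_classification` (same shared score table)."""
    scores, classes = sf6d.score_table()
    idx = np.searchsorted(scores, utilities)
    out = []
    for u, i in zip(utilities, idx):
        candidates = sorted(
            {max(i - 1, 0), min(i, len(scores) - 1)},
            key=lambda j: (abs(scores[j] - u),
                           sum(classes[j].levels()), classes[j].levels()),
        )
        out.append(classes[candidates[0]])
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_trial(config: TrialConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate the long-format patient-record table.

    One row per observation: ``record`` is "utility" (with visit in ``when``
    and the back-filled SF-6D levels), "stable_cost" (semiannual Yuan per
    window), "ae" (episode with severity and cost per window), or
    "progression" (GOLD 1-2 -> 3-4 event per window).  ``weight`` is 1 for
    sampled rows and the event probability in expectation mode.
    """
    rng = np.random.default_rng(seed)
    rows: List[tuple] = []

    for arm in config.arms:
        n12, n34 = (config.scale * n for n in config.strata[arm])
        patients = [(f"{arm}-{i+1:05d}", "gold12" if i < n12 else "gold34")
                    for i in range(n12 + n34)]
        by_stratum = {
            s: [pid for pid, st in patients if st == s] for s in STRATA
        }
        for stratum, ids in by_stratum.items():
            n = len(ids)
            if n == 0:
                continue
            # utilities with SF-6D back-fill
            for visit in VISITS:
                cell = config.utilities[arm][stratum][visit]
                values = _draw_utilities(cell, n, rng, config.point_mass)
                classes = nearest_classifications(values)
                for pid, u, cls in zip(ids, values, classes):
                    rows.append((pid, arm, stratum, "utility", visit, "",
                                 float(u), 1.0, *cls.levels()))
            # semiannual stable costs (half the annual cell mean per window)
            annual = config.costs[arm][stratum]["stable"]
            semi = Cell(annual.mean / 2.0, annual.sd / 2.0)
            for window in WINDOWS:
                values = _draw_costs(semi, n, rng, config.point_mass)
                for pid, v in zip(ids, values):
                    rows.append((pid, arm, stratum, "stable_cost", window, "",
                                 float(v), 1.0, *(("",) * 6)))
            # AE events
            mild_annual, severe_annual = config.ae_annual[arm][stratum]
            p_mild = semiannualize(mild_annual)
            p_severe = semiannualize(severe_annual)
            cost_cells = {
                "mild": config.costs[arm][stratum]["mild_ae"],
                "severe": config.costs[arm][stratum]["severe_ae"],
            }
            for window in WINDOWS:
                if config.point_mass:
                    for severity, p in (("mild", p_mild), ("severe", p_severe)):
                        for pid in ids:
                            rows.append((pid, arm, stratum, "ae", window,
                                         severity, cost_cells[severity].mean,
                                         p, *(("",) * 6)))
                else:
                    u = rng.random(n)
                    severities = np.where(
                        u < p_mild, "mild",
                        np.where(u < p_mild + p_severe, "severe", "none"),
                    )
                    for severity in ("mild", "severe"):
                        mask = severities == severity
                        k = int(mask.sum())
                        if k == 0:
                            continue
                        costs = _draw_costs(cost_cells[severity], k, rng, False)
                        for pid, c in zip(np.asarray(ids)[mask], costs):
                            rows.append((pid, arm, stratum, "ae", window,
                                         severity, float(c), 1.0, *(("",) * 6)))
            # progression (GOLD 1-2 only)
            if stratum == "gold12":
                p = semiannualize(config.progression_annual[arm])
                if config.point_mass:
                    for window, w in (("w1", p), ("w2", (1.0 - p) * p)):
                        for pid in ids:
                            rows.append((pid, arm, stratum, "progression",
                                         window, "", math.nan, w, *(("",) * 6)))
                else:
                    at_risk = np.ones(n, dtype=bool)
                    for window in WINDOWS:
                        events = at_risk & (rng.random(n) < p)
                        for pid in np.asarray(ids)[events]:
                            rows.append((pid, arm, stratum, "progression",
                                         window, "", math.nan, 1.0, *(("",) * 6)))
                        at_risk &= ~events

    frame = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    for col in ("pf", "rl", "sf", "pain", "mh", "vit"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce").astype("Int64")
    return frame


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> Tuple[float, float]:
    total = weights.sum()
    mean = float(np.sum(weights * values) / total)
    if len(values) < 2:
        return mean, math.nan
    var = float(np.sum(weights * (values - mean) ** 2) / total)
    # unbiased correction for unit weights; harmless for expectation mode
    if np.allclose(weights, 1.0):
        var = var * len(values) / (len(values) - 1)
    return mean, math.sqrt(var)


def trial_moments(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell sample means/SDs shaped for side-by-side comparison with the
    generating configuration.

    Quantities: ``utility_<visit>``, ``stable_cost_annual`` (per-patient
    window sums), ``mild_ae_cost`` and ``severe_ae_cost`` (per episode).
    Empty cells are flagged with n = 0 rather than dropped.
    """
    out: List[dict] = []

    def push(arm, stratum, quantity, values, weights):
        values = np.asarray(values, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if len(values) == 0 or weights.sum() == 0:
            out.append(dict(arm=arm, stratum=stratum, quantity=quantity,
                            n=0, mean=math.nan, sd=math.nan))
            return
        mean, sd = _weighted_mean_sd(values, weights)
        out.append(dict(arm=arm, stratum=stratum, quantity=quantity,
                        n=len(values), mean=mean, sd=sd))

    for (arm, stratum), group in records.groupby(["arm", "stratum"], sort=False):
        utilities = group[group["record"] == "utility"]
        for visit in VISITS:
            sub = utilities[utilities["when"] == visit]
            push(arm, stratum, f"utility_{visit}", sub["value"], sub["weight"])
        stable = group[group["record"] == "stable_cost"]
        annual = stable.groupby("patient_id")["value"].sum()
        push(arm, stratum, "stable_cost_annual", annual.to_numpy(),
             np.ones(len(annual)))
        ae = group[group["record"] == "ae"]
        for severity in ("mild", "severe"):
            sub = ae[ae["severity"] == severity]
            push(arm, stratum, f"{severity}_ae_cost", sub["value"], sub["weight"])
    return pd.DataFrame(out)


def write_trial_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"severity": str, "when": str})
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    frame["severity"] = frame["severity"].fillna("")
    return frame
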