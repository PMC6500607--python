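"""Parameter-file loading, scenario assembly, serialization and manifests.

The parameter file is YAML with one block per treatment arm mirroring the
model's field names: per-state annual costs (mean/sd), per-visit utilities
(mean/sd), annual AE/progression probabilities, shared mortality and AE
settings, simulation controls and the willingness-to-pay threshold.  The
packaged default file carries the published trial's values and is the base
case for every pipeline stage.

Only the cell means feed the Markov engine; the SDs drive the synthetic
trial generator, so one file describes both the cohort model and the
patient-level data-generating process.
"""

from __future__ import annotations

import copy
import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Tuple

import yaml

from .econ import DiscountSettings, WTPThreshold
from .markov import (
    AEProbs,
    AESet,
    ArmParameters,
    CostSet,
    ParameterError,
    SimulationSettings,
    StateCosts,
    UtilitySet,
)
from .trial import Cell, TrialConfig, VISITS

__all__ = [
    "Scenario",
    "SchemaError",
    "default_params_path",
    "load_parameters",
    "save_parameters",
    "scenario_get",
    "scenario_set",
    "config_digest",
    "RunManifest",
    "write_manifest",
]

_STATES = ("gold12", "gold34")
_COST_CATEGORIES = ("stable", "mild_ae", "severe_ae")


class SchemaError(ValueError):
    """Parameter file violates the expected schema."""


def default_params_path() -> Path:
    return Path(resources.files("copdcua") / "data" / "default_params.yaml")


@dataclass(frozen=True)
class Scenario:
    """Everything needed to run the full pipeline: per-arm model parameters,
    per-arm initial state splits (trial enrollment), simulation controls,
    the WTP threshold, and the trial-generating configuration."""

    arms: Mapping[str, ArmParameters]
    initial_distributions: Mapping[str, Tuple[float, float]]
    cohort_size: float
    cycles: int
    discount: DiscountSettings
    half_cycle_correction: bool
    wtp: WTPThreshold
    trial: TrialConfig

    def settings_for(self, arm: str) -> SimulationSettings:
        return SimulationSettings(
            cohort_size=self.cohort_size,
            cycles=self.cycles,
            discount=self.discount,
            initial_distribution=self.initial_distributions[arm],
            half_cycle_correction=self.half_cycle_correction,
        )

    @property
    def arm_names(self) -> Tuple[str, ...]:
        return tuple(self.arms)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _require(mapping: Any, keys: Tuple[str, ...], where: str) -> None:
    if not isinstance(mapping, dict):
        raise SchemaError(f"{where}: expected a mapping")
    unknown = set(mapping) - set(keys)
    if unknown:
        raise SchemaError(f"{where}: unknown keys {sorted(unknown)}")
    missing = set(keys) - set(mapping)
    if missing:
        raise SchemaError(f"{where}: missing keys {sorted(missing)}")


def _number(value: Any, where: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise SchemaError(f"{where}: expected a number, got {value!r}")
    return float(value)


def _cell(raw: Any, where: str) -> Cell:
    _require(raw, ("mean", "sd"), where)
    try:
        return Cell(_number(raw["mean"], f"{where}.mean"),
                    _number(raw["sd"], f"{where}.sd"))
    except ValueError as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def load_parameters(path: Optional[str | Path] = None) -> Scenario:
    """Load and validate a parameter file (the bundled default when ``path``
    is None).  Unknown or missing keys are rejected with their location;
    parameter-range violations name the offending field."""
    path = Path(path) if path is not None else default_params_path()
    with open(path) as handle:
        raw = yaml.safe_load(handle)

    _require(raw, ("schema", "settings", "wtp", "shared", "arms"), str(path))
    if raw["schema"] != 1:
        raise SchemaError(f"{path}: unrecognized schema version {raw['schema']!r}")

    s = raw["settings"]
    _require(s, ("cohort_size", "cycles", "discount_rate", "discount_low",
                 "discount_high", "half_cycle_correction"), "settings")
    discount = DiscountSettings(
        rate=_number(s["discount_rate"], "settings.discount_rate"),
        low=_number(s["discount_low"], "settings.discount_low"),
        high=_number(s["discount_high"], "settings.discount_high"),
    )

    _require(raw["wtp"], ("gdp_per_capita",), "wtp")
    wtp = WTPThreshold(_number(raw["wtp"]["gdp_per_capita"], "wtp.gdp_per_capita"))

    sh = raw["shared"]
    _require(sh, ("mortality_gold12", "mortality_gold34", "severe_ae_fatality",
                  "apply_ae_fatality", "mild_ae_utility_multiplier",
                  "severe_ae_utility_multiplier", "ae_duration_years",
                  "ae_incidence"), "shared")

    arms: Dict[str, ArmParameters] = {}
    initial: Dict[str, Tuple[float, float]] = {}
    strata: Dict[str, Tuple[int, int]] = {}
    cost_cells: Dict[str, Dict[str, Dict[str, Cell]]] = {}
    utility_cells: Dict[str, Dict[str, Dict[str, Cell]]] = {}
    ae_annual: Dict[str, Dict[str, Tuple[float, float]]] = {}
    progression: Dict[str, float] = {}

    if not isinstance(raw["arms"], dict) or not raw["arms"]:
        raise SchemaError("arms: expected at least one arm block")

    for arm_name, block in raw["arms"].items():
        where = f"arms.{arm_name}"
        _require(block, ("enrolled_gold12", "enrolled_gold34", "costs",
                         "utilities", "probabilities"), where)
        n12 = int(_number(block["enrolled_gold12"], f"{where}.enrolled_gold12"))
        n34 = int(_number(block["enrolled_gold34"], f"{where}.enrolled_gold34"))
        strata[arm_name] = (n12, n34)
        total = n12 + n34
        if total <= 0:
            raise SchemaError(f"{where}: enrollment must be positive")
        initial[arm_name] = (n12 / total, n34 / total)

        _require(block["costs"], _STATES, f"{where}.costs")
        cost_cells[arm_name] = {}
        for state in _STATES:
            _require(block["costs"][state], _COST_CATEGORIES, f"{where}.costs.{state}")
            cost_cells[arm_name][state] = {
                cat: _cell(block["costs"][state][cat], f"{where}.costs.{state}.{cat}")
                for cat in _COST_CATEGORIES
            }

        _require(block["utilities"], _STATES, f"{where}.utilities")
        utility_cells[arm_name] = {}
        for state in _STATES:
            _require(block["utilities"][state], ("baseline", "month6"),
                     f"{where}.utilities.{state}")
            cells = {
                visit: _cell(block["utilities"][state][visit],
                             f"{where}.utilities.{state}.{visit}")
                for visit in ("baseline", "month6")
            }
            # month-3 visit: interpolated midpoint of baseline and month 6
            cells["month3"] = Cell(
                (cells["baseline"].mean + cells["month6"].mean) / 2.0,
                (cells["baseline"].sd + cells["month6"].sd) / 2.0,
            )
            utility_cells[arm_name][state] = cells

        p = block["probabilities"]
        _require(p, ("mild_ae_gold12", "severe_ae_gold12", "mild_ae_gold34",
                     "severe_ae_gold34", "progression"), f"{where}.probabilities")
        probs = {k: _number(v, f"{where}.probabilities.{k}") for k, v in p.items()}
        ae_annual[arm_name] = {
            "gold12": (probs["mild_ae_gold12"], probs["severe_ae_gold12"]),
            "gold34": (probs["mild_ae_gold34"], probs["severe_ae_gold34"]),
        }
        progression[arm_name] = probs["progression"]

        try:
            arms[arm_name] = ArmParameters(
                name=arm_name,
                costs=CostSet(
                    gold12=StateCosts(**{c: cost_cells[arm_name]["gold12"][c].mean
                                         for c in _COST_CATEGORIES}),
                    gold34=StateCosts(**{c: cost_cells[arm_name]["gold34"][c].mean
                                         for c in _COST_CATEGORIES}),
                ),
                utilities=UtilitySet(
                    gold12=utility_cells[arm_name]["gold12"]["month6"].mean,
                    gold34=utility_cells[arm_name]["gold34"]["month6"].mean,
                    mild_multiplier=_number(sh["mild_ae_utility_multiplier"],
                                            "shared.mild_ae_utility_multiplier"),
                    severe_multiplier=_number(sh["severe_ae_utility_multiplier"],
                                              "shared.severe_ae_utility_multiplier"),
                ),
                ae=AESet(
                    gold12=AEProbs(*ae_annual[arm_name]["gold12"]),
                    gold34=AEProbs(*ae_annual[arm_name]["gold34"]),
                ),
                progression=progression[arm_name],
                mortality_gold12=_number(sh["mortality_gold12"], "shared.mortality_gold12"),
                mortality_gold34=_number(sh["mortality_gold34"], "shared.mortality_gold34"),
                severe_ae_fatality=_number(sh["severe_ae_fatality"], "shared.severe_ae_fatality"),
                apply_ae_fatality=bool(sh["apply_ae_fatality"]),
                ae_duration=_number(sh["ae_duration_years"], "shared.ae_duration_years"),
                ae_incidence=_number(sh["ae_incidence"], "shared.ae_incidence"),
            )
        except ParameterError as exc:
            raise SchemaError(f"{where}: {exc}") from exc

    trial_config = TrialConfig(
        strata=strata,
        costs=cost_cells,
        utilities=utility_cells,
        ae_annual=ae_annual,
        progression_annual=progression,
    )

    return Scenario(
        arms=arms,
        initial_distributions=initial,
        cohort_size=_number(s["cohort_size"], "settings.cohort_size"),
        cycles=int(_number(s["cycles"], "settings.cycles")),
        discount=discount,
        half_cycle_correction=bool(s["half_cycle_correction"]),
        wtp=wtp,
        trial=trial_config,
    )


# ---------------------------------------------------------------------------
# canonical serialization
# ---------------------------------------------------------------------------

def _scenario_to_raw(scenario: Scenario) -> Dict[str, Any]:
    first = next(iter(scenario.arms.values()))
    raw: Dict[str, Any] = {
        "schema": 1,
        "settings": {
            "cohort_size": scenario.cohort_size,
            "cycles": scenario.cycles,
            "discount_rate": scenario.discount.rate,
            "discount_low": scenario.discount.low,
            "discount_high": scenario.discount.high,
            "half_cycle_correction": scenario.half_cycle_correction,
        },
        "wtp": {"gdp_per_capita": scenario.wtp.gdp_per_capita},
        "shared": {
            "mortality_gold12": first.mortality_gold12,
            "mortality_gold34": first.mortality_gold34,
            "severe_ae_fatality": first.severe_ae_fatality,
            "apply_ae_fatality": first.apply_ae_fatality,
            "mild_ae_utility_multiplier": first.utilities.mild_multiplier,
            "severe_ae_utility_multiplier": first.utilities.severe_multiplier,
            "ae_duration_years": first.ae_duration,
            "ae_incidence": first.ae_incidence,
        },
        "arms": {},
    }
    for name in scenario.arm_names:
        # the ArmParameters are authoritative for means/probabilities (they
        # may have been edited, e.g. by a sensitivity sweep); the trial
        # config supplies the generating SDs and the baseline-visit cells
        arm = scenario.arms[name]
        n12, n34 = scenario.trial.strata[name]
        raw["arms"][name] = {
            "enrolled_gold12": n12,
            "enrolled_gold34": n34,
            "costs": {
                state: {
                    cat: {
                        "mean": getattr(getattr(arm.costs, state), cat),
                        "sd": scenario.trial.costs[name][state][cat].sd,
                    }
                    for cat in _COST_CATEGORIES
                }
                for state in _STATES
            },
            "utilities": {
                state: {
                    "baseline": {
                        "mean": scenario.trial.utilities[name][state]["baseline"].mean,
                        "sd": scenario.trial.utilities[name][state]["baseline"].sd,
                    },
                    "month6": {
                        "mean": getattr(arm.utilities, state),
                        "sd": scenario.trial.utilities[name][state]["month6"].sd,
                    },
                }
                for state in _STATES
            },
            "probabilities": {
                "mild_ae_gold12": arm.ae.gold12.mild,
                "severe_ae_gold12": arm.ae.gold12.severe,
                "mild_ae_gold34": arm.ae.gold34.mild,
                "severe_ae_gold34": arm.ae.gold34.severe,
                "progression": arm.progression,
            },
        }
    return raw


def save_parameters(scenario: Scenario, path: str | Path) -> None:
    """Write the scenario in canonical form (stable key order), so that
    save(load(f)) is idempotent byte for byte."""
    with open(path, "w") as handle:
        yaml.safe_dump(_scenario_to_raw(scenario), handle,
                       sort_keys=False, default_flow_style=False)


def config_digest(scenario: Scenario) -> str:
    """SHA-256 of the canonical JSON form; stable under key reordering."""
    blob = json.dumps(_scenario_to_raw(scenario), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# parameter paths (used by the sensitivity sweeps)
# ---------------------------------------------------------------------------

def _walk(obj: Any, parts: List[str]) -> Any:
    for part in parts:
        if isinstance(obj, Mapping):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    return obj


def scenario_get(scenario: Scenario, path: str) -> float:
    """Read a numeric parameter by dotted path.

    Paths: ``<arm>.costs.<state>.<category>``, ``<arm>.utilities.<state>``,
    ``<arm>.ae.<state>.<severity>``, ``<arm>.progression``, and
    ``discount.rate``.
    """
    parts = path.split(".")
    if parts[0] == "discount":
        return _walk(scenario.discount, parts[1:])
    if parts[0] in scenario.arms:
        return _walk(scenario.arms[parts[0]], parts[1:])
    raise KeyError(f"unknown parameter path root {parts[0]!r}")


def _rebuild(obj: Any, parts: List[str], value: Any) -> Any:
    if not parts:
        return value
    head, rest = parts[0], parts[1:]
    if isinstance(obj, Mapping):
        new = dict(obj)
        new[head] = _rebuild(new[head], rest, value)
        return new
    return dataclasses.replace(obj, **{head: _rebuild(getattr(obj, head), rest, value)})


def scenario_set(scenario: Scenario, path: str, value: float) -> Scenario:
    """Return a new Scenario with the parameter at ``path`` replaced; the
    input scenario is never mutated (all containers are rebuilt)."""
    parts = path.split(".")
    if parts[0] == "discount":
        return dataclasses.replace(
            scenario, discount=_rebuild(scenario.discount, parts[1:], value)
        )
    if parts[0] in scenario.arms:
        new_arms = dict(scenario.arms)
        new_arms[parts[0]] = _rebuild(scenario.arms[parts[0]], parts[1:], value)
        return dataclasses.replace(scenario, arms=new_arms)
    raise KeyError(f"unknown parameter path root {parts[0]!r}")


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted once per pipeline run."""

    command: str
    config_digest: str
    seed: Optional[int]
    version: str
    timestamp: str
    outputs: Tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=list)


def write_manifest(
    out_dir: str | Path,
    command: str,
    scenario: Scenario,
    outputs: List[str],
    seed: Optional[int] = None,
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        command=command,
        config_digest=config_digest(scenario),
        seed=seed,
        version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        outputs=tuple(outputs),
    )
    out = Path(out_dir) / "manifest.json"
    out.write_text(manifest.to_json())
    return manifest
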