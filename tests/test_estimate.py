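"""Parameter estimation: cell means, probability conversion, ANCOVA, and
end-to-end recovery of the generating configuration."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from copdcua import estimate, markov, trial
from copdcua.estimate import (
    EstimationError,
    estimate_costs,
    estimate_probabilities,
    estimate_utilities,
    fit_arm_parameters,
    scenario_from_estimate,
)
from conftest import LITERATURE_DEFAULTS


def make_records(rows):
    frame = pd.DataFrame(rows, columns=trial.RECORD_COLUMNS[:8])
    for col in trial.RECORD_COLUMNS[8:]:
        frame[col] = pd.NA
    return frame


def test_stable_cost_annualized_by_doubling():
    rows = [(f"p{i}", "a", "gold12", "stable_cost", w, "", 1499.18, 1.0)
            for i in range(10) for w in ("w1", "w2")]
    rows += [(f"p{i}", "a", "gold12", "utility", "month6", "", 0.7, 1.0)
             for i in range(10)]
    costs, missing = estimate_costs(make_records(rows))
    assert costs["a"]["gold12"]["stable"] == pytest.approx(2998.36, abs=1e-9)
    assert "a/gold12/mild_ae" in missing  # no AE episodes observed


def test_single_episode_cost_is_its_own_mean():
    rows = [("p1", "a", "gold34", "stable_cost", "w1", "", 10.0, 1.0),
            ("p1", "a", "gold34", "ae", "w1", "severe", 8200.0, 1.0)]
    costs, _ = estimate_costs(make_records(rows))
    assert costs["a"]["gold34"]["severe_ae"] == 8200.0


def test_semiannual_ae_proportion_annualized():
    """20 of 100 patients with an AE in one 26-week window: semiannual 0.2,
    annual 1 - 0.8^2 = 0.36."""
    rows = [(f"p{i}", "a", "gold12", "stable_cost", "w1", "", 10.0, 1.0)
            for i in range(100)]
    rows += [(f"p{i}", "a", "gold12", "ae", "w1", "mild", 50.0, 1.0)
             for i in range(20)]
    ae, _, log = estimate_probabilities(make_records(rows))
    mild, severe = ae["a"]["gold12"]
    assert mild == pytest.approx(0.36, abs=1e-12)
    assert severe == 0.0
    entry = next(e for e in log if e["quantity"] == "mild_ae_gold12")
    assert entry["semiannual"] == pytest.approx(0.2)


def test_ae_severity_split_recovered():
    rows = [(f"p{i}", "a", "gold12", "stable_cost", w, "", 10.0, 1.0)
            for i in range(50) for w in ("w1", "w2")]
    # 67 mild and 33 severe episodes over the 100 person-windows
    rows += [(f"p{i%50}", "a", "gold12", "ae", "w1" if i < 50 else "w2",
              "mild" if i < 67 else "severe", 5.0, 1.0) for i in range(100)]
    ae, _, _ = estimate_probabilities(make_records(rows))
    mild, severe = ae["a"]["gold12"]
    # semiannual proportions 0.67/0.33 annualize above the unit sum and are
    # renormalized; the mild:severe odds survive exactly
    assert mild + severe == pytest.approx(1.0, abs=1e-12)
    assert mild / severe == pytest.approx(
        (1 - 0.33**2) / (1 - 0.67**2), rel=1e-9
    )


def test_no_events_zero_probability():
    rows = [("p1", "a", "gold12", "stable_cost", "w1", "", 10.0, 1.0)]
    ae, _, _ = estimate_probabilities(make_records(rows))
    assert ae["a"]["gold12"] == (0.0, 0.0)


def test_ancova_identical_arms_zero_differences():
    rows = []
    for arm in ("a", "b", "c"):
        for i, (x, y) in enumerate([(0.5, 0.6), (0.7, 0.8)]):
            rows.append((f"{arm}{i}", arm, "gold12", "utility", "baseline", "", x, 1.0))
            rows.append((f"{arm}{i}", arm, "gold12", "utility", "month6", "", y, 1.0))
    _, ancova = estimate_utilities(make_records(rows))
    means = list(ancova.adjusted_means.values())
    assert max(means) - min(means) == pytest.approx(0.0, abs=1e-12)


def test_ancova_hand_worked_six_patients():
    """Closed-form one-covariate adjustment: pooled within-group slope
    b = 7/6, adjusted means ybar_i - b (xbar_i - xbar)."""
    data = {
        "a": [(0.5, 0.6), (0.7, 0.8)],
        "b": [(0.4, 0.5), (0.6, 0.9)],
        "c": [(0.6, 0.6), (0.8, 0.7)],
    }
    rows = []
    for arm, points in data.items():
        for i, (x, y) in enumerate(points):
            rows.append((f"{arm}{i}", arm, "gold12", "utility", "baseline", "", x, 1.0))
            rows.append((f"{arm}{i}", arm, "gold12", "utility", "month6", "", y, 1.0))
    _, ancova = estimate_utilities(make_records(rows))
    assert ancova.adjusted
    assert ancova.covariate_slope == pytest.approx(7 / 6, rel=1e-9)
    assert ancova.adjusted_means["a"] == pytest.approx(0.7, abs=1e-9)
    assert ancova.adjusted_means["b"] == pytest.approx(0.7 + 7 / 60, abs=1e-9)
    assert ancova.adjusted_means["c"] == pytest.approx(0.65 - 7 / 60, abs=1e-9)
    assert 0.0 <= ancova.p_value <= 1.0


def test_ancova_degenerate_covariate_falls_back():
    rows = []
    for arm, ys in (("a", [0.5, 0.6]), ("b", [0.7, 0.8])):
        for i, y in enumerate(ys):
            rows.append((f"{arm}{i}", arm, "gold12", "utility", "baseline", "", 0.5, 1.0))
            rows.append((f"{arm}{i}", arm, "gold12", "utility", "month6", "", y, 1.0))
    _, ancova = estimate_utilities(make_records(rows))
    assert not ancova.adjusted
    assert "degenerate" in ancova.warning


def test_missing_mortality_default_is_assembly_error(point_mass_records):
    with pytest.raises(EstimationError, match="mortality_gold34"):
        fit_arm_parameters(point_mass_records,
                           {"mortality_gold12": 0.0286, "severe_ae_fatality": 0.032})


def test_point_mass_recovery_field_by_field(scenario, point_mass_records):
    """Expectation-mode synthetic data reproduces the generating parameters."""
    arms, report = fit_arm_parameters(point_mass_records, LITERATURE_DEFAULTS)
    for name, expected in scenario.arms.items():
        got = arms[name]
        for attr in ("stable", "mild_ae", "severe_ae"):
            for state in ("gold12", "gold34"):
                assert getattr(getattr(got.costs, state), attr) == pytest.approx(
                    getattr(getattr(expected.costs, state), attr), rel=1e-12
                )
        assert got.utilities.gold12 == pytest.approx(expected.utilities.gold12, rel=1e-12)
        assert got.utilities.gold34 == pytest.approx(expected.utilities.gold34, rel=1e-12)
        for state in ("gold12", "gold34"):
            assert getattr(got.ae, state).mild == pytest.approx(
                getattr(expected.ae, state).mild, rel=1e-12)
            assert getattr(got.ae, state).severe == pytest.approx(
                getattr(expected.ae, state).severe, rel=1e-12)
        assert got.progression == pytest.approx(expected.progression, rel=1e-12)
    assert "mortality_gold34" in report.defaults_used


def test_pipeline_equality_on_point_mass_data(scenario, point_mass_records):
    """Estimation -> simulation -> CUA on expectation-mode data matches the
    pipeline run directly on the bundled parameters."""
    fitted = scenario_from_estimate(point_mass_records, scenario)
    for name in scenario.arm_names:
        direct = markov.summarize(
            markov.run_cohort(scenario.arms[name], scenario.settings_for(name)))
        refit = markov.summarize(
            markov.run_cohort(fitted.arms[name], fitted.settings_for(name)))
        assert refit.cost == pytest.approx(direct.cost, rel=1e-9)
        assert refit.qaly == pytest.approx(direct.qaly, rel=1e-9)
        assert refit.life_years == pytest.approx(direct.life_years, rel=1e-9)


def test_stochastic_estimates_tighten_with_sample_size(scenario):
    """Utility-cell errors shrink as the trial grows (10x arms)."""
    errors = []
    for scale, seed in ((1, 21), (10, 22)):
        records = trial.generate_trial(scenario.trial.scaled(scale), seed=seed)
        arms, _ = fit_arm_parameters(records, LITERATURE_DEFAULTS)
        errs = [
            abs(getattr(arms[name].utilities, state)
                - getattr(scenario.arms[name].utilities, state))
            for name in scenario.arm_names for state in ("gold12", "gold34")
        ]
        errors.append(np.mean(errs))
    assert errors[1] < errors[0]
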