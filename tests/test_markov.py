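"""Cohort engine: transition structure, reward accrual, and oracles."""

import dataclasses

import numpy as np
import pytest

from copdcua.econ import CUAResult, DiscountSettings, WTPThreshold
from copdcua.markov import (
    AEProbs,
    AESet,
    ArmParameters,
    CostSet,
    ParameterError,
    SimulationSettings,
    StateCosts,
    UtilitySet,
    build_transition_matrix,
    compare_arms,
    cycle_reward,
    effective_transition_matrix,
    run_cohort,
    summarize,
)
from conftest import REFERENCE_TOTALS


def make_arm(**overrides) -> ArmParameters:
    base = dict(
        name="test",
        costs=CostSet(StateCosts(0.0, 0.0, 0.0), StateCosts(0.0, 0.0, 0.0)),
        utilities=UtilitySet(1.0, 1.0),
        ae=AESet(AEProbs(0.0, 0.0), AEProbs(0.0, 0.0)),
        progression=0.0,
        mortality_gold12=0.0,
        mortality_gold34=0.0,
        severe_ae_fatality=0.0,
    )
    base.update(overrides)
    return ArmParameters(**base)


def test_transition_matrix_from_trial_inputs():
    arm = make_arm(progression=0.215, mortality_gold12=0.0286, mortality_gold34=0.126)
    matrix = build_transition_matrix(arm)
    expected = np.array(
        [[0.7564, 0.215, 0.0286], [0.0, 0.874, 0.126], [0.0, 0.0, 1.0]]
    )
    np.testing.assert_allclose(matrix, expected, atol=1e-12)
    assert np.allclose(matrix.sum(axis=1), 1.0, atol=1e-12)


def test_transition_matrix_identity_when_static():
    matrix = build_transition_matrix(make_arm())
    np.testing.assert_allclose(matrix, np.eye(3), atol=0)


def test_transition_row_overflow_names_arm():
    with pytest.raises(ParameterError, match="test"):
        make_arm(progression=0.9, mortality_gold12=0.2)


def test_no_recovery_from_severe_state(scenario):
    for arm in scenario.arms.values():
        matrix = build_transition_matrix(arm)
        assert matrix[1, 0] == 0.0
        assert tuple(matrix[2]) == (0.0, 0.0, 1.0)


def test_cycle_reward_cost_example():
    """One GOLD 1-2 person under the Western-arm cost/AE inputs."""
    arm = make_arm(
        costs=CostSet(StateCosts(2998.36, 7345.33, 17882.67),
                      StateCosts(0.0, 0.0, 0.0)),
        ae=AESet(AEProbs(0.67, 0.33), AEProbs(0.0, 0.0)),
    )
    cost, _, life_years = cycle_reward([1.0, 0.0], arm)
    assert cost == pytest.approx(2998.36 + 0.67 * 7345.33 + 0.33 * 17882.67, abs=1e-9)
    assert life_years == 1.0


def test_cycle_reward_severe_ae_utility_depression():
    arm = make_arm(
        utilities=UtilitySet(0.7, 0.7),
        ae=AESet(AEProbs(0.0, 1.0), AEProbs(0.0, 0.0)),
    )
    d = arm.ae_duration
    _, qaly, _ = cycle_reward([1.0, 0.0], arm)
    assert qaly == pytest.approx(0.7 * (1.0 - d + d * 0.30), abs=1e-12)
    assert qaly == pytest.approx(0.67958, abs=5e-6)


def test_cycle_reward_no_ae_is_pure_occupancy():
    arm = make_arm(utilities=UtilitySet(1.0, 0.5),
                   costs=CostSet(StateCosts(10.0, 999.0, 999.0),
                                 StateCosts(20.0, 999.0, 999.0)))
    cost, qaly, life_years = cycle_reward([3.0, 4.0], arm)
    assert cost == pytest.approx(3 * 10 + 4 * 20, abs=1e-12)
    assert qaly == pytest.approx(3 * 1.0 + 4 * 0.5, abs=1e-12)
    assert life_years == 7.0


def test_run_cohort_static_population():
    arm = make_arm()
    settings = SimulationSettings(cohort_size=100_000, cycles=2,
                                  discount=DiscountSettings(rate=0.0))
    trace = run_cohort(arm, settings)
    totals = summarize(trace)
    assert totals.qaly == pytest.approx(200_000.0, abs=1e-9)
    occ = trace.frame[["gold12", "gold34", "dead"]].sum(axis=1)
    np.testing.assert_allclose(occ, 100_000.0, atol=1e-6)


def test_run_cohort_geometric_oracle():
    """Single living state, mortality 0.1, discount 5%: the discounted QALY
    total has the closed form sum_k N0 (1-m)^(k-1) (1+i)^-k."""
    arm = make_arm(mortality_gold34=0.1)
    settings = SimulationSettings(
        cohort_size=100_000, cycles=2, discount=DiscountSettings(rate=0.05),
        initial_distribution=(0.0, 1.0),
    )
    totals = summarize(run_cohort(arm, settings))
    assert totals.qaly == pytest.approx(100_000 / 1.05 + 90_000 / 1.05**2, abs=1e-6)
    assert totals.qaly == pytest.approx(176_870.75, abs=5e-3)


def test_run_cohort_death_absorbing(scenario):
    for name, arm in scenario.arms.items():
        trace = run_cohort(arm, scenario.settings_for(name))
        dead = trace.frame["dead"].to_numpy()
        living = (trace.frame["gold12"] + trace.frame["gold34"]).to_numpy()
        assert (np.diff(dead) >= -1e-9).all()
        assert (np.diff(living) <= 1e-9).all()


def test_matrix_power_equivalence_random_draws():
    rng = np.random.default_rng(42)
    for _ in range(20):
        mort12, prog = rng.uniform(0, 0.4, 2)
        arm = make_arm(
            progression=prog * (1 - mort12),
            mortality_gold12=mort12,
            mortality_gold34=rng.uniform(0, 0.5),
            ae=AESet(AEProbs(*sorted(rng.uniform(0, 0.5, 2))),
                     AEProbs(*sorted(rng.uniform(0, 0.5, 2)))),
            severe_ae_fatality=rng.uniform(0, 0.1),
        )
        settings = SimulationSettings(cohort_size=1000.0, cycles=12,
                                      initial_distribution=(0.6, 0.4))
        trace = run_cohort(arm, settings)
        matrix = effective_transition_matrix(arm)
        occ1 = trace.frame.iloc[0][["gold12", "gold34", "dead"]].to_numpy(float)
        for k in (1, 5, 12):
            row = trace.frame.iloc[k - 1][["gold12", "gold34", "dead"]].to_numpy(float)
            np.testing.assert_allclose(
                row, occ1 @ np.linalg.matrix_power(matrix, k - 1), rtol=1e-10
            )


def test_case_fatality_switch_changes_survival():
    kwargs = dict(ae=AESet(AEProbs(0.5, 0.5), AEProbs(0.5, 0.5)),
                  severe_ae_fatality=0.032, mortality_gold34=0.126)
    on = make_arm(**kwargs)
    off = make_arm(**kwargs, apply_ae_fatality=False)
    settings = SimulationSettings(cohort_size=1000.0, cycles=10,
                                  initial_distribution=(0.0, 1.0))
    assert summarize(run_cohort(on, settings)).life_years < \
        summarize(run_cohort(off, settings)).life_years


def test_half_cycle_correction_bounds_rewards():
    arm = make_arm(mortality_gold34=0.2)
    base = SimulationSettings(cohort_size=1000.0, cycles=10,
                              initial_distribution=(0.0, 1.0))
    corrected = dataclasses.replace(base, half_cycle_correction=True)
    plain = summarize(run_cohort(arm, base))
    half = summarize(run_cohort(arm, corrected))
    # start-of-cycle accrual overstates a shrinking cohort
    assert half.qaly < plain.qaly


def test_discount_monotonicity(scenario):
    name, arm = next(iter(scenario.arms.items()))
    totals = []
    for rate in (0.0, 0.02, 0.05, 0.08):
        settings = dataclasses.replace(
            scenario.settings_for(name),
            discount=DiscountSettings(rate=rate),
        )
        totals.append(summarize(run_cohort(arm, settings)))
    costs = [t.cost for t in totals]
    qalys = [t.qaly for t in totals]
    assert all(a > b for a, b in zip(costs, costs[1:]))
    assert all(a > b for a, b in zip(qalys, qalys[1:]))


def _reference_results():
    return [
        CUAResult(arm=arm, cost=v["cost"], qaly=v["qaly"], life_years=v["life_years"])
        for arm, v in REFERENCE_TOTALS.items()
    ]


def test_compare_arms_reference_qaly():
    results = _reference_results()
    per_qaly = {
        (r.arm_a, r.arm_b): r
        for r in compare_arms(results, WTPThreshold(), effect="qaly")
    }
    cw = per_qaly[("combined", "western")]
    assert round(cw.icur) == 8707
    assert cw.wtp_category == "very cost-effective"


def test_compare_arms_reference_life_years():
    results = _reference_results()
    per_ly = {
        (r.arm_a, r.arm_b): r
        for r in compare_arms(results, WTPThreshold(), effect="life_years")
    }
    assert round(per_ly[("combined", "western")].icur) == 155_833
    assert round(per_ly[("combined", "tcm")].icur) == 27_810


def test_compare_arms_identical_undefined():
    a = CUAResult(arm="a", cost=100.0, qaly=2.0, life_years=3.0)
    b = CUAResult(arm="b", cost=100.0, qaly=2.0, life_years=3.0)
    (res,) = compare_arms([a, b], pairs=[("b", "a")])
    assert res.icur is None and res.wtp_category is None


def test_settings_validation():
    with pytest.raises(ParameterError):
        SimulationSettings(cohort_size=0)
    with pytest.raises(ParameterError):
        SimulationSettings(initial_distribution=(0.7, 0.7))
    with pytest.raises(ParameterError):
        AEProbs(0.7, 0.4)
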