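"""Generate a synthetic three-arm trial and re-estimate the model from it.

Draws patient-level records (236 patients: utilities at three visits,
semiannual stable costs, AE episodes with costs, progression events) from
the bundled generating configuration, then fits arm parameters back from
the records: cell means for costs/utilities, semiannual-to-annual
probability conversion, and the covariance-adjusted utility comparison.
"""

from copdcua import fit_arm_parameters, generate_trial, load_parameters

scenario = load_parameters()
records = generate_trial(scenario.trial, seed=42)
patients = records["patient_id"].nunique()
print(f"generated {patients} patients, {len(records)} records")

defaults = {  # literature-derived fields a one-year trial cannot identify
    "mortality_gold12": 0.0286,
    "mortality_gold34": 0.126,
    "severe_ae_fatality": 0.032,
}
arms, report = fit_arm_parameters(records, defaults)

print()
for name, arm in arms.items():
    ref = scenario.arms[name]
    print(f"{name:>9}: progression {arm.progression:.3f} (generating {ref.progression:.3f}) | "
          f"utility GOLD 1-2 {arm.utilities.gold12:.3f} (generating {ref.utilities.gold12:.3f})")

print()
anc = report.ancova
print(f"ANCOVA on month-6 utility (baseline covariate): "
      f"F = {anc.f_statistic:.2f}, p = {anc.p_value:.3f}")
for arm_name, mean in anc.adjusted_means.items():
    print(f"  adjusted mean, {arm_name:>9}: {mean:.3f}")
print()
print("With 236 patients the estimates scatter around the generating values")
print("by sampling noise; rerunning with scenario.trial.scaled(10) tightens")
print("them by about sqrt(10).")
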