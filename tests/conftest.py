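import dataclasses

import pytest

from copdcua import config, trial

#: published cohort totals per 100 000 patients over 40 years, used as given
#: inputs for the incremental worked examples (the evaluation's own engine
#: does not regenerate them; see docs/methods.md)
REFERENCE_TOTALS = {
    "western": dict(cost=13_582_138_466.0, qaly=1_556_961.0, life_years=1_702_773.0),
    "tcm": dict(cost=12_073_904_113.0, qaly=1_618_433.0, life_years=1_616_797.0),
    "combined": dict(cost=14_656_607_371.0, qaly=1_680_364.0, life_years=1_709_668.0),
}

LITERATURE_DEFAULTS = {
    "mortality_gold12": 0.0286,
    "mortality_gold34": 0.126,
    "severe_ae_fatality": 0.032,
}


@pytest.fixture(scope="session")
def scenario():
    return config.load_parameters()


@pytest.fixture(scope="session")
def point_mass_records(scenario):
    cfg = dataclasses.replace(scenario.trial, point_mass=True)
    return trial.generate_trial(cfg, seed=0)
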