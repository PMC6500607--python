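"""SF-6D classification validity, scoring, recoding and QALY arithmetic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copdcua import sf6d
from copdcua.sf6d import (
    LEVELS,
    SF36Response,
    SF6DClassification,
    UtilityModel,
    enumerate_classifications,
    most_flag,
    nearest_classification,
    recode_sf36_to_sf6d,
    score_sf6d,
    utility_to_qaly,
)

classifications = st.builds(
    SF6DClassification,
    **{dim: st.integers(1, top) for dim, top in LEVELS.items()},
)


@pytest.mark.parametrize(
    "levels, expected",
    [
        ((1, 1, 1, 1, 1, 1), False),           # full health
        ((6, 1, 1, 1, 1, 1), True),            # PF at its worst
        ((5, 4, 1, 1, 1, 1), True),            # RL tops out at level 4
        ((5, 3, 4, 5, 4, 4), False),           # severe but nothing at the floor
    ],
)
def test_most_flag(levels, expected):
    assert most_flag(SF6DClassification(*levels)) is expected


@pytest.mark.parametrize(
    "levels, expected",
    [
        ((1, 1, 1, 1, 1, 1), 1.0),
        # worst state: 1 - .111 - .050 - .087 - .167 - .128 - .091 - .070
        ((6, 4, 5, 6, 5, 5), 0.296),
        # mid state without the MOST penalty
        ((2, 3, 2, 3, 2, 3), 0.702),
    ],
)
def test_score_worked_examples(levels, expected):
    assert score_sf6d(SF6DClassification(*levels)) == pytest.approx(expected, abs=1e-12)


def test_invalid_levels_rejected():
    with pytest.raises(ValueError):
        SF6DClassification(7, 1, 1, 1, 1, 1)
    with pytest.raises(ValueError):
        SF6DClassification(1, 5, 1, 1, 1, 1)  # RL has only 4 levels


def test_model_validation():
    with pytest.raises(ValueError):
        UtilityModel(most_penalty=0.1)
    bad = dict(sf6d._DEFAULT_DEDUCTIONS)
    bad["pf"] = (0.0, -0.053)  # wrong arity
    with pytest.raises(ValueError):
        UtilityModel(deductions=bad)


def test_attainable_score_range_by_enumeration():
    """The additive model's decrements are not monotone in level index, so
    the attainable minimum (0.291, at PF6/RL3/SF5/PAIN6/MH5/VIT5) lies below
    the all-worst state's score (0.296)."""
    scores = {cls: score_sf6d(cls) for cls in enumerate_classifications()}
    assert len(scores) == 6 * 4 * 5 * 6 * 5 * 5  # 18000 states
    assert max(scores.values()) == pytest.approx(1.0, abs=1e-12)
    assert min(scores.values()) == pytest.approx(0.291, abs=1e-12)
    assert scores[SF6DClassification(6, 3, 5, 6, 5, 5)] == pytest.approx(0.291, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(classifications)
def test_score_bounds_and_most_penalty(cls):
    score = score_sf6d(cls)
    assert 0.291 - 1e-12 <= score <= 1.0 + 1e-12
    # removing the MOST penalty must give back the plain additive sum
    no_most = UtilityModel(most_penalty=0.0)
    gap = score_sf6d(cls, no_most) - score
    assert gap == pytest.approx(0.070 if most_flag(cls) else 0.0, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(classifications)
def test_worsening_from_full_health_never_raises_score(cls):
    """Any departure from level 1 carries a non-positive decrement."""
    assert score_sf6d(cls) <= score_sf6d(SF6DClassification.best()) + 1e-12


BEST_ANSWERS = dict(q3a=3, q3b=3, q3j=3, q4c=2, q5b=2, q7=1, q8=1,
                    q9b=6, q9e=1, q9f=6, q10=5)
WORST_ANSWERS = dict(q3a=1, q3b=1, q3j=1, q4c=1, q5b=1, q7=6, q8=5,
                     q9b=1, q9e=6, q9f=1, q10=1)


def test_recode_extremes():
    assert recode_sf36_to_sf6d(SF36Response(BEST_ANSWERS)) == SF6DClassification.best()
    assert recode_sf36_to_sf6d(SF36Response(WORST_ANSWERS)) == SF6DClassification.worst()


def test_recode_hand_worked_sheet():
    """One questionnaire recoded by hand against the shipped rule table:
    a little vigorous limitation (PF2), physical-only role limitation (RL2),
    social interference a little of the time (SF2), mild non-interfering...
    pain magnitude 3 with interference 'a little bit' (PAIN3), rarely
    nervous/never blue (MH2), energy some of the time (VIT3)."""
    answers = dict(q3a=2, q3b=3, q3j=3, q4c=1, q5b=2, q7=3, q8=2,
                   q9b=5, q9e=4, q9f=6, q10=4)
    cls = recode_sf36_to_sf6d(SF36Response(answers))
    assert cls == SF6DClassification(2, 2, 2, 3, 2, 3)
    assert score_sf6d(cls) == pytest.approx(0.704, abs=1e-12)


def test_recode_missing_item_named():
    answers = dict(BEST_ANSWERS)
    del answers["q8"]
    with pytest.raises(sf6d.RecodingError, match="q8"):
        recode_sf36_to_sf6d(SF36Response(answers))


def test_recode_ambiguous_patterns_take_less_severe_level():
    # vigorous limited a lot with nothing else -> PF2 (no own level)
    answers = dict(BEST_ANSWERS, q3a=1)
    assert recode_sf36_to_sf6d(SF36Response(answers)).pf == 2
    # pain present but reported as non-interfering -> PAIN2
    answers = dict(BEST_ANSWERS, q7=4)
    assert recode_sf36_to_sf6d(SF36Response(answers)).pain == 2


@pytest.mark.parametrize(
    "utility, years, expected",
    [(1.0, 1.0, 1.0), (0.5, 2.0, 1.0), (0.296, 0.5, 0.148)],
)
def test_utility_to_qaly(utility, years, expected):
    assert utility_to_qaly(utility, years) == pytest.approx(expected, abs=1e-12)


def test_utility_to_qaly_rejects_negative_duration():
    with pytest.raises(ValueError):
        utility_to_qaly(0.5, -1.0)


def test_nearest_classification_roundtrip():
    """Scoring the nearest classification of an achievable score returns
    that score (recode-inverse idempotence)."""
    for cls in (SF6DClassification.best(), SF6DClassification(2, 3, 2, 3, 2, 3),
                SF6DClassification.worst()):
        u = score_sf6d(cls)
        assert score_sf6d(nearest_classification(u)) == pytest.approx(u, abs=1e-9)


def test_csv_roundtrip(tmp_path):
    import pandas as pd

    frame = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2"],
            "visit": ["baseline", "month6", "baseline"],
            "pf": [1, 2, 6], "rl": [1, 2, 4], "sf": [1, 2, 5],
            "pain": [1, 3, 6], "mh": [1, 2, 5], "vit": [1, 3, 5],
        }
    )
    path = tmp_path / "cls.csv"
    frame.to_csv(path, index=False)
    loaded = sf6d.read_classifications_csv(path)
    out = sf6d.write_utilities_csv(loaded, tmp_path / "util.csv")
    assert out["utility"].tolist() == pytest.approx([1.0, 0.704, 0.296], abs=1e-12)
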