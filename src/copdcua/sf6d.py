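"""SF-6D utility scoring and SF-36 recoding.

The SF-6D describes a health state on six dimensions — physical functioning
(PF, 6 levels), role limitation (RL, 4), social functioning (SF, 5), pain
(PAIN, 6), mental health (MH, 5) and vitality (VIT, 5) — and values it with
the UK additive model:

    utility = C + PF + RL + SF + PAIN + MH + VIT + MOST

where C = 1, each term is the (non-positive) decrement for the attained
level, and MOST is an extra penalty applied once if any dimension sits at its
most severe level.  Note the published level decrements are not monotone in
the level index everywhere (e.g. PF3 is a smaller decrement than PF2); this
is a property of the econometric estimates, preserved here verbatim.

An SF-6D classification can be obtained from SF-36 item responses via
:func:`recode_sf36_to_sf6d`, which applies the standard Brazier recoding of
the 11 SF-36 items used by the SF-6D (assuming the standard-recall SF-36
form).  The recoding rule table ships with the package and is editable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "LEVELS",
    "SF6DClassification",
    "UtilityModel",
    "SF36Response",
    "RecodingError",
    "most_flag",
    "score_sf6d",
    "recode_sf36_to_sf6d",
    "utility_to_qaly",
    "enumerate_classifications",
    "nearest_classification",
    "read_classifications_csv",
    "write_utilities_csv",
]

logger = logging.getLogger(__name__)

#: dimension name -> number of levels (level 1 = best health)
LEVELS: Dict[str, int] = {"pf": 6, "rl": 4, "sf": 5, "pain": 6, "mh": 5, "vit": 5}
DIMENSIONS: Tuple[str, ...] = tuple(LEVELS)


@dataclass(frozen=True, order=True)
class SF6DClassification:
    """Six dimension levels for one respondent at one visit (1 = best)."""

    pf: int
    rl: int
    sf: int
    pain: int
    mh: int
    vit: int

    def __post_init__(self) -> None:
        for dim, top in LEVELS.items():
            level = getattr(self, dim)
            if not (isinstance(level, int) and 1 <= level <= top):
                raise ValueError(
                    f"{dim.upper()} level must be an integer in 1..{top}, got {level!r}"
                )

    def levels(self) -> Tuple[int, ...]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)

    @classmethod
    def best(cls) -> "SF6DClassification":
        return cls(1, 1, 1, 1, 1, 1)

    @classmethod
    def worst(cls) -> "SF6DClassification":
        return cls(*(LEVELS[d] for d in DIMENSIONS))


# UK SF-6D additive model: level decrements per dimension (level 1 -> 0.0).
_DEFAULT_DEDUCTIONS: Dict[str, Tuple[float, ...]] = {
    "pf": (0.0, -0.053, -0.011, -0.040, -0.054, -0.111),
    "rl": (0.0, -0.053, -0.055, -0.050),
    "sf": (0.0, -0.055, -0.067, -0.070, -0.087),
    "pain": (0.0, -0.047, -0.025, -0.056, -0.091, -0.167),
    "mh": (0.0, -0.049, -0.042, -0.109, -0.128),
    "vit": (0.0, -0.086, -0.061, -0.054, -0.091),
}


@dataclass(frozen=True)
class UtilityModel:
    """Additive SF-6D valuation: constant + level decrements + MOST penalty."""

    constant: float = 1.0
    deductions: Mapping[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_DEDUCTIONS)
    )
    most_penalty: float = -0.070

    def __post_init__(self) -> None:
        for dim, top in LEVELS.items():
            if dim not in self.deductions:
                raise ValueError(f"utility model missing decrements for {dim.upper()}")
            vals = self.deductions[dim]
            if len(vals) != top:
                raise ValueError(
                    f"{dim.upper()} needs {top} level decrements, got {len(vals)}"
                )
            if vals[0] != 0.0:
                raise ValueError(f"{dim.upper()} level-1 decrement must be 0")
            if any(v > 0 for v in vals):
                raise ValueError(f"{dim.upper()} decrements must be <= 0")
        if self.most_penalty > 0:
            raise ValueError("MOST penalty must be <= 0")


DEFAULT_MODEL = UtilityModel()


def most_flag(cls: SF6DClassification) -> bool:
    """True iff any dimension is at its most severe level (PF=6, RL=4, SF=5,
    PAIN=6, MH=5, VIT=5), which triggers the MOST penalty."""
    return any(getattr(cls, dim) == top for dim, top in LEVELS.items())


def score_sf6d(cls: SF6DClassification, model: UtilityModel = DEFAULT_MODEL) -> float:
    """Utility of an SF-6D state under the additive model."""
    total = model.constant
    for dim in DIMENSIONS:
        total += model.deductions[dim][getattr(cls, dim) - 1]
    if most_flag(cls):
        total += model.most_penalty
    return total


def utility_to_qaly(utility: float, years: float) -> float:
    """QALYs accrued over ``years`` at constant ``utility`` (full health for
    one year = 1 QALY)."""
    if years < 0:
        raise ValueError(f"duration must be nonnegative, got {years}")
    if not (0.0 <= utility <= 1.0):
        raise ValueError(f"utility must lie in [0, 1], got {utility}")
    return utility * years


def enumerate_classifications() -> Iterator[SF6DClassification]:
    """All 6*4*5*6*5*5 = 18000 valid SF-6D states."""
    for combo in itertools.product(*(range(1, LEVELS[d] + 1) for d in DIMENSIONS)):
        yield SF6DClassification(*combo)


# score table memoized for the default model: unique attainable scores
# (rounded to 9 decimals so algebraically equal sums coincide) paired with
# the least severe classification attaining each
_SCORE_TABLE: Optional[Tuple[np.ndarray, list]] = None


def score_table(model: UtilityModel = DEFAULT_MODEL) -> Tuple[np.ndarray, list]:
    global _SCORE_TABLE
    if model is DEFAULT_MODEL and _SCORE_TABLE is not None:
        return _SCORE_TABLE
    best: Dict[float, SF6DClassification] = {}
    for cls in enumerate_classifications():
        score = round(score_sf6d(cls, model), 9)
        cur = best.get(score)
        if cur is None or (sum(cls.levels()), cls.levels()) < (sum(cur.levels()), cur.levels()):
            best[score] = cls
    scores = np.asarray(sorted(best))
    table = (scores, [best[s] for s in scores])
    if model is DEFAULT_MODEL:
        _SCORE_TABLE = table
    return table


def nearest_classification(
    utility: float, model: UtilityModel = DEFAULT_MODEL
) -> SF6DClassification:
    """SF-6D state whose score is closest to ``utility``.

    Ties resolve to the less severe state (smallest level sum, then
    lexicographically smallest levels), so the mapping is deterministic.
    """
    scores, classes = score_table(model)
    i = int(np.searchsorted(scores, utility))
    candidates = sorted(
        {max(i - 1, 0), min(i, len(scores) - 1)},
        key=lambda j: (abs(scores[j] - utility),
                       sum(classes[j].levels()), classes[j].levels()),
    )
    return classes[candidates[0]]


# ---------------------------------------------------------------------------
# SF-36 -> SF-6D recoding (Brazier selection of 11 SF-36 items)
# ---------------------------------------------------------------------------

class RecodingError(ValueError):
    """Raised when a required SF-36 item is missing or out of range."""


@dataclass(frozen=True)
class SF36Response:
    """Answers to the SF-36 items used by the SF-6D, keyed by item id.

    Items (standard SF-36 numbering, standard recall):
      q3a  vigorous activities           1 limited a lot .. 3 not limited
      q3b  moderate activities           1 limited a lot .. 3 not limited
      q3j  bathing or dressing           1 limited a lot .. 3 not limited
      q4c  limited in kind of work (physical causes)    1 yes, 2 no
      q5b  accomplished less (emotional causes)         1 yes, 2 no
      q7   pain magnitude                1 none .. 6 very severe
      q8   pain interference with work   1 not at all .. 5 extremely
      q9b  felt very nervous             1 all of the time .. 6 none
      q9e  had a lot of energy           1 all of the time .. 6 none
      q9f  felt downhearted and blue     1 all of the time .. 6 none
      q10  health interfered with social activities
                                         1 all of the time .. 5 none
    """

    items: Mapping[str, int]
    visit: str = "baseline"


_ITEM_RANGES = {
    "q3a": 3, "q3b": 3, "q3j": 3, "q4c": 2, "q5b": 2,
    "q7": 6, "q8": 5, "q9b": 6, "q9e": 6, "q9f": 6, "q10": 5,
}

#: frequency recode for 6-point "how much of the time" items -> 5 severity levels
_MH_FREQ = {1: 5, 2: 4, 3: 4, 4: 3, 5: 2, 6: 1}
#: vitality: q9e asks about energy (positive), so the scale inverts
_VIT_FREQ = {1: 1, 2: 2, 3: 3, 4: 3, 5: 4, 6: 5}


def _get(resp: SF36Response, item: str) -> int:
    try:
        value = resp.items[item]
    except KeyError:
        raise RecodingError(f"missing required SF-36 item {item!r}") from None
    if value is None or (isinstance(value, float) and value != value):
        raise RecodingError(f"missing required SF-36 item {item!r}")
    value = int(value)
    if not (1 <= value <= _ITEM_RANGES[item]):
        raise RecodingError(
            f"SF-36 item {item!r} answer {value} outside 1..{_ITEM_RANGES[item]}"
        )
    return value


def recode_sf36_to_sf6d(resp: SF36Response) -> SF6DClassification:
    """Deterministic recode of SF-36 answers to an SF-6D classification.

    Worst-first precedence within each dimension; where the instrument leaves
    an answer pattern ambiguous the less severe level is taken (logged).
    """
    q3a, q3b, q3j = _get(resp, "q3a"), _get(resp, "q3b"), _get(resp, "q3j")
    if q3j == 1:
        pf = 6
    elif q3j == 2:
        pf = 5
    elif q3b == 1:
        pf = 4
    elif q3b == 2:
        pf = 3
    elif q3a in (1, 2):
        # "limited a lot in vigorous" has no own SF-6D level; both vigorous
        # limitations map to the less severe level 2
        if q3a == 1:
            logger.info(
                "visit %s: vigorous-only limitation 'a lot' mapped to PF level 2",
                resp.visit,
            )
        pf = 2
    else:
        pf = 1

    phys = _get(resp, "q4c") == 1
    emot = _get(resp, "q5b") == 1
    rl = 4 if (phys and emot) else 3 if emot else 2 if phys else 1

    sf = 6 - _get(resp, "q10")

    q7, q8 = _get(resp, "q7"), _get(resp, "q8")
    if q7 == 1 and q8 == 1:
        pain = 1
    elif q8 == 1:
        # pain present but reported as not interfering: less severe reading
        logger.info(
            "visit %s: pain magnitude %d with no interference mapped to PAIN level 2",
            resp.visit, q7,
        )
        pain = 2
    else:
        pain = q8 + 1

    mh = max(_MH_FREQ[_get(resp, "q9b")], _MH_FREQ[_get(resp, "q9f")])
    vit = _VIT_FREQ[_get(resp, "q9e")]

    return SF6DClassification(pf=pf, rl=rl, sf=sf, pain=pain, mh=mh, vit=vit)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_classifications_csv(path: str | Path) -> pd.DataFrame:
    """Read per-patient per-visit SF-6D classifications.

    Expected columns: patient_id, visit, pf, rl, sf, pain, mh, vit.  A
    ``classification`` object column is appended after validation.
    """
    frame = pd.read_csv(path)
    required = {"patient_id", "visit", *DIMENSIONS}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"classification CSV missing columns: {sorted(missing)}")
    frame = frame.copy()
    frame["classification"] = [
        SF6DClassification(*(int(row[d]) for d in DIMENSIONS))
        for _, row in frame.iterrows()
    ]
    return frame


def write_utilities_csv(
    frame: pd.DataFrame, path: str | Path, model: UtilityModel = DEFAULT_MODEL
) -> pd.DataFrame:
    """Score a classification frame (from :func:`read_classifications_csv`)
    and write (patient_id, visit, utility) to ``path``; returns the frame."""
    out = frame[["patient_id", "visit"]].copy()
    out["utility"] = [score_sf6d(c, model) for c in frame["classification"]]
    out.to_csv(path, index=False)
    return out
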