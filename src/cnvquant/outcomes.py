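"""Categorical clinical outcomes: lesion activity, anatomic and functional
response, and injection-burden class.

Definitions (all configurable where a threshold is involved):

* **activity** — at a follow-up visit the lesion is active if BCVA dropped
  by >= 5 ETDRS letters in the presence of intra- or subretinal fluid, or
  there is a macular hemorrhage, or fluid persists from the previous visit,
  or central macular thickness increased while fluid is present.
* **anatomic response** (baseline vs month 3) — *good* if all fluid has
  resolved or central macular thickness decreased by more than 100 µm;
  *bad* otherwise.  When fluid resolves but the thickness decrease is
  <= 100 µm, resolution takes precedence and the response is good (the
  good-responder definition is disjunctive).
* **functional response** (baseline vs month 12) — *good* on a gain of at
  least 5 ETDRS letters; undefined (patient excluded) without a 12-month
  measurement.
* **burden class** — *regular* with 8 or more injections in the first
  12 months, *extended* with 7 or fewer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

from .protocol import PatientCourse

__all__ = [
    "OutcomeLabels",
    "MissingDataError",
    "assess_activity",
    "classify_anatomic_response",
    "classify_functional_response",
    "classify_burden",
    "label_course",
]

REGULAR_BURDEN_MIN_IVI = 8
ANATOMIC_CMT_DECREASE_UM = 100.0
FUNCTIONAL_GAIN_LETTERS = 5


class MissingDataError(ValueError):
    """A required clinical field is absent."""


class VisitLike(Protocol):
    bcva_letters: int
    cmt_um: float
    irf: bool
    srf: bool
    hemorrhage: bool


@dataclass
class OutcomeLabels:
    anatomic_response: str | None  # "good" | "bad"
    functional_response: str | None  # "good" | "other" | None (no 12-month visit)
    burden_class: str  # "regular" | "extended"
    injection_count: int


def _require(visit: VisitLike, fields: tuple[str, ...]) -> None:
    for name in fields:
        if getattr(visit, name, None) is None:
            raise MissingDataError(f"visit record lacks required field {name!r}")


def assess_activity(visit: VisitLike, previous: VisitLike) -> bool:
    """Neovascular activity at ``visit`` given the ``previous`` visit."""
    for v in (visit, previous):
        _require(v, ("bcva_letters", "cmt_um", "irf", "srf", "hemorrhage"))
    fluid_now = visit.irf or visit.srf
    fluid_prev = previous.irf or previous.srf
    bcva_drop = previous.bcva_letters - visit.bcva_letters >= FUNCTIONAL_GAIN_LETTERS
    cmt_increase = visit.cmt_um > previous.cmt_um
    return bool(
        (bcva_drop and fluid_now)
        or visit.hemorrhage
        or (fluid_now and fluid_prev)
        or (cmt_increase and fluid_now)
    )


def classify_anatomic_response(baseline: VisitLike, month3: VisitLike) -> str:
    """'good' or 'bad' response to the anti-VEGF loading dose."""
    for v in (baseline, month3):
        _require(v, ("cmt_um", "irf", "srf"))
    fluid_resolved = not (month3.irf or month3.srf)
    cmt_decrease = baseline.cmt_um - month3.cmt_um
    return "good" if fluid_resolved or cmt_decrease > ANATOMIC_CMT_DECREASE_UM else "bad"


def classify_functional_response(baseline_bcva: int | None, month12_bcva: int | None) -> str | None:
    """'good' on a >= 5-letter gain at 12 months; None without a 12-month BCVA."""
    if baseline_bcva is None:
        raise MissingDataError("baseline BCVA is required")
    if month12_bcva is None:
        return None
    return "good" if month12_bcva - baseline_bcva >= FUNCTIONAL_GAIN_LETTERS else "other"


def classify_burden(course: PatientCourse, horizon_weeks: int = 52) -> tuple[str, int]:
    """Injection count within the horizon and its burden class."""
    count = sum(1 for v in course.visits if v.injection_given and v.week < horizon_weeks)
    return ("regular" if count >= REGULAR_BURDEN_MIN_IVI else "extended"), count


def label_course(course: PatientCourse, horizon_weeks: int = 52) -> OutcomeLabels:
    """All outcome labels for one simulated patient course.

    Expects the evaluation records produced by the cohort generator under
    ``course.metrics["evaluations"]`` (weeks 0 and 12 required; week 52
    optional, without it the functional response is undefined).
    """
    evaluations = course.metrics.get("evaluations", {})
    if 0 not in evaluations or 12 not in evaluations:
        raise MissingDataError("baseline and month-3 evaluations are required")
    anatomic = classify_anatomic_response(evaluations[0], evaluations[12])
    month12 = evaluations.get(52)
    functional = classify_functional_response(
        evaluations[0].bcva_letters, month12.bcva_letters if month12 is not None else None
    )
    burden, count = classify_burden(course, horizon_weeks)
    return OutcomeLabels(
        anatomic_response=anatomic,
        functional_response=functional,
        burden_class=burden,
        injection_count=count,
    )
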