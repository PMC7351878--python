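"""Treat-and-extend (TAE) visit scheduling and per-patient course simulation.

The regimen: three monthly loading injections, then follow-up visits whose
spacing is extended by a fixed step when the lesion is quiet and shortened
by the same step when it is active, clamped between a floor and a cap.  An
injection is given at every attended visit regardless of activity, so the
injection count equals the visit count within the follow-up horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["TAEProtocol", "VisitRecord", "PatientCourse", "simulate_tae_course"]


@dataclass(frozen=True)
class TAEProtocol:
    """Dosing-schedule parameters, all in weeks.

    Defaults: loading injections at weeks 0/4/8, first TAE interval 8,
    step 2, floor 4, cap 12, horizon 52 — under which an always-inactive
    patient attends weeks 0, 4, 8, 16, 26, 38, 50 and receives 7
    injections in the first year.
    """

    loading_interval_weeks: int = 4
    n_loading: int = 3
    initial_interval_weeks: int = 8
    step_weeks: int = 2
    floor_weeks: int = 4
    cap_weeks: int = 12
    horizon_weeks: int = 52

    def __post_init__(self) -> None:
        if self.step_weeks <= 0:
            raise ValueError("step_weeks must be positive")
        if not (self.floor_weeks <= self.initial_interval_weeks <= self.cap_weeks):
            raise ValueError("need floor <= initial interval <= cap")
        if self.floor_weeks <= 0:
            raise ValueError("floor_weeks must be positive")
        if self.n_loading < 1:
            raise ValueError("need at least one loading injection")
        loading_span = (self.n_loading - 1) * self.loading_interval_weeks
        if self.horizon_weeks < loading_span:
            raise ValueError("horizon shorter than the loading phase")


@dataclass
class VisitRecord:
    """One attended visit with its clinical observations."""

    week: int
    bcva_letters: int
    cmt_um: float
    irf: bool
    srf: bool
    hemorrhage: bool
    injection_given: bool = True
    active: bool = False  # activity assessed at this visit (drives the schedule)


@dataclass
class PatientCourse:
    """Baseline traits plus the ordered visit history of one simulated patient."""

    patient_id: str
    baseline_bcva: int
    baseline_cmt: float
    visits: list[VisitRecord]
    baseline_traits: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)  # visit week -> LesionMetrics
    completed_12m: bool = True

    def __post_init__(self) -> None:
        weeks = [v.week for v in self.visits]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("visit weeks must be strictly increasing")
        for v in self.visits:
            if not (0 <= v.bcva_letters <= 100):
                raise ValueError("BCVA must lie in [0, 100] letters")
            if not v.injection_given:
                raise ValueError("an injection is given at every attended visit")

    @property
    def injection_count(self) -> int:
        return sum(1 for v in self.visits if v.injection_given)


def simulate_tae_course(
    activity_prob_per_visit: Callable[[int], float],
    protocol: TAEProtocol = TAEProtocol(),
    horizon_weeks: int | None = None,
    seed: int = 0,
    patient_id: str = "sim",
    clinical: Callable[[int, bool, VisitRecord | None], dict] | None = None,
) -> PatientCourse:
    """Simulate one patient's visit schedule under the TAE rules.

    ``activity_prob_per_visit`` maps a visit week to the probability that
    the lesion is judged active at that visit; activity is drawn Bernoulli
    with the seeded generator.  During loading the cadence is fixed; from
    the first post-loading visit on, the next interval moves by
    ``step_weeks`` down (active) or up (inactive), clamped to
    [floor, cap].  Only visits strictly before the horizon are returned.

    ``clinical`` optionally supplies the observed BCVA/CMT/fluid fields for
    each visit given (week, active, previous record); by default a minimal
    internally consistent record is produced in which active visits show
    subretinal fluid with a rise in central macular thickness.
    """
    horizon = protocol.horizon_weeks if horizon_weeks is None else horizon_weeks
    loading_span = (protocol.n_loading - 1) * protocol.loading_interval_weeks
    if horizon < loading_span:
        raise ValueError("horizon shorter than the loading phase")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7AE]))

    def default_clinical(week: int, active: bool, prev: VisitRecord | None) -> dict:
        prev_cmt = prev.cmt_um if prev is not None else 380.0
        if active:
            return {
                "bcva_letters": 60,
                "cmt_um": prev_cmt + 40.0,
                "irf": False,
                "srf": True,
                "hemorrhage": False,
            }
        return {
            "bcva_letters": 60,
            "cmt_um": max(prev_cmt - 30.0, 250.0),
            "irf": False,
            "srf": False,
            "hemorrhage": False,
        }

    make_clinical = clinical or default_clinical
    visits: list[VisitRecord] = []
    week = 0
    interval = protocol.initial_interval_weeks
    n_seen = 0
    while week < horizon:
        p = float(activity_prob_per_visit(week))
        if not (0.0 <= p <= 1.0):
            raise ValueError("activity probability must lie in [0, 1]")
        active = bool(rng.random() < p)
        prev = visits[-1] if visits else None
        fields = make_clinical(week, active, prev)
        visits.append(VisitRecord(week=week, active=active, injection_given=True, **fields))
        n_seen += 1
        if n_seen < protocol.n_loading:
            week += protocol.loading_interval_weeks
        else:
            if n_seen > protocol.n_loading:
                # adjust the running interval by the assessed activity
                delta = -protocol.step_weeks if active else protocol.step_weeks
                interval = int(np.clip(interval + delta, protocol.floor_weeks, protocol.cap_weeks))
            week += interval
    return PatientCourse(
        patient_id=patient_id,
        baseline_bcva=visits[0].bcva_letters,
        baseline_cmt=visits[0].cmt_um,
        visits=visits,
    )
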