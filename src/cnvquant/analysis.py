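"""Cohort-level analysis: serial biomarker comparisons, repeatability,
outcome-group contrasts, and per-predictor discrimination models.

Reproduces the standard layout of a treat-and-extend OCT-A study: for each
biomarker (FD, LAC, SA, VD) the baseline / month-3 / month-12 summary with
paired tests against baseline; the ICC of the two consecutive baseline
acquisitions; Mann-Whitney contrasts of baseline biomarkers between outcome
groups; and a univariable logistic model per (biomarker, outcome) with odds
ratio, ROC AUC and DeLong interval.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd

from .outcomes import classify_anatomic_response, classify_burden, classify_functional_response
from .protocol import PatientCourse
from .quantify import BinarizeOptions, quantify_lesion
from .stats import (
    describe,
    fit_binary_glm,
    icc_absolute_agreement,
    paired_location_test,
    rank_sum_test,
)

__all__ = ["quantify_cohort", "label_cohort", "labels_from_frames", "analyze_study"]

BIOMARKERS = ("fd", "lac", "sa_mm2", "vd")

# Odds ratios are reported per these predictor increments (FD in 0.01
# dimensionless units, LAC in 0.01 units, SA per mm^2, VD per 0.01).
OR_UNIT_SCALE = {"fd": 0.01, "lac": 0.01, "sa_mm2": 1.0, "vd": 0.01}


def quantify_cohort(
    courses: list[PatientCourse], options: BinarizeOptions | None = None
) -> pd.DataFrame:
    """Biomarker table: one row per (patient, evaluation week, repeat)."""
    rows = []
    for course in courses:
        images = course.metrics.get("images", {})
        for week in sorted(images):
            for rep, img in enumerate(images[week]):
                m = quantify_lesion(img, options)
                rows.append(
                    {
                        "patient_id": course.patient_id,
                        "week": week,
                        "repeat": rep,
                        "fd": m.fd,
                        "n0": m.n0,
                        "lac": m.lac,
                        "sa_mm2": m.sa_mm2,
                        "vd": m.vd,
                        "fit_r2": m.fit_r2,
                        "flags": ";".join(m.flags),
                    }
                )
    return pd.DataFrame(rows)


def label_cohort(courses: list[PatientCourse], horizon_weeks: int = 52) -> pd.DataFrame:
    """Outcome labels per patient, from the course objects."""
    rows = []
    for course in courses:
        ev = course.metrics["evaluations"]
        anatomic = classify_anatomic_response(ev[0], ev[12])
        m12 = ev.get(52)
        functional = classify_functional_response(
            ev[0].bcva_letters, m12.bcva_letters if m12 is not None else None
        )
        burden, count = classify_burden(course, horizon_weeks)
        rows.append(
            {
                "patient_id": course.patient_id,
                "anatomic_response": anatomic,
                "functional_response": functional if functional is not None else "",
                "burden_class": burden,
                "injection_count": count,
                "completed_12m": course.completed_12m,
                "baseline_bcva": course.baseline_bcva,
            }
        )
    return pd.DataFrame(rows)


def labels_from_frames(
    evaluations: pd.DataFrame, visits: pd.DataFrame, horizon_weeks: int = 52
) -> pd.DataFrame:
    """Outcome labels recomputed from the on-disk cohort tables."""
    rows = []
    for pid, ev in evaluations.groupby("patient_id", sort=True):
        ev = ev.set_index("week")
        if 0 not in ev.index or 12 not in ev.index:
            raise ValueError(f"patient {pid} lacks baseline or month-3 evaluation")
        to_ns = lambda r: SimpleNamespace(  # noqa: E731
            bcva_letters=int(r.bcva_letters),
            cmt_um=float(r.cmt_um),
            irf=bool(r.irf),
            srf=bool(r.srf),
            hemorrhage=bool(getattr(r, "hemorrhage", False)),
        )
        anatomic = classify_anatomic_response(to_ns(ev.loc[0]), to_ns(ev.loc[12]))
        bcva12 = int(ev.loc[52].bcva_letters) if 52 in ev.index else None
        functional = classify_functional_response(int(ev.loc[0].bcva_letters), bcva12)
        v = visits[visits.patient_id == pid]
        count = int(((v.week < horizon_weeks) & v.injection.astype(bool)).sum())
        rows.append(
            {
                "patient_id": pid,
                "anatomic_response": anatomic,
                "functional_response": functional if functional is not None else "",
                "burden_class": "regular" if count >= 8 else "extended",
                "injection_count": count,
                "completed_12m": 52 in ev.index,
                "baseline_bcva": int(ev.loc[0].bcva_letters),
            }
        )
    return pd.DataFrame(rows)


def _paired_block(metrics: pd.DataFrame, week: int) -> dict:
    """Baseline-vs-week paired comparisons for each biomarker."""
    base = metrics[(metrics.week == 0) & (metrics.repeat == 0)].set_index("patient_id")
    follow = metrics[(metrics.week == week) & (metrics.repeat == 0)].set_index("patient_id")
    common = sorted(base.index.intersection(follow.index))
    block: dict = {"n": len(common)}
    for param in BIOMARKERS:
        x = base.loc[common, param].to_numpy(float)
        y = follow.loc[common, param].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        t = paired_location_test(y[ok], x[ok])
        block[param] = {
            "baseline": describe(x[ok]),
            "follow_up": describe(y[ok]),
            "median_change": float(np.median(y[ok] - x[ok])),
            "p_value": t.p_value,
            "test": t.name,
        }
    return block


def analyze_study(metrics: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Full statistical battery; returns a JSON-serializable dict."""
    results: dict = {"n_patients": int(labels.shape[0])}

    # Serial comparisons (baseline -> month 3 on everyone, -> month 12 on
    # completers), mirroring the follow-up biomarker table.
    results["serial"] = {
        "baseline_vs_month3": _paired_block(metrics, 12),
        "baseline_vs_month12": _paired_block(metrics, 52),
    }

    # Repeatability of the two consecutive baseline acquisitions.
    icc_block = {}
    base = metrics[metrics.week == 0]
    wide = base.pivot_table(index="patient_id", columns="repeat", values=list(BIOMARKERS))
    for param in BIOMARKERS:
        tab = wide[param].dropna()
        if tab.shape[1] >= 2 and tab.shape[0] >= 3:
            r = icc_absolute_agreement(tab.to_numpy(float)[:, :2])
            icc_block[param] = {
                "icc": r.estimate,
                "ci": [r.ci_low, r.ci_high],
                "n": r.n_subjects,
            }
    results["icc"] = icc_block

    # Outcome-group contrasts and univariable discrimination models on the
    # baseline biomarkers.
    base0 = (
        metrics[(metrics.week == 0) & (metrics.repeat == 0)]
        .set_index("patient_id")
        .join(labels.set_index("patient_id"), how="inner")
    )
    # Burden is modelled with regular treatment (8+ injections) as the
    # positive class, so denser lesions (higher FD, larger SA) carry odds
    # ratios below 1.
    outcomes = {
        "anatomic_response": ("good", base0.anatomic_response),
        "functional_response": ("good", base0.functional_response),
        "burden_regular": ("regular", base0.burden_class),
    }
    groups_block: dict = {}
    models_block: dict = {}
    for outcome, (positive, series) in outcomes.items():
        defined = series.notna() & (series.astype(str) != "")
        y = (series[defined] == positive).to_numpy(int)
        if np.unique(y).size < 2:
            continue
        groups_block[outcome] = {}
        models_block[outcome] = {}
        for param in BIOMARKERS:
            x = base0.loc[defined, param].to_numpy(float)
            ok = np.isfinite(x)
            xo, yo = x[ok], y[ok]
            if min((yo == 1).sum(), (yo == 0).sum()) == 0:
                continue
            t = rank_sum_test(xo[yo == 1], xo[yo == 0])
            groups_block[outcome][param] = {
                "positive": describe(xo[yo == 1]),
                "negative": describe(xo[yo == 0]),
                "p_value": t.p_value,
                "test": t.name,
            }
            try:
                fit = fit_binary_glm(xo, yo, unit_scale=OR_UNIT_SCALE[param])
            except ValueError:  # e.g. too few observations for a stable fit
                continue
            models_block[outcome][param] = {
                "odds_ratio": fit.odds_ratio,
                "or_ci": list(fit.or_ci),
                "or_unit": OR_UNIT_SCALE[param],
                "auc": fit.auc,
                "auc_ci": list(fit.auc_ci),
                "discrimination": fit.discrimination,
                "separation": fit.separation,
            }
    results["group_comparisons"] = groups_block
    results["models"] = models_block
    results["injections"] = describe(labels.injection_count.to_numpy(float))
    results["share_regular"] = float((labels.burden_class == "regular").mean())
    return results
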