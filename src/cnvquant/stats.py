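"""Statistical layer: repeatability ICC, nonparametric comparisons, binary
GLMs with odds ratios and partial-effect curves, and ROC discrimination.

The repeatability model is the two-way mixed-effects, absolute-agreement,
mean-of-k-raters intraclass correlation ICC(A,k) with k = 2 consecutive
acquisitions; confidence limits follow the F-distribution construction of
McGraw & Wong (1996).  Paired and two-group comparisons use exact
small-sample nulls where feasible.  Discrimination is summarized by the
rank-statistic (Mann-Whitney) AUC with a DeLong confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ICCResult",
    "TestResult",
    "ModelFit",
    "icc_absolute_agreement",
    "paired_location_test",
    "rank_sum_test",
    "fit_binary_glm",
    "roc_curve_auc",
    "describe",
    "restricted_cubic_spline_basis",
]


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    name: str
    n: tuple[int, ...]


@dataclass
class ModelFit:
    """Binary-response GLM summary on the odds-ratio scale."""

    coef: np.ndarray
    coef_ci: np.ndarray  # (p, 2)
    odds_ratio: float
    or_ci: tuple[float, float]
    unit_scale: float
    fitted_prob: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    partial: dict = field(default_factory=dict)  # grid, log_odds, ci_low, ci_high
    separation: bool = False
    discrimination: str = ""


def icc_absolute_agreement(measurements: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,k): two-way mixed effects, absolute agreement, mean of k raters.

    ``measurements`` is an (n subjects x k repeats) table with no missing
    cells, n >= 3.  The point estimate is
    ``(MSR - MSE) / (MSR + (MSC - MSE) / n)`` from the two-way ANOVA mean
    squares; the confidence interval applies the Spearman-Brown step-up to
    the single-rater absolute-agreement F bounds.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an (n x k) table with k >= 2 repeats")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if sst == 0:
        raise ValueError("zero total variance: ICC undefined")

    denom = msr + (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate mean squares: ICC undefined")
    icc_k = (msr - mse) / denom

    # Single-rater absolute-agreement bounds (McGraw-Wong case 2A,1), then
    # Spearman-Brown to the k-rater scale.
    denom1 = msr + (k - 1) * mse + k * (msc - mse) / n
    rho1 = (msr - mse) / denom1 if denom1 != 0 else 0.0
    a = k * rho1 / (n * (1.0 - rho1)) if rho1 < 1.0 else np.inf
    b = 1.0 + k * rho1 * (n - 1.0) / (n * (1.0 - rho1)) if rho1 < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        nu = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, nu)
        f2 = sps.f.ppf(1 - alpha / 2, nu, n - 1)
        lo1 = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi1 = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        step_up = lambda r: k * r / (1.0 + (k - 1) * r)  # noqa: E731
        ci_low, ci_high = step_up(lo1), step_up(hi1)
    else:
        ci_low, ci_high = 1.0, 1.0
    return ICCResult(
        estimate=float(icc_k),
        ci_low=float(min(ci_low, icc_k)),
        ci_high=float(min(max(ci_high, icc_k), 1.0)),
        model=f"two-way mixed, absolute agreement, mean of k={k}",
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n_subjects=n,
        n_raters=k,
    )


def paired_location_test(
    x: np.ndarray, y: np.ndarray, method: str = "wilcoxon_exact", exact_max_n: int = 25
) -> TestResult:
    """Paired two-sided test of equal location: exact Wilcoxon or sign test.

    Zero differences are discarded (the Wilcoxon convention).  The
    signed-rank null is enumerated exactly up to ``exact_max_n`` non-zero
    pairs and approximated normally beyond; the sign test is always the
    exact binomial.  All differences zero yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, name=method, n=(x.size,))
    if method == "sign":
        res = sps.binomtest(int((nz > 0).sum()), nz.size, 0.5)
        return TestResult(
            statistic=float((nz > 0).sum()), p_value=float(res.pvalue), name="sign", n=(nz.size,)
        )
    if method != "wilcoxon_exact":
        raise ValueError(f"unknown method {method!r}")
    mode = "exact" if nz.size <= exact_max_n else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", method=mode)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        name=f"wilcoxon_{mode}",
        n=(nz.size,),
    )


def rank_sum_test(a: np.ndarray, b: np.ndarray, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U: exact for small tie-free groups, else
    the normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    mode = "exact" if (max(a.size, b.size) <= exact_max_n and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mode)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        name=f"mann_whitney_{mode}",
        n=(a.size, b.size),
    )


def restricted_cubic_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural (restricted) cubic spline basis without intercept.

    With m knots the basis has m - 1 columns: the linear term plus m - 2
    nonlinear terms that are linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    m = t.size
    if m < 3:
        raise ValueError("need at least 3 knots")
    denom = t[-1] - t[0]
    cols = [x]
    plus = lambda v: np.clip(v, 0.0, None) ** 3  # noqa: E731
    for j in range(m - 2):
        cols.append(
            (
                plus(x - t[j])
                - plus(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
                + plus(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
            )
            / denom**2
        )
    return np.column_stack(cols)


def _discrimination_band(auc: float) -> str:
    if auc > 0.8:
        return "very good"
    if auc > 0.7:
        return "good"
    if auc > 0.5:
        return "weak"
    return "none"


def fit_binary_glm(
    x: np.ndarray,
    y: np.ndarray,
    unit_scale: float = 1.0,
    smooth_df: int | None = None,
    alpha: float = 0.05,
    grid_size: int = 100,
) -> ModelFit:
    """Logistic GLM of a binary outcome on one predictor.

    The odds ratio is reported per ``unit_scale`` units of the predictor
    with its Wald confidence interval.  With ``smooth_df`` > 1 the
    predictor enters through a restricted cubic spline with
    ``smooth_df + 1`` quantile knots and the partial log-odds function
    (with pointwise CI) is returned alongside; the linear model's OR then
    refers to the leading linear coefficient and is best read from the
    ``smooth_df=None`` fit.  Perfect separation is flagged and the CI
    reported as unbounded rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if np.unique(y).size != 2:
        raise ValueError("both outcome classes must be present")

    if smooth_df is not None and smooth_df > 1:
        qs = np.linspace(5, 95, smooth_df + 1)
        knots = np.percentile(x, qs)
        if np.unique(knots).size != knots.size:
            raise ValueError("degenerate spline knots; predictor too discrete")
        design = restricted_cubic_spline_basis(x, knots)
    else:
        knots = None
        design = x[:, None]
    design = sm.add_constant(design, has_constant="add")

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design, family=sm.families.Binomial())
        try:
            fit = model.fit(maxiter=200)
        except Exception:
            separation = True
            fit = model.fit_regularized(alpha=1e-8, maxiter=500)
    params = np.asarray(fit.params, dtype=float)
    try:
        cov = np.asarray(fit.cov_params(), dtype=float)
        se = np.sqrt(np.diag(cov))
    except Exception:
        cov = np.full((params.size, params.size), np.nan)
        se = np.full(params.size, np.nan)
    if not np.all(np.isfinite(se)) or np.any(np.abs(params) > 50):
        separation = True
    zcrit = sps.norm.ppf(1 - alpha / 2)
    ci = np.column_stack([params - zcrit * se, params + zcrit * se])
    if separation:
        ci = np.column_stack([np.full(params.size, -np.inf), np.full(params.size, np.inf)])

    beta1 = params[1]
    odds_ratio = float(np.exp(beta1 * unit_scale))
    or_ci = (
        float(np.exp(ci[1, 0] * unit_scale)),
        float(np.exp(ci[1, 1] * unit_scale)),
    )
    fitted = np.asarray(fit.predict(design), dtype=float)
    roc = roc_curve_auc(fitted, y)

    partial: dict = {}
    grid = np.linspace(x.min(), x.max(), grid_size)
    gdesign = (
        restricted_cubic_spline_basis(grid, knots) if knots is not None else grid[:, None]
    )
    gdesign = sm.add_constant(gdesign, has_constant="add")
    eta = gdesign @ params
    if np.all(np.isfinite(cov)):
        gse = np.sqrt(np.einsum("ij,jk,ik->i", gdesign, cov, gdesign))
        partial = {
            "grid": grid,
            "log_odds": eta,
            "ci_low": eta - zcrit * gse,
            "ci_high": eta + zcrit * gse,
        }
    else:
        partial = {"grid": grid, "log_odds": eta, "ci_low": None, "ci_high": None}

    return ModelFit(
        coef=params,
        coef_ci=ci,
        odds_ratio=odds_ratio,
        or_ci=or_ci,
        unit_scale=unit_scale,
        fitted_prob=fitted,
        auc=roc["auc"],
        auc_ci=roc["auc_ci"],
        partial=partial,
        separation=separation,
        discrimination=roc["band"],
    )


def roc_curve_auc(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> dict:
    """AUC by the rank (Mann-Whitney) formulation with a DeLong CI.

    Returns a dict with ``auc``, ``auc_ci``, the qualitative discrimination
    ``band`` (> 0.80 very good, 0.70-0.80 good, 0.50-0.70 weak) and the
    ROC ``curve`` (fpr, tpr, thresholds).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)

    # DeLong structural components.
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = (
        (np.var(v10, ddof=1) / pos.size if pos.size > 1 else 0.0)
        + (np.var(v01, ddof=1) / neg.size if neg.size > 1 else 0.0)
    )
    zcrit = sps.norm.ppf(1 - alpha / 2)
    half = zcrit * np.sqrt(var)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return {
        "auc": float(auc),
        "auc_ci": (float(max(auc - half, 0.0)), float(min(auc + half, 1.0))),
        "band": _discrimination_band(float(auc)),
        "curve": (fpr, tpr, thr),
    }


def describe(values: np.ndarray) -> dict:
    """Median, 25th-75th percentiles (linear interpolation) and range."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    return {
        "n": int(v.size),
        "median": float(np.median(v)),
        "p25": float(np.percentile(v, 25)),
        "p75": float(np.percentile(v, 75)),
        "min": float(v.min()),
        "max": float(v.max()),
    }
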