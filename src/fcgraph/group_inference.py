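"""Covariate-adjusted group statistics, effect sizes, and clinical
correlations.

Group differences in AUC-summarised network metrics are tested with a
linear model ``value ~ intercept + group + age + sex`` (the t and p of the
group coefficient; patients-minus-controls direction), corrected across
metrics by Benjamini-Hochberg FDR.  Standardised effect sizes use Hedges' g
(small-sample-corrected Cohen's d) with conventional magnitude labels.
Brain-behaviour relations use partial correlation (residualising both
variables on age and sex).  Demographic sex ratios are compared with a
Pearson chi-square without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: |g| bands for Cohen-style magnitude labels; lower edges inclusive.
COHEN_BANDS = (
    (0.2, "very small"),
    (0.5, "small"),
    (0.8, "medium"),
    (1.2, "large"),
    (2.0, "very large"),
    (np.inf, "huge"),
)


@dataclass
class GroupComparison:
    """Covariate-adjusted two-sample comparison of one metric."""

    metric: str
    t: float
    p: float
    df: int
    direction: int  # sign of the patient-minus-control effect
    q: float = np.nan  # FDR-adjusted p, filled in across a metric family


@dataclass
class EffectSize:
    """Hedges' g with its small-sample correction and a 95% CI."""

    g: float
    j: float
    ci95: tuple[float, float]
    label: str


@dataclass
class PartialCorrelationResult:
    r: float
    p: float
    df: int


def _encode_sex(sex) -> np.ndarray:
    """F -> 0, M -> 1 (numeric input passed through)."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "UOS":
        mapping = {"F": 0.0, "M": 1.0}
        try:
            return np.array([mapping[str(s)] for s in arr])
        except KeyError as err:
            raise ValueError(f"unknown sex code {err}") from err
    return arr.astype(float)


def adjusted_group_ttest(
    values: np.ndarray,
    group: np.ndarray,
    age: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    metric: str = "",
    patient_label: str = "patient",
) -> GroupComparison:
    """Two-sample comparison adjusted for age and sex in one linear model.

    Fits ``value ~ 1 + I(group==patient) + age + sex`` by OLS and reports
    the group coefficient's t statistic and two-sided p-value.  Constant
    covariate columns are dropped (so with no informative covariates the
    test collapses exactly to the classical pooled two-sample t).  The
    direction is the sign of the patient-minus-control adjusted effect.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    n = values.size
    indicator = (group == patient_label).astype(float)
    if indicator.sum() < 3 or (1 - indicator).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    cols = [np.ones(n), indicator]
    for cov in (age, sex):
        if cov is None:
            continue
        c = _encode_sex(cov) if cov is sex else np.asarray(cov, dtype=float)
        if np.ptp(c) > 0:
            cols.append(c)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design: collinear covariate columns")
    coef, _, _, _ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ coef
    df = n - design.shape[1]
    sigma2 = resid @ resid / df
    scale_tol = 1e-12 * float(values @ values) / n
    if sigma2 <= scale_tol or not np.isfinite(sigma2):
        raise ValueError("zero residual variance: t statistic undefined")
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = coef[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    if t == 0:
        p = 1.0
    return GroupComparison(
        metric=metric, t=float(t), p=float(p), df=int(df),
        direction=int(np.sign(coef[1])),
    )


def fdr_bh(
    pvalues, q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (adjusted p-values, rejection flags at ``q_level``).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return p_adj, reject


def hedges_g(x_patients, x_controls) -> EffectSize:
    """Hedges' g: small-sample-corrected standardised mean difference.

    ``g = J * (mean_p - mean_c) / s_pooled`` with
    ``J = 1 - 3 / (4(n_p + n_c) - 9)``; the 95% CI uses the normal
    approximation ``g +/- 1.96 * SE`` with
    ``SE^2 = (n_p + n_c)/(n_p n_c) + g^2 / (2(n_p + n_c - 2))``.
    """
    xp = np.asarray(x_patients, dtype=float)
    xc = np.asarray(x_controls, dtype=float)
    n_p, n_c = xp.size, xc.size
    if n_p < 2 or n_c < 2:
        raise ValueError("need at least 2 observations per group")
    s2 = ((n_p - 1) * xp.var(ddof=1) + (n_c - 1) * xc.var(ddof=1)) / (
        n_p + n_c - 2
    )
    if s2 <= 0:
        raise ValueError("zero pooled standard deviation")
    j = 1.0 - 3.0 / (4.0 * (n_p + n_c) - 9.0)
    g = j * (xp.mean() - xc.mean()) / np.sqrt(s2)
    se = np.sqrt((n_p + n_c) / (n_p * n_c) + g**2 / (2 * (n_p + n_c - 2)))
    ci = (g - 1.96 * se, g + 1.96 * se)
    return EffectSize(g=float(g), j=float(j), ci95=ci, label=cohen_label(g))


def cohen_label(g: float) -> str:
    """Cohen-style magnitude category of |g|; lower band edges inclusive."""
    if not np.isfinite(g):
        raise ValueError("effect size must be finite")
    a = abs(g)
    for upper, label in COHEN_BANDS:
        if a < upper:
            return label
    return "huge"  # pragma: no cover - unreachable (last band is inf)


def partial_correlation(
    x, y, covariates=None
) -> PartialCorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualised on the covariates (with intercept) by
    least squares; r is the Pearson correlation of the residuals and p comes
    from ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2 - k`` covariates,
    two-sided.  With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        design = np.ones((n, 1))
        k = 0
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        k = cov.shape[1]
        design = np.column_stack([np.ones(n), cov])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("singular covariate design")
    if n < k + 4:
        raise ValueError("too few observations for the covariate count")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(df / (1 - r_**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, p=p, df=df)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity
    correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)
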