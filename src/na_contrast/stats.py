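"""Group statistics for ROI sodium-intensity tables.

Thin, explicit wrappers around scipy/statsmodels covering the study's
statistical layer: two-sided unpaired (Welch by default) and paired
t-tests, Benjamini-Hochberg false-discovery-rate control, partial
Pearson correlation controlling for age and sex (residualize-then-
correlate), and ordinary least-squares regression slopes with 95%
confidence half-widths reported in "slope +/- hw" style.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsConfig",
    "TestResult",
    "unpaired_t",
    "paired_t",
    "bh_fdr",
    "partial_pearson",
    "regression_slope",
]


@dataclass(frozen=True)
class StatsConfig:
    """FDR thresholds and covariate set used across test families."""

    fdr_q_primary: float = 0.05
    fdr_q_exploratory: float = 0.2
    covariates: tuple[str, ...] = ("age", "sex")

    def __post_init__(self) -> None:
        for q in (self.fdr_q_primary, self.fdr_q_exploratory):
            if not (0.0 < q < 1.0):
                raise ValueError("FDR q must be in (0, 1)")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n: int
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    q_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must be in [0, 1]")


def unpaired_t(group_a, group_b, pooled: bool = False) -> TestResult:
    """Two-sided unpaired t-test (Welch by default, pooled optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n=a.size + b.size,
        estimate=float(a.mean() - b.mean()),
    )


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test on complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0) and not np.allclose(d.mean(), 0.0):
        raise ValueError("degenerate pairs: constant nonzero difference")
    res = sps.ttest_rel(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n=x.size,
        estimate=float(d.mean()),
    )


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def partial_pearson(x, y, covariates=None) -> TestResult:
    """Pearson correlation of x and y after removing linear covariate effects.

    Both variables are residualized on the covariate matrix (with
    intercept); the correlation of the residuals is tested against a t
    distribution with ``n - 2 - n_covariates`` degrees of freedom.  With
    no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if covariates is None or (np.asarray(covariates).size == 0):
        c = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        Z = np.column_stack([np.ones(n), np.atleast_2d(np.asarray(covariates, dtype=float).T).T])
        c = Z.shape[1] - 1
        if n <= c + 2:
            raise ValueError("too few observations for the covariate set")
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
        beta_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
        beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
        rx = x - Z @ beta_x
        ry = y - Z @ beta_y
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("zero variance after residualization")
    r = float((rx * ry).sum() / denom)
    df = n - 2 - c
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p=p, n=n, estimate=r)


def regression_slope(x, y, conf: float = 0.95) -> dict[str, float]:
    """Ordinary least-squares line with CI half-widths in "+/-" style.

    Returns slope, intercept, their confidence half-widths, and the
    two-sided p-value of the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x.std(), 0.0):
        raise ValueError("zero variance in x")
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=1 - conf)
    return {
        "slope": float(model.params[1]),
        "slope_halfwidth": float((ci[1, 1] - ci[1, 0]) / 2),
        "intercept": float(model.params[0]),
        "intercept_halfwidth": float((ci[0, 1] - ci[0, 0]) / 2),
        "p_slope": float(model.pvalues[1]),
        "n": int(x.size),
    }
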