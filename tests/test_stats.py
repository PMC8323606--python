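"""t-tests, BH-FDR, partial correlation, OLS slopes: oracles and properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from na_contrast.stats import (
    StatsConfig,
    bh_fdr,
    paired_t,
    partial_pearson,
    regression_slope,
    unpaired_t,
)


def test_identical_groups_give_t0_p1():
    g = [1.0, 2.0, 3.0, 4.0]
    res = unpaired_t(g, list(g))
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_unpaired_t_matches_definition_oracle(rng):
    a = rng.normal(0.3, 1.0, 12)
    b = rng.normal(0.0, 1.5, 9)
    # Welch from the definition
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    res = unpaired_t(a, b)
    assert res.statistic == pytest.approx(t, abs=1e-12)
    # pooled variant
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    t_pooled = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    assert unpaired_t(a, b, pooled=True).statistic == pytest.approx(t_pooled, abs=1e-12)


def test_paired_t_matches_one_sample_oracle(rng):
    x = rng.normal(1.0, 0.5, 15)
    y = x + rng.normal(0.1, 0.2, 15)
    d = x - y
    t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    assert paired_t(x, y).statistic == pytest.approx(t, abs=1e-12)


def test_degenerate_constant_difference_rejected():
    x = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        paired_t(x, x + 0.5)


def test_insufficient_n_rejected():
    with pytest.raises(ValueError):
        unpaired_t([1.0], [1.0, 2.0])


def test_bh_fdr_step_up_hand_example():
    """p = (0.01, 0.02, 0.04, 0.9) at q = 0.05: thresholds i*q/m =
    (0.0125, 0.025, 0.0375, 0.05); largest passing rank is 2, but step-up
    from the top keeps ranks 1-3 iff p(3) <= 0.0375 fails -> check by hand:
    0.04 > 0.0375, 0.02 <= 0.025 -> reject first two."""
    adj, reject = bh_fdr([0.01, 0.02, 0.04, 0.9], q=0.05)
    # hand-computed adjusted values: monotone min over p*m/i from the top
    assert np.allclose(adj, [0.04, 0.04, 0.053333333, 0.9])
    assert list(reject) == [True, True, False, False]


def test_bh_fdr_edge_cases():
    adj, reject = bh_fdr([0.0, 0.0, 0.0], q=0.05)
    assert reject.all()
    adj1, _ = bh_fdr([0.2], q=0.05)
    assert adj1[0] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        bh_fdr([], q=0.05)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_rejections_grow_with_q(ps):
    _, r_small = bh_fdr(ps, q=0.01)
    _, r_large = bh_fdr(ps, q=0.2)
    assert (r_large | ~r_small).all()  # rejections at small q survive at large q


def test_partial_pearson_matches_residualization_oracle(rng):
    n = 40
    cov = np.column_stack([rng.normal(50, 10, n), rng.integers(0, 2, n)])
    x = 0.5 * cov[:, 0] + rng.normal(0, 1, n)
    y = -0.3 * cov[:, 0] + 0.8 * x + rng.normal(0, 1, n)
    res = partial_pearson(x, y, cov)
    Z = np.column_stack([np.ones(n), cov])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())
    assert res.estimate == pytest.approx(r, abs=1e-10)


def test_partial_pearson_reduces_to_plain(rng):
    x = rng.normal(size=25)
    y = 2 * x + rng.normal(size=25)
    plain = partial_pearson(x, y)
    from scipy.stats import pearsonr

    ref = pearsonr(x, y)
    assert plain.estimate == pytest.approx(ref.statistic, abs=1e-12)
    assert plain.p == pytest.approx(ref.pvalue, abs=1e-10)
    # orthogonal covariate changes nothing (up to the df adjustment in p)
    ortho = rng.normal(size=25)
    ortho -= ortho.mean()
    ortho -= x * (ortho @ x) / (x @ x)  # orthogonalize to x only for stability
    res = partial_pearson(x, x.copy(), np.column_stack([ortho]))
    assert res.estimate == pytest.approx(1.0, abs=1e-10)


def test_partial_pearson_rank_deficiency_rejected(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    cov = np.column_stack([x, 2 * x])
    with pytest.raises(ValueError):
        partial_pearson(x, y, cov)


def test_regression_slope_exact_line():
    x = np.arange(10.0)
    out = regression_slope(x, 2 * x + 1)
    assert out["slope"] == pytest.approx(2.0)
    assert out["intercept"] == pytest.approx(1.0)
    assert out["slope_halfwidth"] == pytest.approx(0.0, abs=1e-10)


def test_regression_matches_closed_form_ols(rng):
    x = rng.normal(size=30)
    y = 1.5 * x + rng.normal(0, 0.5, 30)
    out = regression_slope(x, y)
    beta = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    assert out["slope"] == pytest.approx(beta, abs=1e-10)
    with pytest.raises(ValueError):
        regression_slope(np.ones(5), np.arange(5.0))


def test_slope_ci_covers_true_effect_ratio():
    """Cohorts generated with a 1.5x NaPACMAN:NaDW lesion-effect ratio:
    the fitted slope CI covers 1.5 in at least 90% of replicates."""
    from na_contrast.phantom import simulate_cohort

    covered = 0
    n_rep = 25
    for rep in range(n_rep):
        df = simulate_cohort(
            n_controls=9,
            n_patients=30,
            effects={
                "NaDW": {"lesion": 30.0, "nawm": 0.0},
                "NaPACMAN": {"lesion": 45.0, "nawm": 0.0},
            },
            seed=1000 + rep,
        )
        piv = df[df.group == "patient"].pivot_table(
            index=["subject", "region"],
            columns=["sequence", "tissue_state"],
            values="mean_intensity",
        )
        # intra-patient lesion change relative to directly comparable NAWM,
        # averaged to one point per patient as in the study design
        x = (
            (piv[("NaDW", "lesion")] / piv[("NaDW", "nawm")] - 1)
            .groupby("subject")
            .mean()
            .to_numpy()
        )
        y = (
            (piv[("NaPACMAN", "lesion")] / piv[("NaPACMAN", "nawm")] - 1)
            .groupby("subject")
            .mean()
            .to_numpy()
        )
        out = regression_slope(x, y)
        lo = out["slope"] - out["slope_halfwidth"]
        hi = out["slope"] + out["slope_halfwidth"]
        covered += lo <= 1.5 <= hi
    assert covered / n_rep >= 0.9


def test_stats_config_validation():
    cfg = StatsConfig()
    assert cfg.covariates == ("age", "sex")
    with pytest.raises(ValueError):
        StatsConfig(fdr_q_primary=1.5)
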