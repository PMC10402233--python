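"""Regression battery: standardized OLS, summation, mixed models, diagnostics."""

import numpy as np
import pytest
from scipy import stats as sps

from phossum.stats import (
    MixedShapeModel,
    StandardizedOLS,
    SummationRegression,
    bonferroni,
    compare_models,
    qq_normality,
    vif,
    welch_t_from_summary,
)


# ---------------------------------------------------------------------------
# standardized OLS and partial correlations
# ---------------------------------------------------------------------------

def test_single_predictor_beta_equals_pearson(rng):
    x = rng.normal(size=80)
    y = 0.6 * x + rng.normal(size=80)
    fit = StandardizedOLS(y, x).fit()
    assert fit.beta[0] == pytest.approx(np.corrcoef(x, y)[0, 1])
    assert fit.partial_r[0] == pytest.approx(np.corrcoef(x, y)[0, 1])


def test_orthogonal_predictors_partial_equals_marginal(rng):
    n = 64
    x1 = np.repeat([1.0, -1.0], n // 2)
    x2 = np.tile([1.0, -1.0], n // 2)  # exactly orthogonal to x1
    y = 0.5 * x1 - 0.3 * x2 + rng.normal(size=n)
    fit = StandardizedOLS(y, np.column_stack([x1, x2])).fit()
    for j, xj in enumerate((x1, x2)):
        marginal = np.corrcoef(xj, y)[0, 1]
        # residualizing on an orthogonal predictor only rescales, so the
        # partial correlation matches the marginal up to that rescaling
        assert np.sign(fit.partial_r[j]) == np.sign(marginal)
        assert abs(fit.partial_r[j]) >= abs(marginal) - 1e-9


def test_exact_linear_fit_residuals_zero(rng):
    X = rng.normal(size=(40, 2))
    y = X @ [1.5, -2.0]
    fit = StandardizedOLS(y, X).fit()
    assert np.abs(fit.resid).max() < 1e-10
    assert np.abs(fit.partial_r) == pytest.approx([1.0, 1.0], abs=1e-6)


def test_partial_r_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    n = 60
    X = rng.normal(size=(n, 3))
    y = X @ [0.5, -0.4, 0.2] + rng.normal(size=n)
    fit = StandardizedOLS(y, X, predictor_names=["a", "b", "c"]).fit()
    df = pd.DataFrame(X, columns=["a", "b", "c"]).assign(y=y)
    for j, name in enumerate(["a", "b", "c"]):
        covars = [c for c in ("a", "b", "c") if c != name]
        r = pingouin.partial_corr(df, x=name, y="y", covar=covars)["r"].iloc[0]
        assert fit.partial_r[j] == pytest.approx(r, abs=1e-8)
        p = pingouin.partial_corr(df, x=name, y="y", covar=covars)["p_val"].iloc[0]
        assert fit.pvalues[j] == pytest.approx(p, abs=1e-6)


def test_rank_deficiency_and_small_n_rejected(rng):
    x = rng.normal(size=20)
    with pytest.raises(ValueError):
        StandardizedOLS(rng.normal(size=20), np.column_stack([x, 2 * x]))
    with pytest.raises(ValueError):
        StandardizedOLS(np.ones(3), np.ones((3, 2)))


def test_beta_and_partial_share_sign(rng):
    for _ in range(15):
        X = rng.normal(size=(50, 3)) @ (np.eye(3) + 0.4 * rng.normal(size=(3, 3)))
        y = X @ rng.normal(size=3) + rng.normal(size=50)
        fit = StandardizedOLS(y, X).fit()
        nz = np.abs(fit.beta) > 1e-10
        assert (np.sign(fit.beta[nz]) == np.sign(fit.partial_r[nz])).all()


def test_affine_rescaling_of_predictors_is_absorbed(rng):
    X = rng.normal(size=(60, 2))
    y = X @ [1.0, -0.5] + rng.normal(size=60)
    a = StandardizedOLS(y, X).fit()
    b = StandardizedOLS(y, X * [13.0, 0.02] + [5.0, -7.0]).fit()
    assert a.beta == pytest.approx(b.beta)
    assert a.partial_r == pytest.approx(b.partial_r)
    assert a.pvalues == pytest.approx(b.pvalues)


def test_type_one_error_rate_near_nominal():
    """Under the null, regression p-values should reject at ~5%."""
    rng = np.random.default_rng(77)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        fit = StandardizedOLS(y, x).fit()
        rejections += fit.pvalues[0] < 0.05
    assert rejections / reps == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# summation regression
# ---------------------------------------------------------------------------

def test_summation_exact_slopes():
    x = np.linspace(1, 10, 20)
    fit = SummationRegression(0.653 * x, x).fit()
    assert fit.beta[0] == pytest.approx(0.653)
    assert "smaller than their sum" in fit.extra["interpretation"]
    fit1 = SummationRegression(x, x).fit()
    assert fit1.beta[0] == pytest.approx(1.0)


def test_summation_closed_form_oracle(rng):
    x = rng.uniform(1, 50, 100)
    y = 0.7 * x * np.exp(rng.normal(0, 0.1, 100))
    fit = SummationRegression(y, x).fit()
    assert fit.beta[0] == pytest.approx((x @ y) / (x @ x))


def test_summation_gain_recovery_linear_generator():
    rng = np.random.default_rng(5)
    x = rng.uniform(5, 80, 100)
    y = np.clip(0.7 * x + rng.normal(0, 2.0, 100), 0, None)
    fit = SummationRegression(y, x).fit()
    assert fit.beta[0] == pytest.approx(0.7, abs=0.05)


def test_summation_input_validation():
    with pytest.raises(ValueError):
        SummationRegression([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        SummationRegression([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def test_mixed_matches_pooled_ols_when_no_group_variance():
    rng = np.random.default_rng(11)
    n = 240
    x = rng.normal(size=n)
    y = 0.8 * x + rng.normal(0, 0.5, size=n)
    groups = np.repeat(["a", "b", "c"], n // 3)
    import statsmodels.api as sm

    mixed = MixedShapeModel(y, x, groups, standardize=False).fit()
    pooled = sm.OLS(y, sm.add_constant(x)).fit()
    assert mixed.beta[0] == pytest.approx(pooled.params[1], abs=1e-3)


def test_mixed_recovers_slope_with_random_intercepts():
    rng = np.random.default_rng(21)
    n_groups, per = 10, 30
    x = rng.normal(size=n_groups * per)
    intercepts = np.repeat(rng.normal(0, 1.0, n_groups), per)
    y = intercepts + 0.5 * x + rng.normal(0, 0.5, size=n_groups * per)
    groups = np.repeat(np.arange(n_groups), per)
    fit = MixedShapeModel(y, x, groups, standardize=False).fit()
    se = 0.5 / np.sqrt(len(y))  # rough; the CI check below is the contract
    t = sps.norm.ppf(0.975)
    assert abs(fit.beta[0] - 0.5) < 4 * se + t * 0.05
    assert fit.extra["random_intercept_var"] > 0.05


def test_mixed_slope_invariant_to_group_shifts():
    rng = np.random.default_rng(31)
    x = np.tile(rng.normal(size=50), 3)
    base = 0.7 * x[:50] + rng.normal(0, 0.3, 50)
    y = np.concatenate([base, base + 5.0, base - 3.0])
    groups = np.repeat([0, 1, 2], 50)
    fit = MixedShapeModel(y, x, groups, standardize=False).fit()
    assert fit.beta[0] == pytest.approx(0.7, abs=0.1)


def test_mixed_requires_two_groups(rng):
    with pytest.raises(ValueError):
        MixedShapeModel(rng.normal(size=10), rng.normal(size=10),
                        np.zeros(10))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def test_bonferroni():
    assert bonferroni(0.01, 4) == pytest.approx(0.04)
    assert bonferroni(0.5, 4) == 1.0
    assert bonferroni(0.3, 1) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        bonferroni(1.5, 2)


def test_vif_orthogonal_and_collinear(rng):
    X = np.column_stack([np.repeat([1.0, -1.0], 20), np.tile([1.0, -1.0], 20)])
    assert vif(X) == pytest.approx([1.0, 1.0])
    x = rng.normal(size=30)
    with pytest.raises(ValueError):
        vif(np.column_stack([x, x]))


def test_vif_matches_r2_oracle(rng):
    n = 120
    z = rng.normal(size=n)
    X = np.column_stack([
        z + 0.5 * rng.normal(size=n),
        z + 0.8 * rng.normal(size=n),
        rng.normal(size=n),
    ])
    got = vif(X)
    for j in range(3):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ coef
        r2 = 1 - resid @ resid / np.sum((X[:, j] - X[:, j].mean()) ** 2)
        assert got[j] == pytest.approx(1.0 / (1.0 - r2))


def test_welch_t_from_summary(rng):
    assert welch_t_from_summary(5.0, 1.0, 5.0, 2.0) == 0.0
    for _ in range(10):
        m1, m2 = rng.normal(0, 10, 2)
        s1, s2 = rng.uniform(0.5, 5, 2)
        assert welch_t_from_summary(m1, s1, m2, s2) == pytest.approx(
            (m1 - m2) / np.sqrt(s1**2 + s2**2)
        )
    with pytest.raises(ValueError):
        welch_t_from_summary(1.0, 0.0, 2.0, 0.0)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def test_compare_identical_models(rng):
    x = rng.normal(size=50)
    y = x + rng.normal(size=50)
    fit = StandardizedOLS(y, x).fit()
    cmp_ = compare_models(fit, fit)
    assert cmp_.delta_aic == 0.0
    assert cmp_.aic_band == "both supported"
    assert cmp_.winner == "tie"


def test_noise_predictor_costs_about_two_aic():
    """Adding a pure-noise predictor on null data should cost ~2 AIC
    (the parameter penalty) minus the ~1 expected chance improvement."""
    rng = np.random.default_rng(13)
    deltas = []
    for _ in range(300):
        n = 60
        x = rng.normal(size=n)
        noise_pred = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        a = StandardizedOLS(y, x).fit()
        b = StandardizedOLS(y, np.column_stack([x, noise_pred])).fit()
        deltas.append(b.aic - a.aic)
    mean_delta = np.mean(deltas)
    assert 0.0 < mean_delta < 2.2


def test_true_predictor_lowers_aic_and_bic_penalizes_harder():
    rng = np.random.default_rng(17)
    n = 500
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = x1 + 0.8 * x2 + rng.normal(size=n)
    small = StandardizedOLS(y, x1).fit()
    big = StandardizedOLS(y, np.column_stack([x1, x2])).fit()
    assert big.aic < small.aic
    assert big.bic < small.bic
    # for a useless addition the BIC penalty exceeds the AIC penalty
    noise = rng.normal(size=n)
    bigger = StandardizedOLS(y, np.column_stack([x1, x2, noise])).fit()
    assert (bigger.bic - big.bic) > (bigger.aic - big.aic)


def test_between_axon_model_wins_when_it_drives_response(rng):
    n = 90
    between = rng.uniform(0, 2000, n)
    along = rng.uniform(0, 2000, n)
    count = 1 + (between > 800).astype(float) + rng.normal(0, 0.2, n)
    a = StandardizedOLS(count, along).fit()
    b = StandardizedOLS(count, between).fit()
    cmp_ = compare_models(a, b)
    assert cmp_.winner == "B"
    assert cmp_.aic_band == "strong evidence"


def test_compare_models_different_n_rejected(rng):
    y = rng.normal(size=40)
    a = StandardizedOLS(y, rng.normal(size=40)).fit()
    b = StandardizedOLS(y[:30], rng.normal(size=30)).fit()
    with pytest.raises(ValueError):
        compare_models(a, b)


# ---------------------------------------------------------------------------
# normality diagnostics
# ---------------------------------------------------------------------------

def test_qq_normality_discriminates():
    rng = np.random.default_rng(19)
    normal = rng.normal(size=500)
    skewed = rng.exponential(size=500)
    r_norm = qq_normality(normal)
    r_skew = qq_normality(skewed)
    assert r_norm > 0.995
    assert r_skew < r_norm
    with pytest.raises(ValueError):
        qq_normality(np.ones(50))
    with pytest.raises(ValueError):
        qq_normality(normal[:5])


def test_summary_renders(rng):
    x = rng.normal(size=40)
    y = x + rng.normal(size=40)
    text = StandardizedOLS(y, x, predictor_names=["amp"]).fit().summary()
    assert "amp" in text and "AIC" in text
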