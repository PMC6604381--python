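import numpy as np
import pytest

from balli import (
    DesignPair,
    SimConfig,
    fit_gene_ols,
    fit_trend,
    gene_lambda,
    group_design,
    log_cpm,
    predict_mu,
    simulate_counts,
    tmm_factors,
)
from balli.normalization import NormalizedLibSizes


def _nls(R_star):
    R_star = np.asarray(R_star, dtype=float)
    return NormalizedLibSizes(
        factors=np.ones_like(R_star),
        R_star=R_star,
        d=R_star / R_star.mean() * 0.25,
    )


def intercept_design(N):
    # X must be nonempty for a DesignPair; a centered column keeps (Z, X) full rank
    x = np.linspace(-1, 1, N).reshape(-1, 1)
    return DesignPair(Z=np.ones((N, 1)), X=x, M=2)


def test_ols_constant_gene_has_zero_residual_variance(two_group_design):
    y = np.full((1, 6), 3.7)
    ols = fit_gene_ols(y, two_group_design)
    assert ols.resid_var[0] == pytest.approx(0.0, abs=1e-20)
    np.testing.assert_allclose(ols.fitted[0], 3.7)


def test_ols_intercept_only_matches_hand_computation():
    # y = (0, 1, 2) on an intercept: fitted all 1, RSS = 2, divisor N - 1 = 2
    ols = fit_gene_ols(np.array([[0.0, 1.0, 2.0]]), np.ones((3, 1)))
    assert ols.resid_var[0] == pytest.approx(1.0)
    np.testing.assert_allclose(ols.fitted[0], [1.0, 1.0, 1.0])


def test_ols_shift_invariance(two_group_design, rng):
    y = rng.normal(size=(5, 6))
    ols = fit_gene_ols(y, two_group_design)
    ols_shift = fit_gene_ols(y + 2.5, two_group_design)
    np.testing.assert_allclose(ols_shift.fitted, ols.fitted + 2.5, atol=1e-12)
    np.testing.assert_allclose(ols_shift.resid_var, ols.resid_var, atol=1e-12)


def test_gene_lambda_offsets_cancel_at_million_depth(two_group_design, rng):
    y = rng.normal(5, 1, size=(12, 6))
    ols = fit_gene_ols(y, two_group_design)
    lam = gene_lambda(ols, _nls(np.full(6, 1e6 - 1.0)))  # R* + 1 = 1e6
    np.testing.assert_allclose(lam, ols.ybar, atol=1e-12)


def test_gene_lambda_unit_library_shift():
    ols = fit_gene_ols(np.full((1, 4), 4.0), intercept_design(4))
    lam = gene_lambda(ols, _nls(np.ones(4)))  # geomean(R* + 1) = 2
    assert lam[0] == pytest.approx(4.0 + 1.0 - np.log2(1e6))


def test_gene_lambda_tracks_ybar_one_to_one(two_group_design, rng):
    y = rng.normal(size=(15, 6))
    ols1 = fit_gene_ols(y, two_group_design)
    ols2 = fit_gene_ols(y + 1.0, two_group_design)
    nls = _nls(np.full(6, 5e5))
    np.testing.assert_allclose(
        gene_lambda(ols2, nls) - gene_lambda(ols1, nls), 1.0, atol=1e-12
    )


def test_trend_of_constant_scatter_is_constant(rng):
    lam = rng.uniform(0, 10, 50)
    s2 = np.full(50, 0.3)
    trend = fit_trend(lam, s2, _nls(np.full(4, 1e6)))
    np.testing.assert_allclose(trend(lam), 0.3**0.25, atol=1e-10)


def test_trend_recovers_noiseless_line(rng):
    lam = np.sort(rng.uniform(0, 10, 200))
    s_half = 0.2 + 0.05 * lam  # exactly linear, no noise
    trend = fit_trend(lam, s_half**4, _nls(np.full(4, 1e6)))
    interior = (lam > 1) & (lam < 9)
    np.testing.assert_allclose(trend(lam[interior]), s_half[interior], atol=1e-6)


def test_trend_clamps_at_zero_and_extrapolates_flat(rng):
    lam = np.linspace(0, 5, 60)
    s2 = np.zeros(60)
    trend = fit_trend(lam, s2, _nls(np.full(4, 1e6)))
    assert (trend(np.array([-10.0, 2.0, 50.0])) >= 0).all()
    assert trend(np.array([50.0]))[0] == trend(np.array([5.0]))[0]


def test_trend_refuses_fewer_than_ten_genes():
    with pytest.raises(ValueError, match="10 genes"):
        fit_trend(np.arange(5.0), np.ones(5), _nls(np.full(4, 1e6)))


def test_predict_mu_examples(two_group_design, rng):
    y = rng.normal(5, 1, size=(40, 6))
    ols = fit_gene_ols(y, two_group_design)
    nls = _nls(np.full(6, 1e6))
    lam = gene_lambda(ols, nls)
    # flat trend at zero -> mu = 2^lambda exactly
    trend0 = fit_trend(lam, np.zeros(40), nls)
    tech0 = predict_mu(ols, trend0, nls)
    np.testing.assert_allclose(tech0.mu_hat, 2.0**tech0.lambda_hat_obs, rtol=1e-12)
    # lambda = 10, s^2 = 1 -> mu = 1024 * (1 + (ln 2)^2 / 2) ~ 1270.0
    mu = 2.0**10 * (1 + 0.5 * np.log(2) ** 2 * 1.0)
    assert mu == pytest.approx(1269.99, abs=0.05)
    # monotone in lambda at fixed s, and always at least 2^lambda
    assert (tech0.mu_hat > 0).all()
    trend1 = fit_trend(lam, np.ones(40), nls)
    tech1 = predict_mu(ols, trend1, nls)
    assert (tech1.mu_hat >= 2.0**tech1.lambda_hat_obs - 1e-9).all()


def test_mu_hat_tracks_true_nb_mean():
    """On NB counts with known means, mu_hat approximates the truth within 20%
    for genes with mean >= 50 (quality of the second-order approximation)."""
    cfg = SimConfig(G=1500, N=16, u=1.0, de_fraction=0.0, seed=123)
    truth = simulate_counts(cfg)
    cm = truth.counts
    dp = group_design(cfg.N)
    nls = tmm_factors(cm)
    y = log_cpm(cm, nls)
    ols = fit_gene_ols(y, dp)
    lam = gene_lambda(ols, nls)
    trend = fit_trend(lam, ols.resid_var, nls)
    tech = predict_mu(ols, trend, nls)
    true_mean = cm.counts.mean(axis=1)
    sel = true_mean >= 50
    ratio = tech.mu_hat.mean(axis=1)[sel] / true_mean[sel]
    assert np.median(np.abs(ratio - 1)) < 0.2
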