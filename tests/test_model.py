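"""Unit and property tests for the Gibbs sampler's full conditionals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bvsreg.exceptions import ConfigError, InvalidDataError, InvalidStateError
from bvsreg.model import (
    ChainConfig,
    ChainState,
    ModelData,
    Priors,
    SpikeSlabRegressor,
    gibbs_step,
    inclusion_probability,
    run_chain,
    sample_effect_and_indicator,
    sample_intercept,
    sample_pi,
    sample_residual_variance,
    sample_scaled_inv_chi2,
    sample_slab_variance,
)

from conftest import make_state


# ---------------------------------------------------------------------------
# scaled inverse chi-square draws
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "df, scale, expected_mean, tol",
    [
        (100.0, 1.0, 100.0 / 98.0, 0.003),  # residual-variance FCPF shape
        (6.0, 2.0 / 3.0, 1.0, 0.02),  # slab FCPF with effects {1, -1}
    ],
)
def test_scaled_inv_chi2_monte_carlo_mean(df, scale, expected_mean, tol):
    """Empirical mean of draws matches df*scale/(df-2)."""
    rng = np.random.default_rng(1)
    draws = df * scale / rng.chisquare(df, size=100_000)
    assert abs(draws.mean() - expected_mean) < tol
    single = sample_scaled_inv_chi2(np.random.default_rng(0), df, scale)
    assert single > 0


def test_residual_variance_fcpf_parameters(small_data):
    """With v_eps=4, S_eps=1, r'r=96, n=96 the FCPF is ScaledInv-chi2(100, 1)."""
    n = 96
    y = np.zeros(n)
    X = np.zeros((n, 0))
    data = ModelData(y=y, X=X)
    priors = Priors(s_eps=1.0, v_eps=4.0, s_alpha=1.0)
    state = make_state(data, priors)
    state.resid = np.full(n, 1.0)  # r'r = 96
    draw = sample_residual_variance(state, data, priors, np.random.default_rng(42))
    expected = 100.0 * 1.0 / np.random.default_rng(42).chisquare(100.0)
    assert draw == pytest.approx(expected)
    # the paper-scale case: n=697 with v_eps=10 gives df 707
    assert Priors(v_eps=10.0).v_eps + 697 == 707


def test_residual_variance_rejects_nonfinite_rss(small_data):
    priors = Priors().resolved(small_data.y)
    state = make_state(small_data, priors)
    state.resid = state.resid.copy()
    state.resid[0] = np.inf
    with pytest.raises(InvalidStateError):
        sample_residual_variance(state, small_data, priors, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# intercept
# ---------------------------------------------------------------------------

def test_intercept_fcpf_constant_residual():
    """Residual y - X(theta o alpha) = 1-vector, n=100, s2e=1 -> N(1, 0.01)."""
    n = 100
    data = ModelData(y=np.ones(n), X=np.zeros((n, 0)))
    state = make_state(data, Priors(s_alpha=1.0))
    state.mu = 0.0
    state.resid = np.ones(n)
    state.sigma2_eps = 1.0
    draw = sample_intercept(state, data, np.random.default_rng(7))
    expected = np.random.default_rng(7).normal(1.0, 0.1)
    assert draw == pytest.approx(expected)


def test_intercept_monte_carlo_variance():
    """Empirical variance of draws is sigma2_eps / n = 0.01."""
    n = 100
    data = ModelData(y=np.zeros(n), X=np.zeros((n, 0)))
    state = make_state(data, Priors(s_alpha=1.0, s_eps=1.0))
    state.mu = 0.0
    state.resid = np.zeros(n)  # zero-sum: mean 0, variance 1/100
    state.sigma2_eps = 1.0
    rng = np.random.default_rng(3)
    draws = np.array([sample_intercept(state, data, rng) for _ in range(100_000)])
    assert abs(draws.mean()) < 0.001
    assert draws.var() == pytest.approx(0.01, abs=2e-4)


# ---------------------------------------------------------------------------
# inclusion probability
# ---------------------------------------------------------------------------

def test_inclusion_probability_prior_extremes():
    assert inclusion_probability(5.0, 10.0, 1.0, 0.5, 0.0) == 0.0
    assert inclusion_probability(5.0, 10.0, 1.0, 0.5, 1.0) == 1.0


def test_inclusion_probability_degenerate_slab_returns_pi():
    """sigma2_alpha -> 0 makes both likelihoods equal, so posterior = prior."""
    for pi in (0.05, 0.5, 0.9):
        assert inclusion_probability(3.0, 50.0, 1.2, 0.0, pi) == pytest.approx(pi)


def test_inclusion_probability_against_scalar_densities():
    """Posterior odds recomputed from scipy normal log-densities."""
    u, cjj, s2e, s2a, pi = 30.0, 100.0, 1.0, 0.1, 0.1
    logf0 = stats.norm.logpdf(u, 0.0, np.sqrt(cjj * s2e))
    logf1 = stats.norm.logpdf(u, 0.0, np.sqrt(cjj * s2e + cjj**2 * s2a))
    expected = 1.0 / (1.0 + np.exp(np.log((1 - pi) / pi) + logf0 - logf1))
    got = inclusion_probability(u, cjj, s2e, s2a, pi)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got == pytest.approx(0.667020, abs=5e-6)


def test_inclusion_probability_invalid_inputs():
    with pytest.raises(InvalidDataError):
        inclusion_probability(1.0, 0.0, 1.0, 1.0, 0.5)
    with pytest.raises(InvalidDataError):
        inclusion_probability(1.0, 1.0, 1.0, 1.0, 1.5)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    u=st.floats(-100, 100),
    cjj=st.floats(0.1, 1e4),
    s2e=st.floats(1e-3, 1e3),
    s2a=st.floats(1e-6, 1e3),
    pi=st.floats(0.01, 0.99),
)
def test_inclusion_probability_is_probability_and_monotone_in_pi(u, cjj, s2e, s2a, pi):
    p1 = inclusion_probability(u, cjj, s2e, s2a, pi)
    assert 0.0 <= p1 <= 1.0
    p2 = inclusion_probability(u, cjj, s2e, s2a, min(pi + 0.005, 0.995))
    assert p2 >= p1 - 1e-12


# ---------------------------------------------------------------------------
# effect + indicator update
# ---------------------------------------------------------------------------

def test_effect_mean_zero_when_orthogonal(rng):
    """x_j orthogonal to r_{-j} gives conditional effect mean exactly 0."""
    n = 40
    x = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
    r = np.concatenate([np.zeros(n // 2), rng.normal(size=n // 2)])
    data = ModelData(y=r, X=x[:, None])
    state = make_state(data, Priors(s_alpha=1.0, fix_pi=0.999))
    state.mu = 0.0
    state.resid = r.copy()
    state.sigma2_eps, state.sigma2_alpha, state.pi = 1.0, 1.0, 0.999
    seed = 5
    theta, a = sample_effect_and_indicator(0, state, data, np.random.default_rng(seed))
    c_j = x @ x + 1.0
    check = np.random.default_rng(seed)
    p1 = inclusion_probability(0.0, x @ x, 1.0, 1.0, 0.999)
    assert check.random() < p1 and theta == 1
    assert a == pytest.approx(check.normal(0.0, np.sqrt(1.0 / c_j)))


def test_effect_mean_flat_prior_limit(rng):
    """sigma2_alpha -> inf: conditional mean -> least-squares coefficient."""
    n = 80
    x = rng.binomial(2, 0.4, n).astype(float)
    r = 0.7 * x + rng.normal(0, 0.1, n)
    ls = (x @ r) / (x @ x)
    c_j = x @ x + 1.0 / 1e12
    assert (x @ r) / c_j == pytest.approx(ls, rel=1e-9)


def test_incremental_residual_matches_recompute(rng):
    """After many updates the running residual equals the from-scratch one."""
    n, p = 200, 50
    X = rng.binomial(2, rng.uniform(0.05, 0.5, p), size=(n, p)).astype(float)
    y = X[:, 0] * 0.5 - X[:, 3] * 0.4 + rng.normal(0, 1, n)
    data = ModelData(y=y, X=X)
    priors = Priors().resolved(y)
    state = make_state(data, priors)
    gen = np.random.default_rng(0)
    for _ in range(100):
        gibbs_step(state, data, priors, gen)
    scratch = data.y - state.mu - data.X @ (state.theta * state.alpha)
    denom = 1.0 + np.abs(data.y).max()
    assert np.abs(state.resid - scratch).max() / denom < 1e-8


# ---------------------------------------------------------------------------
# slab variance and pi
# ---------------------------------------------------------------------------

def test_slab_variance_empty_model_is_prior_draw(small_data):
    priors = Priors(s_alpha=0.5, v_alpha=4.0).resolved(small_data.y)
    state = make_state(small_data, priors)
    assert state.k == 0
    draw = sample_slab_variance(state, priors, np.random.default_rng(9))
    expected = 4.0 * 0.5 / np.random.default_rng(9).chisquare(4.0)
    assert draw == pytest.approx(expected)


def test_slab_variance_pools_included_effects(small_data):
    """Effects {1, -1}: df = 6, scale = (4*0.5 + 2)/6 = 2/3."""
    priors = Priors(s_alpha=0.5, v_alpha=4.0).resolved(small_data.y)
    state = make_state(small_data, priors)
    state.theta[:2] = 1
    state.alpha[:2] = [1.0, -1.0]
    draw = sample_slab_variance(state, priors, np.random.default_rng(4))
    expected = 6.0 * (2.0 / 3.0) / np.random.default_rng(4).chisquare(6.0)
    assert draw == pytest.approx(expected)


def test_sample_pi_beta_posterior():
    priors = Priors(a0=1.0, b0=1.0)
    draw = sample_pi(3, 97, priors, np.random.default_rng(2))
    expected = np.random.default_rng(2).beta(4.0, 95.0)
    assert draw == pytest.approx(expected)
    rng = np.random.default_rng(0)
    draws = rng.beta(4.0, 95.0, size=100_000)
    assert draws.mean() == pytest.approx(0.04, abs=1e-3)
    with pytest.raises(InvalidStateError):
        sample_pi(5, 3, priors, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# full sweeps and chains
# ---------------------------------------------------------------------------

def test_gibbs_step_determinism(small_data):
    """Two sweeps from identical seeds give identical theta trajectories."""
    priors = Priors().resolved(small_data.y)
    trajs = []
    for _ in range(2):
        state = make_state(small_data, priors)
        gen = np.random.default_rng(123)
        traj = [gibbs_step(state, small_data, priors, gen).theta.copy() for _ in range(50)]
        trajs.append(np.array(traj))
    assert (trajs[0] == trajs[1]).all()


def test_gibbs_step_degenerate_schedule(small_data):
    """All variances and pi fixed, p=0: only mu moves."""
    n = 30
    data = ModelData(y=np.linspace(-1, 1, n), X=np.zeros((n, 0)))
    priors = Priors(
        s_alpha=1.0, fix_sigma2_eps=1.0, fix_sigma2_alpha=1.0, fix_pi=0.5
    ).resolved(data.y)
    state = make_state(data, priors)
    before = (state.sigma2_eps, state.sigma2_alpha, state.pi)
    mu0 = state.mu
    gibbs_step(state, data, priors, np.random.default_rng(1))
    assert (state.sigma2_eps, state.sigma2_alpha, state.pi) == before
    assert state.mu != mu0


def test_pure_python_chain_matches_enumeration(rng):
    """Reference-path inclusion frequencies converge to the exact posterior."""
    from bvsreg.oracle import enumerate_posterior

    n, p = 60, 4
    X = rng.binomial(2, 0.35, size=(n, p)).astype(float)
    y = 0.4 * X[:, 1] + rng.normal(0, 1, n)
    y -= y.mean()
    data = ModelData(y=y, X=X)
    s2e, s2a, pi = 1.0, 0.1, 0.2
    priors = Priors(
        s_alpha=s2a, fix_sigma2_eps=s2e, fix_sigma2_alpha=s2a, fix_pi=pi, fix_mu=0.0
    ).resolved(y)
    state = make_state(data, priors)
    gen = np.random.default_rng(99)
    n_iter, burn = 20_000, 500
    counts = np.zeros(p)
    for s in range(n_iter):
        gibbs_step(state, data, priors, gen)
        if s >= burn:
            counts += state.theta
    freq = counts / (n_iter - burn)
    exact = enumerate_posterior(data, s2e, s2a, pi).ppa_exact
    assert np.abs(freq - exact).max() < 0.03


def test_run_chain_ppa_identities(small_data):
    """sum(PPA) equals mean k exactly; PPAs live in [0, 1]."""
    summary = run_chain(
        small_data, Priors(), ChainConfig(n_iter=2_000, burn_in=200, seed=5)
    )
    assert ((summary.ppa >= 0) & (summary.ppa <= 1)).all()
    assert summary.ppa.sum() == pytest.approx(summary.k_samples.mean(), abs=1e-12)
    assert summary.n_retained == 1_800


def test_run_chain_seed_determinism(small_data):
    a = run_chain(small_data, Priors(), ChainConfig(n_iter=1_500, burn_in=100, seed=7))
    b = run_chain(small_data, Priors(), ChainConfig(n_iter=1_500, burn_in=100, seed=7))
    assert (a.ppa == b.ppa).all()
    assert (a.alpha_mean == b.alpha_mean).all()
    assert (a.k_samples == b.k_samples).all()
    c = run_chain(small_data, Priors(), ChainConfig(n_iter=1_500, burn_in=100, seed=8))
    assert (a.ppa != c.ppa).any()


def test_residual_consistency_after_long_kernel_run(rng):
    """Kernel residual drift stays below 1e-6 relative to y's magnitude."""
    n, p = 120, 30
    X = rng.binomial(2, rng.uniform(0.05, 0.5, p), size=(n, p)).astype(float)
    y = 0.6 * X[:, 2] + rng.normal(0, 1, n)
    est = SpikeSlabRegressor(n_iter=5_000, burn_in=500, random_state=1)
    est.fit(X, y)
    scratch = y - est._final_mu - X @ (est._final_theta * est._final_alpha)
    assert np.abs(est._final_resid - scratch).max() / (1 + np.abs(y).max()) < 1e-6


def test_mean_k_monotone_in_fixed_pi(rng):
    """Raising fixed pi never lowers the posterior mean model size."""
    n, p = 100, 20
    X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
    y = 0.5 * X[:, 0] + rng.normal(0, 1, n)
    means = []
    for pi in (0.02, 0.1, 0.3):
        ks = []
        for seed in range(3):
            s = run_chain(
                ModelData(y=y, X=X),
                Priors(fix_pi=pi),
                ChainConfig(n_iter=3_000, burn_in=500, seed=seed),
            )
            ks.append(s.k_samples.mean())
        means.append(np.mean(ks))
    assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9


def test_monomorphic_columns_excluded(rng):
    n, p = 50, 5
    X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
    X[:, 2] = 0.0
    y = rng.normal(size=n)
    est = SpikeSlabRegressor(n_iter=1_000, burn_in=100, random_state=0)
    est.fit(X, y)
    assert est.monomorphic_[2] and est.ppa_[2] == 0.0
    with pytest.raises(InvalidDataError):
        SpikeSlabRegressor(n_iter=500, burn_in=50).fit(np.zeros((50, 3)), y)


def test_missing_dosages_imputed_to_column_mean(rng):
    X = np.array([[0.0, 1.0], [np.nan, 2.0], [2.0, 0.0], [0.0, np.nan]])
    est = SpikeSlabRegressor(n_iter=500, burn_in=50, random_state=0)
    est.fit(X, np.array([0.1, -0.2, 0.3, 0.0]))
    # fitting succeeded => imputation happened; check the helper directly
    from bvsreg.model import impute_mean_dosage

    Xi = impute_mean_dosage(X)
    assert Xi[1, 0] == pytest.approx(2.0 / 3.0)
    assert Xi[3, 1] == pytest.approx(1.0)


def test_config_and_data_validation():
    with pytest.raises(ConfigError):
        ChainConfig(n_iter=100, burn_in=100)
    with pytest.raises(ConfigError):
        ChainConfig(n_iter=100, burn_in=10, thin=0)
    with pytest.raises(InvalidDataError):
        ModelData(y=np.zeros(3), X=np.zeros((4, 2)))
    with pytest.raises(InvalidDataError):
        ModelData(y=np.zeros(4), X=np.full((4, 2), 3.0))
    with pytest.raises(InvalidDataError):
        Priors(fix_pi=1.5)


def test_estimator_predict_and_sklearn_clone(small_data):
    from sklearn.base import clone

    est = SpikeSlabRegressor(n_iter=1_000, burn_in=100, random_state=0)
    est2 = clone(est)
    assert est2.get_params() == est.get_params()
    est.fit(small_data.X, small_data.y)
    pred = est.predict(small_data.X)
    assert pred.shape == small_data.y.shape
    # with one real signal the fit should track the phenotype direction
    assert np.corrcoef(pred, small_data.y)[0, 1] > 0.2
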