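"""Spike-and-slab Bayesian variable selection for quantitative traits.

The model regresses a quantitative phenotype on all SNP dosages at once:

    y = mu 1 + X (theta o alpha) + eps,      eps ~ N(0, sigma2_eps I)

where X is the n x p dosage matrix (0/1/2), theta_j in {0,1} is a latent
inclusion indicator with P(theta_j = 1) = pi shared across SNPs, and
alpha_j ~ N(0, sigma2_alpha) is the slab effect.  Both variances carry
scaled-inverse-chi-square priors (ScaledInv-chi2(v, S) is the law of
v*S/chi2_v) and pi carries a Beta(a0, b0) prior, so every full conditional
is standard and the posterior is explored by Gibbs sampling.  The per-SNP
posterior probability of association (PPA) is the post-burn-in proportion
of sweeps with theta_j = 1.

Two implementations coexist:

* readable NumPy step functions (`gibbs_step` and the `sample_*` family)
  that follow the full conditionals one draw at a time — the reference path
  used by the unit tests;
* a compiled kernel (:mod:`bvsreg._kernel`) used by :func:`run_chain` and
  :class:`SpikeSlabRegressor`, which maintains X'resid so that SNPs outside
  the model cost O(1) per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils import check_random_state

from . import _kernel
from .datatypes import GenotypeMatrix
from .exceptions import ConfigError, InvalidDataError, InvalidStateError

__all__ = [
    "ModelData",
    "Priors",
    "ChainState",
    "ChainConfig",
    "PosteriorSummary",
    "SpikeSlabRegressor",
    "run_chain",
    "gibbs_step",
    "sample_residual_variance",
    "sample_intercept",
    "inclusion_probability",
    "sample_effect_and_indicator",
    "sample_slab_variance",
    "sample_pi",
    "sample_scaled_inv_chi2",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ModelData:
    """Validated (y, X) pair ready for fitting.

    Missing dosages must be imputed before construction; every entry of X
    is finite and in [0, 2].  ``p = 0`` is allowed (intercept-only model).
    """

    y: np.ndarray
    X: np.ndarray
    snp_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise InvalidDataError("X must be 2-D")
        if self.y.ndim != 1 or len(self.y) != self.X.shape[0]:
            raise InvalidDataError("length of y must equal the row count of X")
        if not np.isfinite(self.y).all():
            raise InvalidDataError("y contains non-finite values")
        if not np.isfinite(self.X).all():
            raise InvalidDataError("X contains non-finite values (impute first)")
        if self.X.size and ((self.X < 0) | (self.X > 2)).any():
            raise InvalidDataError("X entries must lie in [0, 2]")
        if self.n < 2:
            raise InvalidDataError("need at least 2 individuals")
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp_{j}" for j in range(self.p)], dtype=object)
        else:
            self.snp_ids = np.asarray(self.snp_ids, dtype=object)
            if len(self.snp_ids) != self.p:
                raise InvalidDataError("snp_ids length must equal column count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_genotypes(cls, geno: GenotypeMatrix, y: np.ndarray) -> "ModelData":
        X = impute_mean_dosage(geno.X)
        return cls(y=y, X=X, snp_ids=geno.snp_ids)


@dataclass
class Priors:
    """Hyperparameters of the spike-and-slab model.

    ``s_alpha`` / ``s_eps`` left as None are resolved from the phenotype at
    fit time: s_eps = var(y)/2 and s_alpha = var(y)/(2*expected_k), a
    weakly informative, scale-aware choice.  The ``fix_*`` entries disable
    the corresponding Gibbs update and hold the parameter at the given
    value (testing hooks; ``fix_mu`` additionally supports the enumeration
    oracle, which treats the intercept as 0 on centred phenotypes).
    """

    s_alpha: float | None = None
    v_alpha: float = 4.0
    s_eps: float | None = None
    v_eps: float = 10.0
    a0: float = 1.0
    b0: float = 1.0
    expected_k: int = 10
    fix_sigma2_eps: float | None = None
    fix_sigma2_alpha: float | None = None
    fix_pi: float | None = None
    fix_mu: float | None = None

    def __post_init__(self) -> None:
        for name in ("v_alpha", "v_eps", "a0", "b0"):
            if getattr(self, name) <= 0:
                raise InvalidDataError(f"{name} must be > 0")
        for name in ("s_alpha", "s_eps"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidDataError(f"{name} must be > 0")
        if self.expected_k < 1:
            raise InvalidDataError("expected_k must be >= 1")
        for name in ("fix_sigma2_eps", "fix_sigma2_alpha"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidDataError(f"{name} must be > 0 when set")
        if self.fix_pi is not None and not (0.0 < self.fix_pi < 1.0):
            raise InvalidDataError("fix_pi must lie strictly inside (0, 1)")

    def resolved(self, y: np.ndarray) -> "Priors":
        """Fill scale hyperparameters from the phenotype variance."""
        vy = float(np.var(y))
        if vy <= 0:
            vy = 1.0
        s_eps = self.s_eps if self.s_eps is not None else vy / 2.0
        s_alpha = (
            self.s_alpha if self.s_alpha is not None else vy / (2.0 * self.expected_k)
        )
        return replace(self, s_eps=s_eps, s_alpha=s_alpha)


@dataclass
class ChainState:
    """All latent quantities of one Gibbs iteration."""

    mu: float
    alpha: np.ndarray
    theta: np.ndarray
    sigma2_eps: float
    sigma2_alpha: float
    pi: float
    resid: np.ndarray

    @property
    def k(self) -> int:
        return int(self.theta.sum())

    @classmethod
    def initial(cls, data: ModelData, priors: Priors) -> "ChainState":
        """Neutral start: empty model, mu at the phenotype mean."""
        priors = priors.resolved(data.y)
        mu = priors.fix_mu if priors.fix_mu is not None else float(np.mean(data.y))
        vy = float(np.var(data.y)) or 1.0
        return cls(
            mu=mu,
            alpha=np.zeros(data.p),
            theta=np.zeros(data.p, dtype=np.int64),
            sigma2_eps=(
                priors.fix_sigma2_eps if priors.fix_sigma2_eps is not None else vy
            ),
            sigma2_alpha=(
                priors.fix_sigma2_alpha
                if priors.fix_sigma2_alpha is not None
                else priors.s_alpha
            ),
            pi=(
                priors.fix_pi
                if priors.fix_pi is not None
                else priors.a0 / (priors.a0 + priors.b0)
            ),
            resid=data.y - (priors.fix_mu if priors.fix_mu is not None else np.mean(data.y)),
        )


@dataclass
class ChainConfig:
    """MCMC schedule: 15,000 sweeps with a 1,000-sweep burn-in by default."""

    n_iter: int = 15_000
    burn_in: int = 1_000
    seed: int | None = None
    thin: int = 1
    recompute_resid_every: int = 1_000

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ConfigError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Per-SNP posterior summaries of one chain.

    ``ppa[j]`` is exactly the fraction of retained sweeps with theta_j = 1;
    ``alpha_mean[j]`` averages theta_j * alpha_j over retained sweeps (zero
    contribution while excluded); ``k_point`` is the posterior mode of the
    model size, ties broken toward the smaller value.
    """

    snp_ids: np.ndarray
    ppa: np.ndarray
    alpha_mean: np.ndarray
    k_samples: np.ndarray
    k_point: int
    n_retained: int
    mu_samples: np.ndarray | None = None
    sigma2_eps_samples: np.ndarray | None = None
    pi_samples: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def impute_mean_dosage(X: np.ndarray) -> np.ndarray:
    """Replace NaN dosages with the column mean of the observed dosages."""
    X = np.array(X, dtype=np.float64)
    if not np.isnan(X).any():
        return X
    means = np.nanmean(np.where(np.isnan(X).all(axis=0), 0.0, X), axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(means, idx[1])
    return X


def sample_scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float) -> float:
    """Draw from ScaledInv-chi2(df, scale) = df*scale / chi2_df."""
    return df * scale / rng.chisquare(df)


def posterior_mode_k(k_samples: np.ndarray) -> int:
    """Posterior mode of the model size; ties go to the smaller k."""
    counts = np.bincount(np.asarray(k_samples, dtype=np.int64))
    return int(np.argmax(counts))


# --------------------------------------------------------------------------
# full-conditional updates (reference NumPy path)
# --------------------------------------------------------------------------

def sample_residual_variance(
    state: ChainState, data: ModelData, priors: Priors, rng: np.random.Generator
) -> float:
    """Draw sigma2_eps from ScaledInv-chi2(v_eps + n, (v_eps S_eps + r'r)/(v_eps + n))."""
    rss = float(state.resid @ state.resid)
    if not np.isfinite(rss):
        raise InvalidStateError("non-finite residual sum of squares")
    df = priors.v_eps + data.n
    scale = (priors.v_eps * priors.s_eps + rss) / df
    return sample_scaled_inv_chi2(rng, df, scale)


def sample_intercept(
    state: ChainState, data: ModelData, rng: np.random.Generator
) -> float:
    """Draw mu from Normal(mean(y - X(theta o alpha)), sigma2_eps / n).

    The caller must refresh ``state.resid`` with the returned intercept.
    """
    if data.n == 0:
        raise InvalidDataError("cannot sample an intercept with n = 0")
    m = float(np.mean(state.resid)) + state.mu
    return float(rng.normal(m, np.sqrt(state.sigma2_eps / data.n)))


def inclusion_probability(
    u_j: float, c_jj: float, sigma2_eps: float, sigma2_alpha: float, pi: float
) -> float:
    """P(theta_j = 1 | rest) from the collapsed likelihood of u_j = x_j' r_{-j}.

    Under exclusion u_j ~ N(0, c_jj sigma2_eps); under inclusion, with
    alpha_j integrated over its slab, u_j ~ N(0, c_jj sigma2_eps +
    c_jj^2 sigma2_alpha).  Combined with the prior odds pi : (1 - pi) in
    log space for stability.
    """
    if c_jj <= 0:
        raise InvalidDataError("c_jj must be > 0 (monomorphic column?)")
    if not (0.0 <= pi <= 1.0):
        raise InvalidDataError("pi must lie in [0, 1]")
    if pi == 0.0:
        return 0.0
    if pi == 1.0:
        return 1.0
    v0 = c_jj * sigma2_eps
    v1 = v0 + c_jj * c_jj * sigma2_alpha
    llr = 0.5 * np.log(v0 / v1) + 0.5 * u_j * u_j * (1.0 / v0 - 1.0 / v1)
    return float(expit(np.log(pi) - np.log1p(-pi) + llr))


def sample_effect_and_indicator(
    j: int, state: ChainState, data: ModelData, rng: np.random.Generator
) -> tuple[int, float]:
    """One partially collapsed (theta_j, alpha_j) update.

    Removes SNP j's contribution to form r_{-j}, draws theta_j from its
    collapsed Bernoulli conditional, then (if included) alpha_j from
    Normal(u_j / c_j, sigma2_eps / c_j) with c_j = x_j'x_j +
    sigma2_eps / sigma2_alpha; the residual is updated incrementally.
    """
    x = data.X[:, j]
    c_jj = float(x @ x)
    r_minus = state.resid + state.theta[j] * state.alpha[j] * x
    u = float(x @ r_minus)
    p1 = inclusion_probability(u, c_jj, state.sigma2_eps, state.sigma2_alpha, state.pi)
    if rng.random() < p1:
        c_j = c_jj + state.sigma2_eps / state.sigma2_alpha
        a = float(rng.normal(u / c_j, np.sqrt(state.sigma2_eps / c_j)))
        if not np.isfinite(a):
            raise InvalidStateError("non-finite effect draw")
        theta_j = 1
    else:
        theta_j, a = 0, 0.0
    state.theta[j] = theta_j
    state.alpha[j] = a
    state.resid = r_minus - theta_j * a * x
    return theta_j, a


def sample_slab_variance(
    state: ChainState, priors: Priors, rng: np.random.Generator
) -> float:
    """Draw the shared slab variance from its scaled-inverse-chi-square FCPF.

    Pools the squared effects of the currently included SNPs; with an empty
    model this is a draw from the prior ScaledInv-chi2(v_alpha, S_alpha).
    """
    k = state.k
    ssa = float(np.sum((state.theta * state.alpha) ** 2))
    df = priors.v_alpha + k
    scale = (priors.v_alpha * priors.s_alpha + ssa) / df
    return sample_scaled_inv_chi2(rng, df, scale)


def sample_pi(k: int, p: int, priors: Priors, rng: np.random.Generator) -> float:
    """Draw pi from its Beta(a0 + k, b0 + p - k) posterior."""
    if k > p or k < 0:
        raise InvalidStateError(f"invalid inclusion count k={k} for p={p}")
    return float(rng.beta(priors.a0 + k, priors.b0 + p - k))


def gibbs_step(
    state: ChainState,
    data: ModelData,
    priors: Priors,
    rng: np.random.Generator,
) -> ChainState:
    """One full Gibbs sweep in the canonical order.

    sigma2_eps, then mu, then (theta_j, alpha_j) for j = 1..p in ascending
    column order, then sigma2_alpha, then pi.  Fixed-value hooks skip the
    corresponding draws.  Mutates and returns ``state``.
    """
    priors = priors.resolved(data.y)
    if priors.fix_sigma2_eps is None:
        state.sigma2_eps = sample_residual_variance(state, data, priors, rng)
    if priors.fix_mu is None:
        new_mu = sample_intercept(state, data, rng)
        state.resid = state.resid - (new_mu - state.mu)
        state.mu = new_mu
    for j in range(data.p):
        x = data.X[:, j]
        if float(x @ x) == 0.0:
            continue  # monomorphic: excluded from updates
        sample_effect_and_indicator(j, state, data, rng)
    if priors.fix_sigma2_alpha is None:
        state.sigma2_alpha = sample_slab_variance(state, priors, rng)
    if priors.fix_pi is None:
        state.pi = sample_pi(state.k, data.p, priors, rng)
    return state


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class SpikeSlabRegressor(RegressorMixin, BaseEstimator):
    """Bayesian spike-and-slab regression over all SNPs simultaneously.

    Fits the linear model y = mu + X (theta o alpha) + eps by Gibbs
    sampling and summarises the posterior per SNP.  Designed for the
    rare-variant association setting: all variants are modelled jointly,
    each SNP's evidence is reported as a posterior probability of
    association, and the posterior of the model size k estimates how many
    SNPs are associated with the trait.

    Parameters
    ----------
    n_iter : int, default=15000
        Total Gibbs sweeps.
    burn_in : int, default=1000
        Initial sweeps discarded before summarising.
    thin : int, default=1
        Keep every ``thin``-th post-burn-in sweep.
    random_state : int or None
        Seed for the (single, fixed-order) random stream of the chain.
    v_eps, s_eps : float
        Residual-variance prior ScaledInv-chi2(v_eps, s_eps); ``s_eps=None``
        resolves to var(y)/2.
    v_alpha, s_alpha : float
        Slab-variance prior; ``s_alpha=None`` resolves to
        var(y)/(2*expected_k).
    a0, b0 : float
        Beta prior on the inclusion probability pi.
    expected_k : int, default=10
        Prior guess of the associated-SNP count, used only to scale
        ``s_alpha`` when it is left unset.
    fix_sigma2_eps, fix_sigma2_alpha, fix_pi, fix_mu : float or None
        Hold the parameter fixed and skip its update (validation hooks).
    per_locus_slab : bool, default=False
        Give each SNP its own slab variance (BayesB-style) instead of the
        default single shared slab variance pooled over included effects.
    recompute_resid_every : int, default=1000
        Sweeps between full recomputations of the running residual.

    Attributes
    ----------
    ppa_ : ndarray of shape (p,)
        Posterior probability of association per SNP.
    alpha_mean_ : ndarray of shape (p,)
        Posterior mean effect (zero while excluded).
    intercept_ : float
        Posterior mean intercept.
    k_samples_ : ndarray
        Retained draws of the model size.
    k_point_ : int
        Posterior mode of k (ties toward the smaller value).
    monomorphic_ : ndarray of bool
        Columns excluded from updates (x_j'x_j = 0); their PPA is 0.
    """

    def __init__(
        self,
        n_iter: int = 15_000,
        burn_in: int = 1_000,
        thin: int = 1,
        random_state: int | None = None,
        v_eps: float = 10.0,
        s_eps: float | None = None,
        v_alpha: float = 4.0,
        s_alpha: float | None = None,
        a0: float = 1.0,
        b0: float = 1.0,
        expected_k: int = 10,
        fix_sigma2_eps: float | None = None,
        fix_sigma2_alpha: float | None = None,
        fix_pi: float | None = None,
        fix_mu: float | None = None,
        per_locus_slab: bool = False,
        recompute_resid_every: int = 1_000,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state
        self.v_eps = v_eps
        self.s_eps = s_eps
        self.v_alpha = v_alpha
        self.s_alpha = s_alpha
        self.a0 = a0
        self.b0 = b0
        self.expected_k = expected_k
        self.fix_sigma2_eps = fix_sigma2_eps
        self.fix_sigma2_alpha = fix_sigma2_alpha
        self.fix_pi = fix_pi
        self.fix_mu = fix_mu
        self.per_locus_slab = per_locus_slab
        self.recompute_resid_every = recompute_resid_every

    # ------------------------------------------------------------------
    def _priors(self) -> Priors:
        return Priors(
            s_alpha=self.s_alpha,
            v_alpha=self.v_alpha,
            s_eps=self.s_eps,
            v_eps=self.v_eps,
            a0=self.a0,
            b0=self.b0,
            expected_k=self.expected_k,
            fix_sigma2_eps=self.fix_sigma2_eps,
            fix_sigma2_alpha=self.fix_sigma2_alpha,
            fix_pi=self.fix_pi,
            fix_mu=self.fix_mu,
        )

    def fit(self, X, y):
        """Run the Gibbs chain on (X, y) and store posterior summaries."""
        config = ChainConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            seed=None,
            thin=self.thin,
            recompute_resid_every=self.recompute_resid_every,
        )
        X = impute_mean_dosage(np.asarray(X, dtype=np.float64))
        data = ModelData(y=np.asarray(y, dtype=np.float64), X=X)
        priors = self._priors().resolved(data.y)

        rs = check_random_state(self.random_state)
        seed = int(rs.randint(0, 2**31 - 1))

        Xf = np.asfortranarray(data.X)
        G = np.asfortranarray(data.X.T @ data.X)
        cjj = np.ascontiguousarray(np.diag(G))
        col_sum = data.X.sum(axis=0)
        active = cjj > 0.0
        if data.p > 0 and not active.any():
            raise InvalidDataError("every genotype column is monomorphic")

        (
            ppa,
            alpha_mean,
            k_samples,
            mu_samples,
            s2e_samples,
            pi_samples,
            resid,
            mu,
            theta,
            alpha,
        ) = _kernel.gibbs_chain(
            np.ascontiguousarray(data.y),
            Xf,
            G,
            np.ascontiguousarray(col_sum),
            cjj,
            active,
            config.n_iter,
            config.burn_in,
            config.thin,
            float(priors.v_eps),
            float(priors.s_eps),
            float(priors.v_alpha),
            float(priors.s_alpha),
            float(priors.a0),
            float(priors.b0),
            priors.fix_sigma2_eps is not None,
            float(priors.fix_sigma2_eps or 0.0),
            priors.fix_sigma2_alpha is not None,
            float(priors.fix_sigma2_alpha or 0.0),
            priors.fix_pi is not None,
            float(priors.fix_pi or 0.0),
            priors.fix_mu is not None,
            float(priors.fix_mu if priors.fix_mu is not None else 0.0),
            bool(self.per_locus_slab),
            int(config.recompute_resid_every),
            seed,
        )

        self.n_features_in_ = data.p
        self.ppa_ = ppa
        self.alpha_mean_ = alpha_mean
        self.k_samples_ = k_samples
        self.k_point_ = posterior_mode_k(k_samples) if len(k_samples) else 0
        self.n_retained_ = len(k_samples)
        self.mu_samples_ = mu_samples
        self.sigma2_eps_samples_ = s2e_samples
        self.pi_samples_ = pi_samples
        self.intercept_ = float(np.mean(mu_samples))
        self.monomorphic_ = ~active
        self._final_resid = resid
        self._final_mu = mu
        self._final_theta = theta
        self._final_alpha = alpha
        self._chain_seed = seed
        return self

    def predict(self, X):
        """Posterior-mean prediction: intercept_ + X @ alpha_mean_."""
        if not hasattr(self, "alpha_mean_"):
            raise InvalidStateError("estimator is not fitted")
        X = impute_mean_dosage(np.asarray(X, dtype=np.float64))
        return self.intercept_ + X @ self.alpha_mean_

    def summary(self, snp_ids=None) -> PosteriorSummary:
        """Package fitted attributes as a :class:`PosteriorSummary`."""
        if not hasattr(self, "ppa_"):
            raise InvalidStateError("estimator is not fitted")
        if snp_ids is None:
            snp_ids = np.array(
                [f"snp_{j}" for j in range(self.n_features_in_)], dtype=object
            )
        return PosteriorSummary(
            snp_ids=np.asarray(snp_ids, dtype=object),
            ppa=self.ppa_,
            alpha_mean=self.alpha_mean_,
            k_samples=self.k_samples_,
            k_point=self.k_point_,
            n_retained=self.n_retained_,
            mu_samples=self.mu_samples_,
            sigma2_eps_samples=self.sigma2_eps_samples_,
            pi_samples=self.pi_samples_,
            meta={
                "n_iter": self.n_iter,
                "burn_in": self.burn_in,
                "thin": self.thin,
                "seed": getattr(self, "_chain_seed", None),
            },
        )


def run_chain(
    data: ModelData, priors: Priors | None = None, config: ChainConfig | None = None
) -> PosteriorSummary:
    """Fit one Gibbs chain and return its posterior summary.

    Thin wrapper over :class:`SpikeSlabRegressor` keeping the functional
    interface: validated :class:`ModelData` in, :class:`PosteriorSummary`
    out.
    """
    priors = priors if priors is not None else Priors()
    config = config if config is not None else ChainConfig()
    est = SpikeSlabRegressor(
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        random_state=config.seed,
        v_eps=priors.v_eps,
        s_eps=priors.s_eps,
        v_alpha=priors.v_alpha,
        s_alpha=priors.s_alpha,
        a0=priors.a0,
        b0=priors.b0,
        expected_k=priors.expected_k,
        fix_sigma2_eps=priors.fix_sigma2_eps,
        fix_sigma2_alpha=priors.fix_sigma2_alpha,
        fix_pi=priors.fix_pi,
        fix_mu=priors.fix_mu,
        recompute_resid_every=config.recompute_resid_every,
    )
    est.fit(data.X, data.y)
    return est.summary(snp_ids=data.snp_ids)
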