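"""Exact posterior by enumeration over all 2^p models.

With sigma2_eps, sigma2_alpha and pi held fixed, the intercept handled by
centring y, and the slab integrated out, the marginal likelihood of each
model gamma in {0,1}^p is Gaussian:

    y | gamma ~ N(0, sigma2_eps I + sigma2_alpha X_gamma X_gamma')

so the posterior over models — and hence each SNP's exact inclusion
probability — can be computed in closed form for small p.  This is the
validation surface for the Gibbs sampler: its inclusion frequencies must
converge to these exact values.

Determinants and quadratic forms use the matrix-inversion lemma on the
|gamma| x |gamma| inner matrix, so enumeration at the p <= 14 cap is cheap
even for large n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import InvalidDataError
from .model import ModelData

__all__ = ["FixedParamPosterior", "enumerate_posterior", "MAX_ENUM_P"]

MAX_ENUM_P = 14


@dataclass
class FixedParamPosterior:
    """Exact fixed-hyperparameter posterior over all models.

    ``model_weights[m]`` is the posterior probability of the model whose
    included-SNP set is ``models[m]`` (bitmask order, bit j = SNP j);
    weights sum to 1.  ``ppa_exact[j]`` sums the weights of all models
    containing SNP j, and ``k_dist_exact[k]`` those of all size-k models.
    """

    models: np.ndarray
    model_weights: np.ndarray
    ppa_exact: np.ndarray
    k_dist_exact: np.ndarray


def _model_loglik(
    yty: float,
    b: np.ndarray,
    G_sub: np.ndarray,
    n: int,
    sigma2_eps: float,
    sigma2_alpha: float,
) -> float:
    """log N(y; 0, s2e I + s2a X_g X_g') via the inversion lemma.

    b = X_g' y, G_sub = X_g' X_g.  B = I/s2a + G_sub/s2e gives
    log|Sigma| = n log s2e + m log s2a + log|B| and
    y'Sigma^-1 y = y'y/s2e - b' B^-1 b / s2e^2.
    """
    m = len(b)
    if m == 0:
        logdet = n * np.log(sigma2_eps)
        quad = yty / sigma2_eps
    else:
        B = np.eye(m) / sigma2_alpha + G_sub / sigma2_eps
        sign, logdet_B = np.linalg.slogdet(B)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "inner matrix not positive definite (singular covariance)"
            )
        logdet = n * np.log(sigma2_eps) + m * np.log(sigma2_alpha) + logdet_B
        quad = yty / sigma2_eps - b @ np.linalg.solve(B, b) / sigma2_eps**2
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def enumerate_posterior(
    data: ModelData,
    sigma2_eps: float,
    sigma2_alpha: float,
    pi: float,
) -> FixedParamPosterior:
    """Exact model posterior at fixed (sigma2_eps, sigma2_alpha, pi).

    ``data.y`` should be centred; the intercept is treated as 0, matching
    the sampler's ``fix_mu=0`` hook.  Refuses p > 14 (2^p models).
    """
    p = data.p
    if p > MAX_ENUM_P:
        raise InvalidDataError(
            f"enumeration capped at p <= {MAX_ENUM_P}, got p = {p}"
        )
    if sigma2_eps <= 0 or sigma2_alpha < 0:
        raise InvalidDataError("variances must be positive")
    if not (0.0 <= pi <= 1.0):
        raise InvalidDataError("pi must lie in [0, 1]")

    n = data.n
    models = np.arange(2**p, dtype=np.int64)
    bits = (models[:, None] >> np.arange(p)) & 1  # (2^p, p)

    if pi == 0.0 or pi == 1.0:
        weights = np.zeros(2**p)
        weights[-1 if pi == 1.0 else 0] = 1.0
    else:
        yty = float(data.y @ data.y)
        Xty = data.X.T @ data.y
        G = data.X.T @ data.X
        log_pi, log_1mpi = np.log(pi), np.log1p(-pi)
        logpost = np.empty(2**p)
        for m_idx, mask in enumerate(bits.astype(bool)):
            k = int(mask.sum())
            ll = _model_loglik(
                yty, Xty[mask], G[np.ix_(mask, mask)], n, sigma2_eps, sigma2_alpha
            )
            logpost[m_idx] = ll + k * log_pi + (p - k) * log_1mpi
        logz = logsumexp(logpost)
        weights = np.exp(logpost - logz)
        weights[weights < 1e-300] = 0.0
        weights /= weights.sum()

    ppa = bits.T @ weights
    sizes = bits.sum(axis=1)
    k_dist = np.bincount(sizes, weights=weights, minlength=p + 1)
    return FixedParamPosterior(
        models=models, model_weights=weights, ppa_exact=ppa, k_dist_exact=k_dist
    )
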