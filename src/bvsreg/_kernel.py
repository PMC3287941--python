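"""Compiled Gibbs-sampling kernel.

One full sweep updates, in order: the residual variance, the intercept, every
(theta_j, alpha_j) pair in ascending column order, the slab variance(s), and
the inclusion probability pi.  The kernel maintains two running quantities so
a sweep over p SNPs costs O(p + (#changed SNPs) * (n + p)) instead of O(n*p):

* ``resid``  — the current residual y - mu - X (theta o alpha);
* ``z``      — X' resid, so the sufficient scalar for SNP j's inclusion
  decision, u_j = x_j' r_{-j}, is read off as z[j] + theta_j alpha_j G[j,j].

Both are rebuilt from scratch every ``recompute_every`` sweeps to bound
floating-point drift.  All randomness flows through numba's np.random state,
seeded once at entry, with a fixed draw order: one chi-square for the
residual variance (unless fixed), one normal for the intercept (unless
fixed), one uniform per polymorphic SNP plus one normal per included SNP,
the slab-variance chi-square draw(s) (unless fixed), one beta for pi
(unless fixed).
"""

import numpy as np
from numba import njit

__all__ = ["gibbs_chain"]


@njit(cache=False)
def gibbs_chain(
    y,
    X,
    G,
    col_sum,
    cjj,
    active,
    n_iter,
    burn_in,
    thin,
    v_eps,
    s_eps,
    v_alpha,
    s_alpha,
    a0,
    b0,
    fix_eps_flag,
    fix_eps,
    fix_alpha_flag,
    fix_alpha,
    fix_pi_flag,
    fix_pi,
    fix_mu_flag,
    fix_mu,
    per_locus,
    recompute_every,
    seed,
):  # pragma: no cover - exercised via model.run_chain
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]

    n_retained = (n_iter - burn_in + thin - 1) // thin

    # --- initialization: neutral start, no data peeking beyond y moments ---
    mu = fix_mu if fix_mu_flag else y.sum() / n
    vy = 0.0
    for i in range(n):
        d = y[i] - y.sum() / n
        vy += d * d
    vy /= n
    if vy <= 0.0:
        vy = 1.0
    sigma2_eps = fix_eps if fix_eps_flag else vy
    s2a_init = fix_alpha if fix_alpha_flag else s_alpha
    sigma2_a = np.full(p, s2a_init)
    pi = fix_pi if fix_pi_flag else a0 / (a0 + b0)

    alpha = np.zeros(p)
    theta = np.zeros(p, dtype=np.int64)

    resid = y - mu
    z = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * resid[i]
        z[j] = acc

    ppa_counts = np.zeros(p)
    alpha_acc = np.zeros(p)
    k_samples = np.zeros(n_retained, dtype=np.int64)
    mu_samples = np.zeros(n_retained)
    s2e_samples = np.zeros(n_retained)
    pi_samples = np.zeros(n_retained)

    t = 0
    for s in range(n_iter):
        # residual variance | rest : scaled inverse chi-square
        if not fix_eps_flag:
            rss = 0.0
            for i in range(n):
                rss += resid[i] * resid[i]
            if not np.isfinite(rss):
                raise RuntimeError("non-finite residual sum of squares")
            df = v_eps + n
            scale = (v_eps * s_eps + rss) / df
            sigma2_eps = df * scale / np.random.chisquare(df)

        # intercept | rest : Normal(mean(y - X(theta o alpha)), sigma2_eps/n)
        if not fix_mu_flag:
            rbar = 0.0
            for i in range(n):
                rbar += resid[i]
            m = rbar / n + mu
            new_mu = np.random.normal(m, np.sqrt(sigma2_eps / n))
            d = new_mu - mu
            mu = new_mu
            for i in range(n):
                resid[i] -= d
            for j in range(p):
                z[j] -= d * col_sum[j]

        # (theta_j, alpha_j) | rest, partially collapsed over alpha_j
        log_prior_odds = np.log(pi) - np.log1p(-pi)
        for j in range(p):
            if not active[j]:
                continue
            u = z[j] + theta[j] * alpha[j] * cjj[j]
            s2a = sigma2_a[j]
            v0 = cjj[j] * sigma2_eps
            v1 = v0 + cjj[j] * cjj[j] * s2a
            llr = 0.5 * np.log(v0 / v1) + 0.5 * u * u * (1.0 / v0 - 1.0 / v1)
            logit = log_prior_odds + llr
            if logit > 0.0:
                p1 = 1.0 / (1.0 + np.exp(-logit))
            else:
                e = np.exp(logit)
                p1 = e / (1.0 + e)
            old = theta[j] * alpha[j]
            if np.random.random() < p1:
                c_j = cjj[j] + sigma2_eps / s2a
                a = np.random.normal(u / c_j, np.sqrt(sigma2_eps / c_j))
                if not np.isfinite(a):
                    raise RuntimeError("non-finite effect draw")
                theta[j] = 1
                alpha[j] = a
            else:
                theta[j] = 0
                alpha[j] = 0.0
            d = theta[j] * alpha[j] - old
            if d != 0.0:
                for i in range(n):
                    resid[i] -= d * X[i, j]
                for q in range(p):
                    z[q] -= d * G[q, j]

        k = 0
        for j in range(p):
            k += theta[j]

        # slab variance | rest
        if not fix_alpha_flag:
            if per_locus:
                for j in range(p):
                    if not active[j]:
                        continue
                    if theta[j] == 1:
                        df_a = v_alpha + 1.0
                        sc = (v_alpha * s_alpha + alpha[j] * alpha[j]) / df_a
                        sigma2_a[j] = df_a * sc / np.random.chisquare(df_a)
                    else:
                        sigma2_a[j] = v_alpha * s_alpha / np.random.chisquare(v_alpha)
            else:
                ssa = 0.0
                for j in range(p):
                    if theta[j] == 1:
                        ssa += alpha[j] * alpha[j]
                df_a = v_alpha + k
                sc = (v_alpha * s_alpha + ssa) / df_a
                val = df_a * sc / np.random.chisquare(df_a)
                for j in range(p):
                    sigma2_a[j] = val

        # pi | rest : Beta(a0 + k, b0 + p - k)
        if not fix_pi_flag:
            pi = np.random.beta(a0 + k, b0 + p - k)

        # bound incremental drift
        if recompute_every > 0 and (s + 1) % recompute_every == 0:
            for i in range(n):
                acc = y[i] - mu
                for j in range(p):
                    if theta[j] == 1:
                        acc -= alpha[j] * X[i, j]
                resid[i] = acc
            for j in range(p):
                acc = 0.0
                for i in range(n):
                    acc += X[i, j] * resid[i]
                z[j] = acc

        if s >= burn_in and (s - burn_in) % thin == 0:
            for j in range(p):
                ppa_counts[j] += theta[j]
                alpha_acc[j] += alpha[j]
            k_samples[t] = k
            mu_samples[t] = mu
            s2e_samples[t] = sigma2_eps
            pi_samples[t] = pi
            t += 1

    ppa = ppa_counts / n_retained
    alpha_mean = alpha_acc / n_retained
    return ppa, alpha_mean, k_samples, mu_samples, s2e_samples, pi_samples, resid, mu, theta, alpha
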