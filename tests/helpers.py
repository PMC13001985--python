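"""Shared test oracles and frozen expected values.

The Kalman oracle here conditions the explicitly assembled joint Gaussian of
(states, observations) — dense linear algebra with no recursions — so it is
an independent check of the filtering code paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: The 40 coefficient labels of the default design (frozen expectation).
EXPECTED_PARAM_LABELS = sorted(
    [
        "beta_ENAP", "beta_ENAP_MPDSR", "beta_ENAP_QUINH", "beta_ENAP_SMGL",
        "beta_ENAP_UNNSC", "beta_MPDSR", "beta_MPDSR_QUINH", "beta_NHSDP",
        "beta_NHSDP_MPDSR", "beta_NHSDP_QUINH", "beta_NHSDP_SMGL",
        "beta_NHSDP_UNNSC", "beta_QUINH", "beta_RMNCAH", "beta_RMNCAH_MPDSR",
        "beta_RMNCAH_NHSDP", "beta_RMNCAH_QUINH", "beta_RMNCAH_SMGL",
        "beta_RMNCAH_UNNSC", "beta_SDGintroAfter", "beta_SDGintroBefore",
        "beta_SMGL", "beta_SMGL_MPDSR", "beta_SMGL_QUINH", "beta_SMGL_UNNSC",
        "beta_UNNSC", "beta_UNNSC_MPDSR", "beta_UNNSC_QUINH", "beta_cost",
        "beta_hcareaccess", "beta_hcenteraccess", "beta_healthfacdensity",
        "beta_hholdinc", "beta_maternaleduc", "beta_regioncentral",
        "beta_regioneastern", "beta_regionnorthern", "beta_regionwestern",
        "beta_seasonDry", "beta_seasonWet",
    ]
)


def joint_gaussian_oracle(X, y, V, W, m0, c0, first_step_evolves=True):
    """Exact filtered moments and log-likelihood by dense joint conditioning.

    Returns (filtered_means, filtered_covs, log_likelihood) where entry t is
    the conditional of state t given observations 1..t.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    T, p = X.shape
    W = np.asarray(W, float) * np.eye(p) if np.ndim(W) == 0 else np.asarray(W, float)
    c0 = np.asarray(c0, float) * np.eye(p) if np.ndim(c0) == 0 else np.asarray(c0, float)
    m0 = np.broadcast_to(np.asarray(m0, float), (p,))

    # number of evolution-noise increments accumulated before observation t
    k = np.arange(1, T + 1) if first_step_evolves else np.arange(0, T)

    def cov_state(t, u):
        return c0 + min(k[t], k[u]) * W

    mean_y = X @ m0
    cov_y = np.empty((T, T))
    for t in range(T):
        for u in range(T):
            cov_y[t, u] = X[t] @ cov_state(t, u) @ X[u]
        cov_y[t, t] += V
    loglik = stats.multivariate_normal.logpdf(y, mean_y, cov_y)

    means, covs = [], []
    for t in range(T):
        idx = slice(0, t + 1)
        c_sy = np.column_stack([cov_state(t, u) @ X[u] for u in range(t + 1)])
        s_yy = cov_y[idx, idx]
        sol = np.linalg.solve(s_yy, (y[idx] - mean_y[idx]))
        means.append(m0 + c_sy @ sol)
        covs.append(cov_state(t, t) - c_sy @ np.linalg.solve(s_yy, c_sy.T))
    return means, covs, float(loglik)


def random_instance(rng, T=None, p=None, first_step_evolves=True):
    """A random small DLM instance with simulated data for oracle checks."""
    T = T or int(rng.integers(2, 7))
    p = p or int(rng.integers(1, 4))
    X = rng.normal(size=(T, p))
    V = float(rng.uniform(0.3, 2.0))
    A = rng.normal(size=(p, p)) * 0.4
    W = A @ A.T + 0.05 * np.eye(p)
    B = rng.normal(size=(p, p)) * 0.6
    c0 = B @ B.T + 0.2 * np.eye(p)
    m0 = rng.normal(size=p)
    # simulate y from the model itself
    k0 = 1 if first_step_evolves else 0
    beta = rng.multivariate_normal(m0, c0)
    ys = np.empty(T)
    for t in range(T):
        if t > 0 or first_step_evolves:
            beta = rng.multivariate_normal(beta, W)
        ys[t] = X[t] @ beta + rng.normal(0, np.sqrt(V))
    _ = k0
    return X, ys, V, W, m0, c0
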