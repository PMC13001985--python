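"""Gaussian state-space engine: Kalman recursions, FFBS, forecasting.

Observation: ``y_t = x_t' beta_t + eps_t``, ``eps_t ~ N(0, V)``.
Evolution:   ``beta_t = beta_{t-1} + omega_t``, ``omega_t ~ N(0, W)``
(random-walk states, identity transition).

The filter uses the Joseph-form covariance update and symmetrizes every
covariance.  ``first_step_evolves`` controls whether the evolution noise is
applied before the first observation: with the default ``True`` the t=1
prior is ``N(m0, c0 + W)``; with ``False`` it is exactly ``N(m0, c0)``,
which matches placing the initial-state prior directly on the first state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "DLMSpec",
    "KalmanMoments",
    "ForecastResult",
    "FilterStep",
    "filter_step",
    "kalman_filter",
    "ffbs_draw",
    "ffbs_local_level",
    "forecast",
]

_PSD_TOL = 1e-10


def _as_cov(value, p: int) -> np.ndarray:
    """Coerce a scalar or matrix to a (p, p) covariance array."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = float(arr) * np.eye(p)
    if arr.shape != (p, p):
        raise ValueError(f"covariance must be scalar or ({p}, {p}), got {arr.shape}")
    return 0.5 * (arr + arr.T)


def _check_psd(mat: np.ndarray, name: str) -> None:
    eigmin = float(np.linalg.eigvalsh(mat).min()) if mat.size else 0.0
    bound = _PSD_TOL * max(1.0, float(np.abs(mat).max()))
    if eigmin < -bound:
        raise ValueError(f"{name} is not positive semidefinite (min eig {eigmin:g})")


@dataclass(frozen=True)
class DLMSpec:
    """Specification of a Gaussian random-walk DLM."""

    p: int
    obs_variance: float
    state_cov: np.ndarray
    m0: np.ndarray
    c0: np.ndarray
    first_step_evolves: bool = True

    def __post_init__(self) -> None:
        if self.obs_variance <= 0:
            raise ValueError(f"obs_variance must be > 0, got {self.obs_variance}")
        object.__setattr__(self, "state_cov", _as_cov(self.state_cov, self.p))
        object.__setattr__(self, "c0", _as_cov(self.c0, self.p))
        object.__setattr__(
            self, "m0", np.broadcast_to(np.asarray(self.m0, float), (self.p,)).copy()
        )
        _check_psd(self.state_cov, "state_cov")
        if float(np.linalg.eigvalsh(self.c0).min()) <= 0:
            raise ValueError("c0 must be positive definite")

    @classmethod
    def local_level(
        cls,
        obs_variance: float,
        state_variance: float,
        m0: float = 0.0,
        c0: float = 3.0,
        first_step_evolves: bool = False,
    ) -> "DLMSpec":
        """Scalar local-level model with the prior placed on the first state."""
        return cls(
            p=1,
            obs_variance=obs_variance,
            state_cov=np.array([[state_variance]]),
            m0=np.array([m0]),
            c0=np.array([[c0]]),
            first_step_evolves=first_step_evolves,
        )

    @classmethod
    def hybrid(
        cls,
        obs_variance: float,
        level_variance: float,
        coef_prior_mean: np.ndarray,
        coef_prior_var: np.ndarray,
        level_mean: float = 0.0,
        level_var: float = 3.0,
    ) -> "DLMSpec":
        """Evolving scalar level (state 0) plus static regression states.

        The regression coefficients get zero evolution variance, so only the
        level moves; their priors enter through ``m0``/``c0``.  Design rows
        must be prefixed with a leading 1 for the level.
        """
        coef_prior_mean = np.asarray(coef_prior_mean, float)
        coef_prior_var = np.asarray(coef_prior_var, float)
        p = coef_prior_mean.size + 1
        W = np.zeros((p, p))
        W[0, 0] = level_variance
        return cls(
            p=p,
            obs_variance=obs_variance,
            state_cov=W,
            m0=np.concatenate([[level_mean], coef_prior_mean]),
            c0=np.diag(np.concatenate([[level_var], coef_prior_var])),
            first_step_evolves=False,
        )


class FilterStep(NamedTuple):
    filtered_mean: np.ndarray
    filtered_cov: np.ndarray
    one_step_mean: float
    one_step_var: float
    predicted_mean: np.ndarray
    predicted_cov: np.ndarray


def filter_step(
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    x_row: np.ndarray,
    y: float,
    V: float,
    W: np.ndarray | float,
) -> FilterStep:
    """One conjugate Gaussian update.

    Prediction: mean carries forward, covariance gains ``W``.  Update: the
    usual Kalman gain with Joseph-form covariance, equal to exact
    conditioning of the joint Gaussian of (state, observation).
    """
    prior_mean = np.asarray(prior_mean, float).ravel()
    p = prior_mean.size
    prior_cov = _as_cov(prior_cov, p)
    x = np.asarray(x_row, float).ravel()
    if x.size != p:
        raise ValueError(f"x_row has {x.size} entries, state dimension is {p}")
    if not (
        np.isfinite(prior_mean).all()
        and np.isfinite(prior_cov).all()
        and np.isfinite(x).all()
        and np.isfinite(y)
        and np.isfinite(V)
    ):
        raise ValueError("non-finite input to filter_step")
    if V <= 0:
        raise ValueError(f"V must be > 0, got {V}")

    R = prior_cov + _as_cov(W, p)
    n_t = float(x @ prior_mean)
    Rx = R @ x
    s_t = float(V + x @ Rx)
    if s_t <= 0:
        raise ValueError(f"one-step variance is nonpositive ({s_t:g})")
    k = Rx / s_t
    m = prior_mean + k * (y - n_t)
    A = np.eye(p) - np.outer(k, x)
    C = A @ R @ A.T + V * np.outer(k, k)
    C = 0.5 * (C + C.T)
    return FilterStep(m, C, n_t, s_t, prior_mean.copy(), R)


@dataclass
class KalmanMoments:
    """Moment trajectories from a full filtering pass."""

    predicted_mean: np.ndarray  # (T, p)
    predicted_cov: np.ndarray   # (T, p, p)
    filtered_mean: np.ndarray   # (T, p)
    filtered_cov: np.ndarray    # (T, p, p)
    one_step_mean: np.ndarray   # (T,)
    one_step_var: np.ndarray    # (T,)
    y: np.ndarray               # (T,)
    log_likelihood: float

    @property
    def T(self) -> int:
        return self.y.size

    @property
    def residuals(self) -> np.ndarray:
        """One-step-ahead residuals ``y_t - n_t``."""
        return self.y - self.one_step_mean

    @property
    def standardized_residuals(self) -> np.ndarray:
        return self.residuals / np.sqrt(self.one_step_var)


def _design_arrays(design) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(design, "X") and hasattr(design, "y"):
        return np.asarray(design.X, float), np.asarray(design.y, float)
    X, y = design
    return np.asarray(X, float), np.asarray(y, float)


def kalman_filter(design, spec: DLMSpec) -> KalmanMoments:
    """Run the filter over ``t = 1..T`` and accumulate the log-likelihood."""
    X, y = _design_arrays(design)
    if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] == 0:
        raise ValueError("design must be a nonempty (T, p) matrix aligned with y")
    if X.shape[1] != spec.p:
        raise ValueError(
            f"design has {X.shape[1]} columns but spec.p = {spec.p}"
        )
    T, p = X.shape
    pm = np.empty((T, p))
    pc = np.empty((T, p, p))
    fm = np.empty((T, p))
    fc = np.empty((T, p, p))
    nt = np.empty(T)
    st = np.empty(T)

    mean, cov = spec.m0, spec.c0
    zero_W = np.zeros((p, p))
    loglik = 0.0
    for t in range(T):
        W = spec.state_cov if (t > 0 or spec.first_step_evolves) else zero_W
        step = filter_step(mean, cov, X[t], y[t], spec.obs_variance, W)
        pm[t], pc[t] = step.predicted_mean, step.predicted_cov
        fm[t], fc[t] = step.filtered_mean, step.filtered_cov
        nt[t], st[t] = step.one_step_mean, step.one_step_var
        loglik += -0.5 * (
            np.log(2.0 * np.pi * step.one_step_var)
            + (y[t] - step.one_step_mean) ** 2 / step.one_step_var
        )
        mean, cov = step.filtered_mean, step.filtered_cov
    return KalmanMoments(pm, pc, fm, fc, nt, st, y.copy(), float(loglik))


def _draw_gaussian(mean: np.ndarray, cov: np.ndarray, rng, t: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    bound = _PSD_TOL * max(1.0, float(vals.max(initial=0.0)))
    if vals.min(initial=0.0) < -bound:
        raise ValueError(
            f"non-PSD covariance encountered at time index {t} "
            f"(min eig {vals.min():g})"
        )
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return mean + root @ rng.standard_normal(mean.size)


def ffbs_draw(moments: KalmanMoments, spec: DLMSpec, rng) -> np.ndarray:
    """Sample one state trajectory from the joint smoothing distribution.

    Forward moments must come from :func:`kalman_filter` under ``spec``.
    Returns a (T, p) array.
    """
    T, p = moments.filtered_mean.shape
    draws = np.empty((T, p))
    draws[-1] = _draw_gaussian(
        moments.filtered_mean[-1], moments.filtered_cov[-1], rng, T - 1
    )
    for t in range(T - 2, -1, -1):
        R = moments.predicted_cov[t + 1]  # = filtered_cov[t] + W
        C = moments.filtered_cov[t]
        # J = C R^{-1}; use pseudo-inverse when R is singular (e.g. W = 0
        # with a degenerate filtered covariance).
        try:
            J = np.linalg.solve(R, C.T).T
        except np.linalg.LinAlgError:
            J = C @ np.linalg.pinv(R, hermitian=True)
        mean = moments.filtered_mean[t] + J @ (
            draws[t + 1] - moments.predicted_mean[t + 1]
        )
        cov = C - J @ R @ J.T
        draws[t] = _draw_gaussian(mean, cov, rng, t)
    return draws


def ffbs_local_level(
    z: np.ndarray,
    V: float,
    W: float,
    m0: float,
    c0: float,
    rng,
    first_step_evolves: bool = False,
) -> np.ndarray:
    """Fast scalar FFBS for a local-level model observed as ``z_t = mu_t + eps``.

    Equivalent to :func:`kalman_filter` + :func:`ffbs_draw` with ``p = 1``
    and unit design, specialized for the Gibbs sweep's inner loop.
    """
    z = np.asarray(z, float)
    T = z.size
    if V <= 0 or W < 0 or c0 <= 0:
        raise ValueError("require V > 0, W >= 0, c0 > 0")
    m = np.empty(T)
    c = np.empty(T)
    mean, cov = m0, c0
    for t in range(T):
        R = cov + W if (t > 0 or first_step_evolves) else cov
        s = R + V
        k = R / s
        mean = mean + k * (z[t] - mean)
        cov = R - k * R
        m[t], c[t] = mean, cov
    mu = np.empty(T)
    eps = rng.standard_normal(T)
    mu[-1] = m[-1] + np.sqrt(max(c[-1], 0.0)) * eps[-1]
    for t in range(T - 2, -1, -1):
        R_next = c[t] + W
        J = c[t] / R_next if R_next > 0 else 1.0
        mean = m[t] + J * (mu[t + 1] - m[t])
        var = c[t] * (1.0 - J)
        mu[t] = mean + np.sqrt(max(var, 0.0)) * eps[t]
    return mu


@dataclass(frozen=True)
class ForecastResult:
    """Multi-step forecast with 95% predictive intervals."""

    horizon: int
    point: np.ndarray
    variance: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def forecast(
    moments: KalmanMoments,
    spec: DLMSpec,
    future_X: np.ndarray,
    h: int | None = None,
) -> ForecastResult:
    """Forecast ``h`` steps beyond the filtered sample.

    Prediction iterates without updates: the state mean stays at the final
    filtered mean and the state covariance grows by ``W`` each step, so step
    ``h`` has point forecast ``x_h' m_T`` and predictive variance
    ``V + x_h' (c_T + h W) x_h``.
    """
    future_X = np.atleast_2d(np.asarray(future_X, float))
    if h is None:
        h = future_X.shape[0]
    if h <= 0:
        raise ValueError(f"forecast horizon must be >= 1, got {h}")
    if future_X.shape[0] == 1 and h > 1:
        future_X = np.repeat(future_X, h, axis=0)
    if future_X.shape != (h, spec.p):
        raise ValueError(
            f"future design must have shape ({h}, {spec.p}), got {future_X.shape}"
        )
    m_T = moments.filtered_mean[-1]
    c_T = moments.filtered_cov[-1]
    steps = np.arange(1, h + 1)
    point = future_X @ m_T
    variance = np.array(
        [
            spec.obs_variance + x @ (c_T + k * spec.state_cov) @ x
            for k, x in zip(steps, future_X)
        ]
    )
    half = stats.norm.ppf(0.975) * np.sqrt(variance)
    return ForecastResult(
        horizon=int(h),
        point=point,
        variance=variance,
        lower=point - half,
        upper=point + half,
    )
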