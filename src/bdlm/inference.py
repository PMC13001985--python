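"""Gibbs sampling for the hybrid dynamic regression model.

Model fitted by :func:`gibbs_run`::

    y_t = mu_t + x_t' beta + eps_t,     eps_t ~ N(0, sigma2_obs)
    mu_t = mu_{t-1} + omega_t,          omega_t ~ N(0, sigma2_state)

with a scalar random-walk level ``mu_t`` over the concatenated panel order
and static regression coefficients ``beta``.  Priors (all configurable):

* ``beta_j ~ N(0.9, 1/16)`` for continuous covariates and
  ``beta_j ~ N(0.9, 1/36)`` for categorical ones, read as variances by
  default (``coef_on_precision=True`` reads them as precisions);
* ``sigma2_obs ~ Gamma(4.5, 4.5)`` placed on the variance itself and
  sampled by a log-scale random-walk Metropolis step
  (``obs_on_precision=True`` switches to the conjugate reading with the
  Gamma prior on the precision);
* ``sigma2_state ~ LogNormal(meanlog=1, sdlog=0.5)``, Metropolis on the
  log scale;
* ``mu_1 ~ N(0, 3)``.

Each sweep draws the level trajectory by FFBS, the coefficient vector from
its joint multivariate-normal full conditional (exact even under perfectly
collinear design columns), and the two variances.  Metropolis step sizes
adapt toward a 0.44 acceptance rate during burn-in only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import linalg

from .design import DesignMatrix
from .dlm import DLMSpec, KalmanMoments, ffbs_local_level, kalman_filter

__all__ = [
    "Priors",
    "ChainConfig",
    "PosteriorDraws",
    "gibbs_run",
    "posterior_summary",
    "effective_sample_size",
    "fitted_filter",
    "fitted_values",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("mean", "sd", "se", "q2.5", "q50", "q97.5")


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters of the hybrid model."""

    coef_mean: float = 0.9
    coef_var_continuous: float = 1.0 / 16.0
    coef_var_categorical: float = 1.0 / 36.0
    coef_on_precision: bool = False
    obs_shape: float = 4.5
    obs_rate: float = 4.5
    obs_on_precision: bool = False
    state_meanlog: float = 1.0
    state_sdlog: float = 0.5
    level_mean: float = 0.0
    level_var: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "coef_var_continuous", "coef_var_categorical",
            "obs_shape", "obs_rate", "state_sdlog", "level_var",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def coef_variances(self, is_continuous: np.ndarray) -> np.ndarray:
        v = np.where(
            is_continuous, self.coef_var_continuous, self.coef_var_categorical
        )
        return 1.0 / v if self.coef_on_precision else v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Priors":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run lengths and per-chain seeds."""

    n_chains: int = 4
    burn_in: int = 1000
    n_iter: int = 5000
    thin: int = 1
    seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError(
                "n_chains must be >= 2: the Gelman-Rubin diagnostic requires "
                "at least two chains"
            )
        if self.burn_in <= 0 or self.n_iter <= 0:
            raise ValueError("burn_in and n_iter must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.seeds is not None:
            if len(self.seeds) != self.n_chains:
                raise ValueError("need one seed per chain")
            if len(set(self.seeds)) != self.n_chains:
                raise ValueError("chain seeds must be distinct")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seeds" in data and data["seeds"] is not None:
            data["seeds"] = tuple(data["seeds"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PosteriorDraws:
    """Per-chain posterior samples and level-trajectory summary."""

    labels: tuple[str, ...]
    draws: np.ndarray          # (n_chains, n_kept, n_params)
    level_mean: np.ndarray     # (T,) posterior mean of mu_t, pooled
    seeds: tuple[int, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.labels):
            raise ValueError("draws must be (chains, iterations, parameters)")
        if not np.isfinite(self.draws).all():
            raise ValueError("non-finite posterior draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def extract(self, label: str) -> np.ndarray:
        """(n_chains, n_kept) array for one parameter."""
        return self.draws[:, :, self.index(label)]

    def pooled(self, label: str) -> np.ndarray:
        return self.extract(label).reshape(-1)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            pd.DataFrame(self.draws[c], columns=list(self.labels)).to_csv(
                directory / f"chain_{c + 1}.csv", index=False
            )
        pd.DataFrame({"level_mean": self.level_mean}).to_csv(
            directory / "level_mean.csv", index=False
        )
        sidecar = {
            "labels": list(self.labels),
            "n_chains": self.n_chains,
            "n_kept": self.n_kept,
            "seeds": [int(s) for s in self.seeds],
            "meta": self.meta,
        }
        (directory / "draws.json").write_text(json.dumps(sidecar, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorDraws":
        directory = Path(directory)
        sidecar = json.loads((directory / "draws.json").read_text())
        chains = [
            pd.read_csv(directory / f"chain_{c + 1}.csv").to_numpy(float)
            for c in range(sidecar["n_chains"])
        ]
        level = pd.read_csv(directory / "level_mean.csv")["level_mean"].to_numpy(float)
        return cls(
            labels=tuple(sidecar["labels"]),
            draws=np.stack(chains),
            level_mean=level,
            seeds=tuple(sidecar["seeds"]),
            meta=sidecar.get("meta", {}),
        )


def _log_target_obs_variance(v, n, ssr, shape, rate):
    # Gamma(shape, rate) prior on the variance + log-scale Jacobian.
    return (shape - 0.5 * n) * np.log(v) - 0.5 * ssr / v - rate * v


def _log_target_state_variance(w, n_inc, ssd, meanlog, sdlog):
    # LogNormal prior; its -log(w) term cancels the log-scale Jacobian.
    return (
        -0.5 * n_inc * np.log(w)
        - 0.5 * ssd / w
        - 0.5 * ((np.log(w) - meanlog) / sdlog) ** 2
    )


def _beta_marginal_draw(
    Xs: np.ndarray,
    y0: np.ndarray,
    prior_prec: np.ndarray,
    prior_mean_s: np.ndarray,
    v: float,
    w: float,
    c0: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw beta from p(beta | y, sigma2_obs, sigma2_state), level integrated out.

    With the level marginalized, ``y0 ~ N(X beta, Sigma)`` where
    ``Sigma = v I + K`` and ``K`` is the random-walk covariance of the level
    (initial variance ``c0``, increment variance ``w``).  ``K``'s precision
    ``Q`` is tridiagonal, so by the Woodbury identity
    ``Sigma^{-1} = I/v - (Q + I/v)^{-1} / v^2`` costs one banded solve.
    Collapsing the level here removes the strong level/coefficient posterior
    correlation that cripples the naive two-block sweep.
    """
    T, p = Xs.shape
    diag = np.empty(T)
    if T == 1:
        diag[0] = 1.0 / c0
    else:
        diag[:] = 2.0 / w
        diag[0] = 1.0 / c0 + 1.0 / w
        diag[-1] = 1.0 / w
    ab = np.zeros((2, T))
    ab[0] = diag + 1.0 / v
    if T > 1:
        ab[1, :-1] = -1.0 / w
    A = np.column_stack([Xs, y0])
    S = linalg.solveh_banded(ab, A, lower=True)
    SiA = A / v - S / (v * v)
    G = Xs.T @ SiA  # X' Sigma^{-1} [X | y0]
    prec = 0.5 * (G[:, :p] + G[:, :p].T) + np.diag(prior_prec)
    rhs = G[:, p] + prior_prec * prior_mean_s
    L = linalg.cholesky(prec, lower=True)
    mean = linalg.cho_solve((L, True), rhs)
    return mean + linalg.solve_triangular(L.T, rng.standard_normal(p), lower=False)


class _AdaptiveMH:
    """Log-scale random-walk Metropolis with burn-in-only step adaptation."""

    WINDOW = 25
    TARGET = 0.44

    def __init__(self, step: float = 0.5):
        self.step = step
        self._window_accepts = 0
        self._window_count = 0
        self.accepts = 0
        self.count = 0

    def update(self, value, log_target, rng, adapting: bool):
        logv = np.log(value)
        prop = np.exp(logv + self.step * rng.standard_normal())
        accept = np.log(rng.random()) < log_target(prop) - log_target(value)
        if accept:
            value = prop
        if adapting:
            self._window_accepts += accept
            self._window_count += 1
            if self._window_count == self.WINDOW:
                rate = self._window_accepts / self.WINDOW
                self.step = float(
                    np.clip(self.step * np.exp(2.0 * (rate - self.TARGET)), 1e-3, 10.0)
                )
                self._window_accepts = self._window_count = 0
        else:
            self.accepts += accept
            self.count += 1
        return value

    @property
    def acceptance_rate(self) -> float:
        return self.accepts / self.count if self.count else float("nan")


def _run_chain(
    Xs: np.ndarray,
    y: np.ndarray,
    XtX: np.ndarray,
    prior_prec: np.ndarray,
    prior_mean_s: np.ndarray,
    priors: Priors,
    chains: ChainConfig,
    rng: np.random.Generator,
    offset: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    n, p = Xs.shape
    n_keep = chains.n_iter // chains.thin
    kept = np.empty((n_keep, p + 2))
    level_sum = np.zeros(n)

    # Warm start at the ridge (conjugate full-conditional) estimate given a
    # flat level, overdispersed by +/- `offset` conditional SDs.  Starting at
    # the raw prior mean instead lets the level trajectory absorb the huge
    # initial misfit of raw-unit covariates and traps every chain in a
    # degenerate large-variance mode.
    prec0 = XtX + np.diag(prior_prec)
    mean0 = linalg.solve(prec0, Xs.T @ y + prior_prec * prior_mean_s, assume_a="pos")
    resid0 = y - Xs @ mean0
    v0 = max(float(resid0 @ resid0) / n, 1e-8)
    prec1 = XtX / v0 + np.diag(prior_prec)
    mean1 = linalg.solve(
        prec1, Xs.T @ y / v0 + prior_prec * prior_mean_s, assume_a="pos"
    )
    cond_sd = np.sqrt(np.diag(linalg.inv(prec1)))
    beta_s = mean1 + offset * cond_sd
    v_obs = v0 * float(np.exp(0.25 * offset))
    w_state = float(np.exp(priors.state_meanlog + 0.25 * offset))

    mh_obs = _AdaptiveMH()
    mh_state = _AdaptiveMH()
    stored = 0
    y0 = y - priors.level_mean
    for it in range(chains.burn_in + chains.n_iter):
        adapting = it < chains.burn_in
        # (a) beta | y, variances — level integrated out (collapsed draw)
        beta_s = _beta_marginal_draw(
            Xs, y0, prior_prec, prior_mean_s, v_obs, w_state,
            priors.level_var, rng,
        )
        # (b) level trajectory | beta, variances (FFBS)
        z = y - Xs @ beta_s
        mu = ffbs_local_level(
            z, v_obs, w_state, priors.level_mean, priors.level_var, rng
        )
        # (c) sigma2_obs | rest
        resid = z - mu
        ssr = float(resid @ resid)
        if priors.obs_on_precision:
            tau = rng.gamma(priors.obs_shape + 0.5 * n, 1.0 / (priors.obs_rate + 0.5 * ssr))
            v_obs = 1.0 / tau
        else:
            v_obs = mh_obs.update(
                v_obs,
                lambda v: _log_target_obs_variance(
                    v, n, ssr, priors.obs_shape, priors.obs_rate
                ),
                rng,
                adapting,
            )
        # (d) sigma2_state | rest
        d = np.diff(mu)
        ssd = float(d @ d)
        w_state = mh_state.update(
            w_state,
            lambda w: _log_target_state_variance(
                w, d.size, ssd, priors.state_meanlog, priors.state_sdlog
            ),
            rng,
            adapting,
        )
        if not np.isfinite(v_obs) or not np.isfinite(w_state):
            raise FloatingPointError(
                f"non-finite variance draw at iteration {it}"
            )
        if not adapting and (it - chains.burn_in) % chains.thin == 0:
            kept[stored, :p] = beta_s
            kept[stored, p] = v_obs
            kept[stored, p + 1] = w_state
            level_sum += mu
            stored += 1
    return (
        kept[:stored],
        level_sum / max(stored, 1),
        beta_s,
        mh_obs.acceptance_rate,
        mh_state.acceptance_rate,
    )


def gibbs_run(
    design: DesignMatrix,
    priors: Priors | None = None,
    chains: ChainConfig | None = None,
    seed: int | None = None,
) -> PosteriorDraws:
    """Fit the hybrid model by Gibbs sampling.

    ``seed`` feeds a root :class:`numpy.random.SeedSequence` that spawns one
    independent stream per chain; explicit ``chains.seeds`` take precedence.
    Identical seeds and inputs give identical draws.
    """
    priors = priors or Priors()
    chains = chains or ChainConfig()

    X = np.asarray(design.X, float)
    y = np.asarray(design.y, float)
    n, p = X.shape
    vbeta = priors.coef_variances(np.asarray(design.is_continuous, bool))
    b0 = np.full(p, priors.coef_mean)

    # Column scaling: an exact reparametrization (beta = beta_s / s) that
    # keeps the normal-equation matrix well conditioned for raw-unit
    # covariates such as household income.
    col_scale = np.sqrt(np.mean(X * X, axis=0))
    col_scale[col_scale == 0] = 1.0
    Xs = X / col_scale
    XtX = Xs.T @ Xs
    prior_prec = 1.0 / (vbeta * col_scale**2)
    prior_mean_s = b0 * col_scale

    if chains.seeds is not None:
        seqs = [np.random.SeedSequence(s) for s in chains.seeds]
        seeds = chains.seeds
    else:
        root = np.random.SeedSequence(seed)
        seqs = root.spawn(chains.n_chains)
        seeds = tuple(int(s.generate_state(1)[0]) for s in seqs)

    offsets = [2.0 if c % 2 == 0 else -2.0 for c in range(chains.n_chains)]
    all_kept = []
    level_total = np.zeros(n)
    for c, (seq, offset) in enumerate(zip(seqs, offsets)):
        rng = np.random.default_rng(seq)
        kept_s, level_mean_c, _, acc_obs, acc_state = _run_chain(
            Xs, y, XtX, prior_prec, prior_mean_s, priors, chains, rng, offset
        )
        kept = kept_s.copy()
        kept[:, :p] /= col_scale  # back to raw-unit coefficients
        all_kept.append(kept)
        level_total += level_mean_c
        for name, acc in (("sigma2_obs", acc_obs), ("sigma2_state", acc_state)):
            if np.isfinite(acc):
                logger.info("chain %d %s MH acceptance rate %.3f", c + 1, name, acc)
                if not 0.05 <= acc <= 0.95:
                    logger.warning(
                        "chain %d: %s MH acceptance rate %.3f outside [0.05, 0.95]",
                        c + 1, name, acc,
                    )

    labels = tuple(f"beta_{name}" for name in design.column_names) + (
        "sigma2_obs", "sigma2_state",
    )
    return PosteriorDraws(
        labels=labels,
        draws=np.stack(all_kept),
        level_mean=level_total / chains.n_chains,
        seeds=tuple(seeds),
        meta={"priors": priors.to_dict(), "chains": chains.to_dict()},
    )


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence on pooled split chains."""
    chains = np.atleast_2d(np.asarray(chains, float))
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    centered = chains - chains.mean(axis=1, keepdims=True)
    var = centered.var(axis=1, ddof=0).mean()
    if var == 0:
        return float(m * n)
    max_lag = n - 1
    rho = np.zeros(max_lag)
    for lag in range(1, max_lag):
        cov = np.mean(
            [c[:-lag] @ c[lag:] / n for c in centered]
        )
        rho[lag] = cov / var
        # stop once a pair of consecutive autocorrelations turns negative
        if lag >= 2 and rho[lag] + rho[lag - 1] < 0:
            rho[lag] = 0.0
            break
    tau = 1.0 + 2.0 * rho.sum()
    return float(m * n / max(tau, 1e-12))


def posterior_summary(
    draws: PosteriorDraws, include_ess_se: bool = False
) -> pd.DataFrame:
    """Pool chains and summarize each parameter.

    The point estimate is the posterior mean (the squared-error-loss
    estimator).  Columns: mean, sd, se (= sd / sqrt(total draws)) and the
    2.5/50/97.5% quantiles; ``include_ess_se`` appends an
    autocorrelation-adjusted ``se_ts`` = sd / sqrt(ESS).
    """
    if draws.n_kept == 0:
        raise ValueError("no retained draws to summarize")
    flat = draws.draws.reshape(-1, len(draws.labels))
    total = flat.shape[0]
    sd = flat.std(axis=0, ddof=1) if total > 1 else np.zeros(flat.shape[1])
    q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "mean": flat.mean(axis=0),
            "sd": sd,
            "se": sd / np.sqrt(total),
            "q2.5": q[0],
            "q50": q[1],
            "q97.5": q[2],
        },
        index=pd.Index(draws.labels, name="Parameter"),
    )
    if include_ess_se:
        ess = np.array(
            [effective_sample_size(draws.draws[:, :, j]) for j in range(flat.shape[1])]
        )
        table["se_ts"] = sd / np.sqrt(ess)
    return table


def fitted_filter(
    design: DesignMatrix,
    draws: PosteriorDraws,
    priors: Priors | None = None,
) -> tuple[KalmanMoments, DLMSpec]:
    """Plug-in Kalman pass for residual diagnostics and forecasting.

    Runs the full-state filter (level + coefficients, with posterior-mean
    variances) over the design, yielding one-step-ahead residuals.
    """
    priors = priors or Priors()
    v_obs = float(draws.pooled("sigma2_obs").mean())
    w_state = float(draws.pooled("sigma2_state").mean())
    vbeta = priors.coef_variances(np.asarray(design.is_continuous, bool))
    spec = DLMSpec.hybrid(
        obs_variance=v_obs,
        level_variance=w_state,
        coef_prior_mean=np.full(design.p, priors.coef_mean),
        coef_prior_var=vbeta,
        level_mean=priors.level_mean,
        level_var=priors.level_var,
    )
    X_full = np.column_stack([np.ones(len(design)), design.X])
    moments = kalman_filter((X_full, design.y), spec)
    return moments, spec


def fitted_values(design: DesignMatrix, draws: PosteriorDraws) -> np.ndarray:
    """Posterior-mean fitted values ``level_mean + X @ beta_mean``."""
    beta_mean = np.array(
        [draws.pooled(f"beta_{name}").mean() for name in design.column_names]
    )
    return draws.level_mean + design.X @ beta_mean
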