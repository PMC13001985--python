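"""Convergence and residual diagnostics.

Gelman-Rubin potential scale reduction (split-chain by default, with the
classic F-distribution upper confidence bound), Durbin-Watson autocorrelation
test, Breusch-Pagan heteroscedasticity test (studentized/Koenker n*R^2 form
by default) and the Shapiro-Wilk normality test with Royston's approximation
to the normal order-statistic weights.

Decision rules use p-values at a configurable significance level; a test
"passes" when its null (well-behaved residuals) is not rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dlm import KalmanMoments
from .inference import PosteriorDraws

__all__ = [
    "gelman_rubin",
    "durbin_watson",
    "breusch_pagan",
    "shapiro_wilk",
    "validate_model",
    "DiagnosticsReport",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gelman-Rubin

def _psrf(chains: np.ndarray) -> tuple[float, float]:
    """Potential scale reduction factor and 97.5% upper bound for one
    parameter, from an (m, n) array of chains."""
    m, n = chains.shape
    xbar = chains.mean(axis=1)
    s2 = chains.var(axis=1, ddof=1)
    W = float(s2.mean())
    B = float(n * xbar.var(ddof=1))
    if W <= 0.0:
        # Degenerate parameter: no within-chain variability.
        return (1.0, 1.0)
    if B / (n * W) < 1e-14:
        # Identical chains: no between-chain spread, no scale reduction.
        return (1.0, 1.0)

    muhat = float(xbar.mean())
    var_w = float(s2.var(ddof=1)) / m
    var_b = 2.0 * B * B / (m - 1)
    cov_s2_xbar2 = float(np.cov(s2, xbar**2, ddof=1)[0, 1])
    cov_s2_xbar = float(np.cov(s2, xbar, ddof=1)[0, 1])
    cov_wb = (n / m) * (cov_s2_xbar2 - 2.0 * muhat * cov_s2_xbar)

    V = (n - 1) / n * W + (1.0 + 1.0 / m) * B / n
    var_V = (
        (n - 1) ** 2 * var_w
        + (1.0 + 1.0 / m) ** 2 * var_b
        + 2.0 * (n - 1) * (1.0 + 1.0 / m) * cov_wb
    ) / n**2
    df_V = 2.0 * V * V / var_V if var_V > 0 else np.inf
    df_adj = (df_V + 3.0) / (df_V + 1.0)

    r2_fixed = (n - 1) / n
    r2_random = (1.0 + 1.0 / m) * B / (n * W)
    rhat = float(np.sqrt(df_adj * (r2_fixed + r2_random)))
    if var_w > 0:
        w_df = 2.0 * W * W / var_w
        f_q = stats.f.ppf(0.975, m - 1, w_df)
    else:
        f_q = 1.0
    upper = float(np.sqrt(df_adj * (r2_fixed + f_q * r2_random)))
    return rhat, upper


def _split(chains: np.ndarray) -> np.ndarray:
    m, n = chains.shape
    half = n // 2
    if half < 2:
        raise ValueError("chains are too short to split")
    return np.concatenate([chains[:, :half], chains[:, n - half:]], axis=0)


def gelman_rubin(
    draws: PosteriorDraws | np.ndarray,
    labels: tuple[str, ...] | None = None,
    split: bool = True,
) -> pd.DataFrame:
    """Per-parameter R-hat and 97.5% upper bound.

    Accepts :class:`PosteriorDraws` or a (chains, iterations, parameters)
    array.  Each chain is split in half first (``split=True``), so
    within-chain drift also inflates the statistic.
    """
    if isinstance(draws, PosteriorDraws):
        array = draws.draws
        labels = labels or draws.labels
    else:
        array = np.asarray(draws, float)
        if array.ndim == 2:
            array = array[:, :, None]
        labels = labels or tuple(f"param_{j}" for j in range(array.shape[2]))
    if array.shape[0] < 2:
        raise ValueError(
            "Gelman-Rubin requires n_chains >= 2; run more chains"
        )
    rows = []
    for j, label in enumerate(labels):
        chains = array[:, :, j]
        if np.all(chains == chains[0]):
            # Identical copies: no between-chain spread by construction.
            rows.append((label, 1.0, 1.0))
            continue
        if split:
            chains = _split(chains)
        rhat, upper = _psrf(chains)
        rows.append((label, rhat, upper))
    return pd.DataFrame(rows, columns=["Parameter", "Rhat", "Upper CI"])


# ---------------------------------------------------------------------------
# Residual tests

def durbin_watson(residuals: np.ndarray) -> tuple[float, float]:
    """Durbin-Watson statistic and two-sided normal-approximation p-value.

    ``DW = sum_t (e_t - e_{t-1})^2 / sum_t e_t^2`` lies in [0, 4]; values
    near 2 indicate no first-order autocorrelation.  Under the null,
    ``(2 - DW) * sqrt(T) / 2`` is treated as standard normal (documented
    approximation; the exact Imhof computation is intentionally omitted).
    """
    e = np.asarray(residuals, float).ravel()
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    denom = float(e @ e)
    if denom == 0.0:
        raise ValueError("Durbin-Watson is undefined for all-zero residuals")
    dw = float(np.sum(np.diff(e) ** 2) / denom)
    z = (2.0 - dw) * np.sqrt(e.size) / 2.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return dw, p


def breusch_pagan(
    residuals: np.ndarray,
    design,
    studentized: bool = True,
) -> tuple[float, float, int]:
    """Breusch-Pagan heteroscedasticity test against the design columns.

    Regresses squared residuals on the covariates (plus an intercept).  The
    default studentized (Koenker) statistic is ``n * R^2`` of that auxiliary
    regression; ``studentized=False`` gives the classical LM form, half the
    explained sum of squares of ``e^2 / mean(e^2)``.  Returns
    ``(statistic, p_value, df)`` with a chi-square null on ``df`` = rank of
    the auxiliary regressors.
    """
    e = np.asarray(residuals, float).ravel()
    Z = np.asarray(design.X if hasattr(design, "X") else design, float)
    if Z.ndim != 2 or Z.shape[0] != e.size:
        raise ValueError("residual count must equal design row count")
    n = e.size
    Zc = np.column_stack([np.ones(n), Z])
    if n <= Zc.shape[1]:
        raise ValueError(
            f"auxiliary regression is infeasible: n={n} <= {Zc.shape[1]} columns"
        )
    rank = int(np.linalg.matrix_rank(Zc))
    if rank < Zc.shape[1]:
        warnings.warn(
            f"auxiliary design is rank deficient ({rank} < {Zc.shape[1]}); "
            "dependent columns contribute no degrees of freedom",
            stacklevel=2,
        )
    df = rank - 1

    g = e**2
    coef, *_ = np.linalg.lstsq(Zc, g, rcond=None)
    fitted = Zc @ coef
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    ss_res = float(np.sum((g - fitted) ** 2))
    if ss_tot == 0.0:
        return 0.0, 1.0, df
    r2 = 1.0 - ss_res / ss_tot
    if studentized:
        bp = n * r2
    else:
        gn = g / g.mean()
        coef_n, *_ = np.linalg.lstsq(Zc, gn, rcond=None)
        fitted_n = Zc @ coef_n
        bp = 0.5 * float(np.sum((fitted_n - gn.mean()) ** 2))
    p = float(stats.chi2.sf(bp, df))
    return float(bp), p, df


# Royston (1995) AS R94 polynomial coefficients.
_C1 = (0.0, 0.221157, -0.147981, -2.071190, 4.434685, -2.706056)
_C2 = (0.0, 0.042981, -0.293762, -1.752461, 5.682633, -3.582633)
_C3 = (0.5440, -0.39978, 0.025054, -0.0006714)
_C4 = (1.3822, -0.77857, 0.062767, -0.0020322)
_C5 = (-1.5861, -0.31082, -0.083751, 0.0038915)
_C6 = (-0.4803, -0.082676, 0.0030302)


def _poly(coefs, x) -> float:
    return float(sum(c * x**k for k, c in enumerate(coefs)))


def shapiro_wilk(residuals: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value via Royston's approximation.

    ``W = (sum_i a_i e_(i))^2 / sum_i (e_i - mean)^2`` with weights ``a_i``
    derived from the expected normal order statistics; valid for
    3 <= n <= 5000.
    """
    x = np.sort(np.asarray(residuals, float).ravel())
    n = x.size
    if n < 3 or n > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {n}")
    if x[0] == x[-1]:
        raise ValueError("Shapiro-Wilk is undefined for zero-variance input")

    m = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = float(m @ m)
    u = 1.0 / np.sqrt(n)
    a = np.empty(n)
    if n > 5:
        a_n = m[-1] / np.sqrt(mm) + _poly(_C1, u)
        a_n1 = m[-2] / np.sqrt(mm) + _poly(_C2, u)
        phi = (mm - 2.0 * m[-1] ** 2 - 2.0 * m[-2] ** 2) / (
            1.0 - 2.0 * a_n**2 - 2.0 * a_n1**2
        )
        a[2:-2] = m[2:-2] / np.sqrt(phi)
        a[-1], a[0] = a_n, -a_n
        a[-2], a[1] = a_n1, -a_n1
    else:
        a_n = np.sqrt(0.5) if n == 3 else m[-1] / np.sqrt(mm) + _poly(_C1, u)
        if n == 3:
            phi = 1.0
            a[1] = 0.0
        else:
            phi = (mm - 2.0 * m[-1] ** 2) / (1.0 - 2.0 * a_n**2)
            a[1:-1] = m[1:-1] / np.sqrt(phi)
        a[-1], a[0] = a_n, -a_n

    num = float(a @ x) ** 2
    den = float(np.sum((x - x.mean()) ** 2))
    W = min(num / den, 1.0)

    if n == 3:
        p = 6.0 / np.pi * (np.arcsin(np.sqrt(W)) - np.arcsin(np.sqrt(0.75)))
        return W, float(np.clip(p, 0.0, 1.0))
    if n <= 11:
        gamma = _poly((-2.273, 0.459), n)
        if gamma - np.log1p(-W) <= 0:
            return W, 1e-99
        wstat = -np.log(gamma - np.log1p(-W))
        mu = _poly(_C3, n)
        sigma = np.exp(_poly(_C4, n))
    else:
        ln = np.log(n)
        wstat = np.log1p(-W)
        mu = _poly(_C5, ln)
        sigma = np.exp(_poly(_C6, ln))
    z = (wstat - mu) / sigma
    return W, float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Combined report

@dataclass
class DiagnosticsReport:
    """Residual-test table, optional R-hat table and pass/fail flags."""

    tests: pd.DataFrame
    alpha: float
    rhat: pd.DataFrame | None = None

    @property
    def passed(self) -> dict[str, bool]:
        return dict(zip(self.tests["Test"], self.tests["passed"]))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.tests.to_csv(path, index=False)
        return path

    def __str__(self) -> str:
        lines = [f"Residual diagnostics (alpha = {self.alpha:g})"]
        for _, row in self.tests.iterrows():
            verdict = "pass" if row["passed"] else "REJECT null"
            lines.append(
                f"  {row['Test']}: statistic = {row['statistic']:.4f}, "
                f"p = {row['p_value']:.4f} [{verdict}]"
            )
        if self.rhat is not None:
            worst = self.rhat.loc[self.rhat["Rhat"].idxmax()]
            lines.append(
                f"  max Rhat = {worst['Rhat']:.4f} ({worst['Parameter']})"
            )
        return "\n".join(lines)


def validate_model(
    moments: KalmanMoments,
    design,
    alpha: float = 0.05,
    standardized: bool = True,
) -> DiagnosticsReport:
    """Run the three residual tests on one-step-ahead filter residuals.

    Uses standardized residuals by default (``standardized=False`` for raw
    ones).  A test passes when its null hypothesis — uncorrelated,
    homoscedastic, normal residuals respectively — is not rejected at
    ``alpha``.
    """
    e = moments.standardized_residuals if standardized else moments.residuals
    dw, p_dw = durbin_watson(e)
    bp, p_bp, _ = breusch_pagan(e, design)
    sw, p_sw = shapiro_wilk(e)
    tests = pd.DataFrame(
        {
            "Test": [
                "Durbin-Watson autocorrelation",
                "Studentized Breusch-Pagan heteroscedasticity",
                "Shapiro-Wilk normality",
            ],
            "statistic": [dw, bp, sw],
            "p_value": [p_dw, p_bp, p_sw],
        }
    )
    tests["passed"] = tests["p_value"] > alpha
    return DiagnosticsReport(tests=tests, alpha=alpha)
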