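"""Design matrices for the dynamic regression model.

Builds the per-row covariate vectors from a validated panel: continuous
covariates, full one-hot dummy blocks (all four regions, both season levels,
both SDG levels — no reference level is dropped and no intercept column is
added; identifiability comes from the priors and from the time-varying
level), the seven policy step indicators, and pairwise policy-interaction
columns.

Interactions of step-function indicators are degenerate: the product of two
onset indicators equals the indicator of the later onset, so *every*
pairwise product duplicates one of its parent main-effect columns.  The
default interaction set therefore follows the reported model: all 21 ordered
pairs except (RMNCAH, ENAP) and (NHSDP, ENAP), giving 19 columns.  A generic
duplicate-pruning rule is available via ``prune_duplicates=True`` and logs
every dropped column; under the default catalog it removes all products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import PANEL_COLUMNS, POLICY_CODES, PanelError

__all__ = [
    "CONTINUOUS_COLUMNS",
    "DUMMY_COLUMNS",
    "DesignMatrix",
    "all_policy_pairs",
    "default_interaction_pairs",
    "expand_dummies",
    "build_interactions",
    "build_design",
]

logger = logging.getLogger(__name__)

#: Continuous covariates, in design order.
CONTINUOUS_COLUMNS = (
    "cost", "healthfacdensity", "hcareaccess",
    "hcenteraccess", "maternaleduc", "hholdinc",
)

_REGION_DUMMIES = {
    1: "regioncentral",
    2: "regionwestern",
    3: "regioneastern",
    4: "regionnorthern",
}

#: Dummy columns in design order (full coding, no dropped level).
DUMMY_COLUMNS = (
    "regioncentral", "regionwestern", "regioneastern", "regionnorthern",
    "seasonDry", "seasonWet", "SDGintroBefore", "SDGintroAfter",
)

#: Pairs omitted from the default interaction set (their products duplicate
#: the RMNCAH and NHSDP main-effect columns under the default catalog).
EXCLUDED_DEFAULT_PAIRS = (("RMNCAH", "ENAP"), ("NHSDP", "ENAP"))


def all_policy_pairs() -> list[tuple[str, str]]:
    """All C(7,2)=21 policy pairs, ordered by catalog position."""
    return list(combinations(POLICY_CODES, 2))


def default_interaction_pairs() -> list[tuple[str, str]]:
    """The 19 interaction pairs of the default fitted model."""
    return [p for p in all_policy_pairs() if p not in EXCLUDED_DEFAULT_PAIRS]


def expand_dummies(panel: pd.DataFrame) -> pd.DataFrame:
    """Full one-hot expansion of region, season and SDG columns.

    Both levels of every factor are kept (no reference level, no intercept).
    """
    for col in ("Region", "season", "SDGintro"):
        if col not in panel.columns:
            raise PanelError(f"panel is missing required column: {col!r}")
    bad = sorted(set(panel["Region"]) - set(_REGION_DUMMIES))
    if bad:
        raise PanelError(f"unseen region codes: {bad}")
    for col in ("season", "SDGintro"):
        if not panel[col].isin([0, 1]).all():
            raise PanelError(f"column {col!r} must be binary 0/1")

    out = pd.DataFrame(index=panel.index)
    for code, name in _REGION_DUMMIES.items():
        out[name] = (panel["Region"] == code).astype(float)
    out["seasonDry"] = (panel["season"] == 1).astype(float)
    out["seasonWet"] = (panel["season"] == 0).astype(float)
    out["SDGintroBefore"] = (panel["SDGintro"] == 0).astype(float)
    out["SDGintroAfter"] = (panel["SDGintro"] == 1).astype(float)
    return out[list(DUMMY_COLUMNS)]


def build_interactions(
    policies: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    prune_duplicates: bool = False,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pairwise products of policy indicator columns.

    Parameters
    ----------
    policies
        Frame holding the seven binary policy columns.
    pairs
        Ordered (a, b) pairs to form; defaults to the 19-pair set of
        :func:`default_interaction_pairs`.
    prune_duplicates
        If True, drop any product column identical to a column of
        ``reference`` (typically the main-effect block) or to an earlier
        retained product; each drop is logged.
    reference
        Existing columns to compare against when pruning.
    """
    missing = [c for c in POLICY_CODES if c not in policies.columns]
    if missing:
        raise PanelError(f"policy columns missing: {missing}")
    for col in POLICY_CODES:
        if not policies[col].isin([0, 1]).all():
            raise PanelError(f"policy column {col!r} must be binary 0/1")
    if pairs is None:
        pairs = default_interaction_pairs()

    kept: dict[str, np.ndarray] = {}
    ref_cols = (
        {c: reference[c].to_numpy(float) for c in reference.columns}
        if reference is not None
        else {}
    )
    for a, b in pairs:
        name = f"{a}_{b}"
        values = policies[a].to_numpy(float) * policies[b].to_numpy(float)
        if prune_duplicates:
            dup = next(
                (
                    other
                    for other, col in {**ref_cols, **kept}.items()
                    if np.array_equal(col, values)
                ),
                None,
            )
            if dup is not None:
                logger.warning(
                    "pruning interaction column %s: identical to column %s",
                    name, dup,
                )
                continue
        kept[name] = values
    return pd.DataFrame(kept, index=policies.index)


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric design matrix aligned with an outcome vector."""

    X: np.ndarray
    y: np.ndarray
    column_names: tuple[str, ...]
    is_continuous: np.ndarray
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise PanelError("design rows and outcome must have equal length")
        if self.X.shape[1] != len(self.column_names):
            raise PanelError("column_names do not match design width")

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return self.X.shape[0]

    def index(self, name: str) -> int:
        return self.column_names.index(name)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.column_names))
        frame["neonat_rate"] = self.y
        return frame

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def destandardize(self, coefs: np.ndarray) -> np.ndarray:
        """Map coefficients on the standardized scale back to raw units.

        Only the rescaling is undone; the effect of centering is absorbed by
        the model's time-varying level, not by any coefficient.
        """
        if self.scale is None:
            return np.asarray(coefs, float)
        return np.asarray(coefs, float) / self.scale


def build_design(
    panel: pd.DataFrame,
    standardize: bool = False,
    coding: str = "full",
    interaction_pairs: list[tuple[str, str]] | None = None,
    prune_duplicates: bool = False,
    drop_empty: bool = True,
    outcome: str = "neonat_rate",
) -> DesignMatrix:
    """Assemble the design matrix from a panel.

    Column order: continuous covariates, dummy blocks, policy main effects,
    retained policy interactions.  ``coding="reference"`` drops the
    ``regioncentral``, ``seasonWet`` and ``SDGintroBefore`` levels instead of
    keeping the full blocks.  All-zero columns (e.g. a policy that never
    switches on inside the panel window) are dropped with a logged warning
    unless ``drop_empty=False``.
    """
    if len(panel) == 0:
        raise PanelError("cannot build a design from an empty panel")
    required = [c for c in PANEL_COLUMNS if c not in ("District",)]
    missing = [c for c in required if c not in panel.columns]
    if missing:
        raise PanelError(f"panel is missing required columns: {missing}")
    if coding not in ("full", "reference"):
        raise PanelError(f"unknown coding {coding!r}")

    # Model order: districts concatenated in label order, months within.
    panel = panel.sort_values(["District", "Observ"], kind="mergesort")

    blocks: list[pd.DataFrame] = []
    blocks.append(panel[list(CONTINUOUS_COLUMNS)].astype(float))
    dummies = expand_dummies(panel)
    if coding == "reference":
        dummies = dummies.drop(
            columns=["regioncentral", "seasonWet", "SDGintroBefore"]
        )
    blocks.append(dummies)
    mains = panel[list(POLICY_CODES)].astype(float)
    blocks.append(mains)
    if interaction_pairs is None or interaction_pairs:
        reference = pd.concat([dummies, mains], axis=1)
        blocks.append(
            build_interactions(
                panel[list(POLICY_CODES)],
                pairs=interaction_pairs,
                prune_duplicates=prune_duplicates,
                reference=reference,
            )
        )

    frame = pd.concat(blocks, axis=1)
    if drop_empty:
        empty = [c for c in frame.columns if not frame[c].to_numpy().any()]
        if empty:
            logger.warning("dropping all-zero design columns: %s", empty)
            frame = frame.drop(columns=empty)

    names = tuple(frame.columns)
    X = frame.to_numpy(float)
    y = panel[outcome].to_numpy(float)
    is_cont = np.array([c in CONTINUOUS_COLUMNS for c in names])

    center = scale = None
    if standardize:
        center = np.where(is_cont, X.mean(axis=0), 0.0)
        sd = X.std(axis=0, ddof=0)
        scale = np.where(is_cont & (sd > 0), sd, 1.0)
        X = (X - center) / scale

    return DesignMatrix(
        X=X, y=y, column_names=names, is_continuous=is_cont,
        center=center, scale=scale,
    )
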