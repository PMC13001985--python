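"""Seeded synthetic district-month mortality panels.

This module generates tidy panels of monthly neonatal mortality rates and
health-system covariates for a configurable set of districts, including step
indicators for seven national health-care policies and for the SDG onset.
The default configuration spans January 2010 through December 2023 over six
districts (1,008 rows) around a baseline rate of 27 deaths per 1,000 live
births.

The outcome for district *i* in month *t* is::

    rate = baseline
         + region offset
         + sum_j effect_j * (x_ij - district base_j)     (continuous covariates)
         + seasonal offset (+e/2 in dry months, -e/2 in wet months)
         + SDG and policy step effects
         + shared national random-walk trend
         + Gaussian noise,

truncated at zero.  Continuous covariate effects act on deviations from the
per-district base level, so the pre-intervention mean of the outcome equals
``baseline_rate`` up to Monte-Carlo noise.  Identical seeds give identical
panels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PanelError",
    "PolicyCatalog",
    "SimulationConfig",
    "POLICY_CODES",
    "PANEL_COLUMNS",
    "REGION_CODES",
    "policy_indicator",
    "sdg_indicator",
    "month_range",
    "generate_panel",
    "validate_panel",
    "read_panel",
    "write_panel",
]

#: Policy short codes, in catalog order (also the order used to label
#: pairwise interaction columns).
POLICY_CODES = ("RMNCAH", "NHSDP", "ENAP", "SMGL", "UNNSC", "MPDSR", "QUINH")

#: Region name -> integer code used in the panel's ``Region`` column.
REGION_CODES = {"Central": 1, "Western": 2, "Eastern": 3, "Northern": 4}

#: Canonical column order of a panel file.
PANEL_COLUMNS = (
    "Observ", "Year", "Month", "District", "Region",
    "cost", "healthfacdensity", "hcareaccess", "hcenteraccess",
    "maternaleduc", "hholdinc", "season", "SDGintro",
) + POLICY_CODES + ("neonat_rate",)

# Policy onsets: years are fixed by the national policy timeline; months are
# not published, so every policy is taken to start in January of its year
# (NHSDP, announced for 2015/16, uses 2016).  Override via PolicyCatalog.
_DEFAULT_STARTS = {
    "RMNCAH": (2016, 1),
    "NHSDP": (2016, 1),
    "ENAP": (2015, 1),
    "SMGL": (2012, 1),
    "UNNSC": (2016, 1),
    "MPDSR": (2015, 1),
    "QUINH": (2016, 1),
}

# Default districts (label-sorted) and their regions: Central x2, Western,
# Eastern, Northern x2.  Arbitrary but documented; configurable.
DEFAULT_DISTRICTS = (
    ("Gulu", "Northern"),
    ("Jinja", "Eastern"),
    ("Kampala", "Central"),
    ("Lira", "Northern"),
    ("Mbarara", "Western"),
    ("Wakiso", "Central"),
)

#: Default additive effects on the mortality rate.  Continuous-covariate
#: effects multiply deviations from the district base value; ``seasonDry``
#: is applied as a zero-mean +/- offset; region offsets average to zero over
#: the default district set so the pre-intervention mean stays at baseline.
DEFAULT_EFFECTS: dict[str, float] = {
    "cost": 0.02,
    "healthfacdensity": 0.03,
    "hcareaccess": 0.01,
    "hcenteraccess": 2e-4,
    "maternaleduc": 0.4,
    "hholdinc": -1e-5,
    "seasonDry": 1.2,
    "SDGintro": -4.0,
    "RMNCAH": -2.0,
    "NHSDP": -2.0,
    "ENAP": -2.5,
    "SMGL": -3.0,
    "UNNSC": -1.5,
    "MPDSR": -2.0,
    "QUINH": -2.0,
    "regionCentral": -0.5,
    "regionWestern": 0.0,
    "regionEastern": 0.0,
    "regionNorthern": 0.5,
}


class PanelError(ValueError):
    """Raised for invalid panel data or simulation configuration."""


def _check_date(date: tuple[int, int]) -> tuple[int, int]:
    year, month = int(date[0]), int(date[1])
    if not 1 <= month <= 12:
        raise PanelError(f"month must be in 1..12, got {month}")
    return year, month


@dataclass(frozen=True)
class PolicyCatalog:
    """Onset dates (year, month) of the seven policy interventions."""

    entries: tuple[tuple[str, int, int], ...] = tuple(
        (code, y, m) for code, (y, m) in _DEFAULT_STARTS.items()
    )

    def __post_init__(self) -> None:
        codes = tuple(e[0] for e in self.entries)
        if set(codes) != set(POLICY_CODES) or len(codes) != len(POLICY_CODES):
            raise PanelError(
                f"catalog must contain exactly the codes {sorted(POLICY_CODES)}, "
                f"got {sorted(codes)}"
            )
        for code, year, month in self.entries:
            _check_date((year, month))

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def start(self, policy_code: str) -> tuple[int, int]:
        for code, year, month in self.entries:
            if code == policy_code:
                return (year, month)
        raise PanelError(f"unknown policy code {policy_code!r}")


def policy_indicator(
    date: tuple[int, int], policy_code: str, catalog: PolicyCatalog | None = None
) -> int:
    """Return 1 iff ``date`` is on or after the policy's onset, else 0."""
    catalog = catalog or PolicyCatalog()
    return int(_check_date(date) >= catalog.start(policy_code))


def sdg_indicator(date: tuple[int, int], onset: tuple[int, int] = (2016, 1)) -> int:
    """Return 1 iff ``date`` is on or after the SDG onset (default Jan 2016)."""
    return int(_check_date(date) >= _check_date(onset))


def month_range(start: tuple[int, int], end: tuple[int, int]) -> list[tuple[int, int]]:
    """Inclusive list of (year, month) pairs from ``start`` to ``end``."""
    start, end = _check_date(start), _check_date(end)
    if end < start:
        raise PanelError(f"end {end} precedes start {start}")
    out = []
    y, m = start
    while (y, m) <= end:
        out.append((y, m))
        m += 1
        if m > 12:
            y, m = y + 1, 1
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the synthetic panel generator."""

    n_districts: int = 6
    start: tuple[int, int] = (2010, 1)
    end: tuple[int, int] = (2023, 12)
    baseline_rate: float = 27.0
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    noise_sd: float = 1.0
    trend_sd: float = 0.05
    seed: int | None = None
    sdg_onset: tuple[int, int] = (2016, 1)
    dry_months: frozenset = frozenset({12, 1, 2, 6, 7, 8})
    districts: tuple[tuple[str, str], ...] | None = None
    max_rows: int = 500_000

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise PanelError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.trend_sd < 0:
            raise PanelError(f"trend_sd must be nonnegative, got {self.trend_sd}")
        if self.n_districts < 1:
            raise PanelError("n_districts must be positive")
        _check_date(self.start)
        _check_date(self.end)
        if tuple(self.end) < tuple(self.start):
            raise PanelError(f"end {self.end} precedes start {self.start}")
        if self.districts is not None:
            if len(self.districts) != self.n_districts:
                raise PanelError(
                    f"{len(self.districts)} districts listed but "
                    f"n_districts={self.n_districts}"
                )
            for _, region in self.districts:
                if region not in REGION_CODES:
                    raise PanelError(f"unknown region {region!r}")

    def district_table(self) -> tuple[tuple[str, str], ...]:
        """(label, region) pairs in label order."""
        if self.districts is not None:
            return tuple(sorted(self.districts))
        if self.n_districts == 6:
            return DEFAULT_DISTRICTS
        regions = list(REGION_CODES)
        return tuple(
            (f"District{i + 1:02d}", regions[i % 4]) for i in range(self.n_districts)
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("start", "end", "sdg_onset"):
            if key in d:
                d[key] = tuple(d[key])
        if "dry_months" in d:
            d["dry_months"] = frozenset(d["dry_months"])
        if "districts" in d and d["districts"] is not None:
            d["districts"] = tuple(tuple(x) for x in d["districts"])
        effects = dict(DEFAULT_EFFECTS)
        effects.update(d.pop("effect_sizes", {}) or {})
        return cls(effect_sizes=effects, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_sizes"] = dict(self.effect_sizes)
        d["dry_months"] = sorted(self.dry_months)
        return d


def generate_panel(
    config: SimulationConfig | None = None,
    catalog: PolicyCatalog | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a district-month panel.

    Rows are ordered by district label then by the 1-based running month
    index ``Observ``.  ``seed`` overrides ``config.seed``.
    """
    config = config or SimulationConfig()
    catalog = catalog or PolicyCatalog()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    months = month_range(config.start, config.end)
    n_rows = len(months) * config.n_districts
    if n_rows > config.max_rows:
        raise PanelError(
            f"{n_rows} rows exceed the configured maximum of {config.max_rows}"
        )

    eff = config.effect_sizes
    e = lambda name: float(eff.get(name, 0.0))

    # Shared national random-walk trend, one value per calendar month.
    if config.trend_sd > 0:
        trend = np.cumsum(rng.normal(0.0, config.trend_sd, size=len(months)))
    else:
        trend = np.zeros(len(months))

    records: list[tuple] = []
    for district, region_name in config.district_table():
        region = REGION_CODES[region_name]
        base = {
            "cost": rng.uniform(40.0, 80.0),
            "healthfacdensity": rng.uniform(15.0, 60.0),
            "hcareaccess": rng.uniform(80.0, 300.0),
            "hcenteraccess": rng.uniform(2000.0, 9000.0),
            "maternaleduc": rng.uniform(2.0, 6.0),
            "hholdinc": rng.uniform(2e5, 6e5),
        }
        for t, (year, month) in enumerate(months, start=1):
            cost = base["cost"] + rng.normal(0.0, 4.0)
            fac = max(int(round(base["healthfacdensity"] + rng.normal(0.0, 2.0))), 0)
            access = max(int(round(base["hcareaccess"] + rng.normal(0.0, 10.0))), 0)
            dist = max(base["hcenteraccess"] + rng.normal(0.0, 150.0), 100.0)
            educ = max(base["maternaleduc"] + rng.normal(0.0, 0.3), 0.0)
            inc = max(base["hholdinc"] + rng.normal(0.0, 2e4), 0.0)
            season = 1 if month in config.dry_months else 0
            sdg = sdg_indicator((year, month), config.sdg_onset)
            flags = [policy_indicator((year, month), c, catalog) for c in POLICY_CODES]

            rate = (
                config.baseline_rate
                + e(f"region{region_name}")
                + e("cost") * (cost - base["cost"])
                + e("healthfacdensity") * (fac - base["healthfacdensity"])
                + e("hcareaccess") * (access - base["hcareaccess"])
                + e("hcenteraccess") * (dist - base["hcenteraccess"])
                + e("maternaleduc") * (educ - base["maternaleduc"])
                + e("hholdinc") * (inc - base["hholdinc"])
                + e("seasonDry") * (season - 0.5)
                + e("SDGintro") * sdg
                + sum(e(c) * f for c, f in zip(POLICY_CODES, flags))
                + trend[t - 1]
                + rng.normal(0.0, config.noise_sd)
            )
            records.append(
                (t, year, month, district, region, cost, fac, access, dist,
                 educ, inc, season, sdg, *flags, max(rate, 0.0))
            )

    panel = pd.DataFrame.from_records(records, columns=list(PANEL_COLUMNS))
    int_cols = ["Observ", "Year", "Month", "Region", "healthfacdensity",
                "hcareaccess", "season", "SDGintro", *POLICY_CODES]
    panel[int_cols] = panel[int_cols].astype(np.int64)
    validate_panel(panel)
    return panel


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a panel against the schema; raise :class:`PanelError`."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelError(f"panel is missing required columns: {missing}")
    if len(panel) == 0:
        raise PanelError("panel has no rows")
    if panel.duplicated(["District", "Observ"]).any():
        raise PanelError("duplicate (District, Observ) pairs")
    if not panel["Region"].isin([1, 2, 3, 4]).all():
        bad = sorted(set(panel["Region"]) - {1, 2, 3, 4})
        raise PanelError(f"region codes outside 1..4: {bad}")
    for col in ("season", "SDGintro", *POLICY_CODES):
        if not panel[col].isin([0, 1]).all():
            raise PanelError(f"column {col!r} must be binary 0/1")
    if (panel["neonat_rate"] < 0).any():
        raise PanelError("negative neonat_rate values")
    if (panel["hcenteraccess"] <= 0).any():
        raise PanelError("hcenteraccess must be positive")
    for col in ("healthfacdensity", "hcareaccess"):
        if (panel[col] < 0).any():
            raise PanelError(f"column {col!r} must be nonnegative")
    for col in ("SDGintro", *POLICY_CODES):
        by_district = panel.sort_values("Observ").groupby("District")[col]
        if (by_district.diff().dropna() < 0).any():
            raise PanelError(f"policy flag {col!r} is not nondecreasing in time")
    return panel


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate a panel from CSV or XLSX."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        panel = pd.read_excel(path, engine="openpyxl")
    else:
        panel = pd.read_csv(path, float_precision="round_trip")
    validate_panel(panel)
    return panel[list(PANEL_COLUMNS)]


def write_panel(panel: pd.DataFrame, path: str | Path) -> Path:
    """Write a panel to CSV in the canonical column order."""
    path = Path(path)
    validate_panel(panel)
    # %.17g round-trips float64 exactly, so a write -> read cycle rebuilds
    # bit-identical design matrices.
    panel[list(PANEL_COLUMNS)].to_csv(path, index=False, float_format="%.17g")
    return path
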