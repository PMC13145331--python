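"""Reading, cleaning and deriving the model's observed inputs.

Winter indexing convention: the winter spanning autumn year ``y`` to spring
``y+1`` is labelled by ``y`` (so winter 1983/1984 is year 1983, the first
study year, ``t = 1``; the study span 1983–2021 gives T = 39 winters).

Counts are whole-flock winter maxima; the model is female-based, so counts
are halved under an even sex ratio before entering the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "FOCAL_GROUPS",
    "STUDY_FIRST_YEAR",
    "STUDY_LAST_YEAR",
    "SiteTable",
    "CountSeries",
    "AgeRatioSeries",
    "DailyWeather",
    "CovariateSet",
    "interpolate_counts",
    "female_counts",
    "elsewhere_age_ratio",
    "juveniles_from_ratio",
    "growing_degree_days",
    "cumulative_snow",
    "storm_days",
    "hunting_period",
    "standardize",
    "read_counts",
    "read_age_ratios",
    "read_sites",
    "read_daily_weather",
]

#: Subpopulation groups, in model order: Wexford, Islay, Loch Ken, Elsewhere.
GROUPS = ("W", "Is", "LK", "E")
FOCAL_GROUPS = ("W", "Is", "LK")

STUDY_FIRST_YEAR = 1983
STUDY_LAST_YEAR = 2022


@dataclass(frozen=True)
class SiteTable:
    """Mapping from wintering site to subpopulation group and weather regions."""

    site_id: tuple[str, ...]
    group: tuple[str, ...]
    winter_region: tuple[str, ...]
    stage_region: tuple[str, ...]
    breed_region: tuple[str, ...]

    def __post_init__(self):
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}; expected {GROUPS}")


@dataclass
class CountSeries:
    """Site-by-winter count table; ``counts[s, t]`` with NaN for missing cells."""

    sites: list[str]
    years: np.ndarray  # autumn calendar years, length T
    counts: np.ndarray  # float array (sites × T), NaN = missing

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sites), len(self.years)):
            raise ValueError("counts shape does not match sites × years")
        with np.errstate(invalid="ignore"):
            if np.any(self.counts < 0):
                raise ValueError("negative counts")


@dataclass
class AgeRatioSeries:
    """Juvenile:adult ratio per site-year with the site count as weight."""

    sites: list[str]
    years: np.ndarray
    ratio: np.ndarray  # NaN = not sampled
    weight: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(self.ratio < 0) or np.any(self.weight < 0):
                raise ValueError("ratios and weights must be nonnegative")


@dataclass
class DailyWeather:
    """Per-region daily series: mean temperature, precipitation, min pressure."""

    region: str
    dates: pd.DatetimeIndex
    tmean_c: np.ndarray
    precip_mm: np.ndarray
    pmin_hpa: np.ndarray

    def __post_init__(self):
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError(f"dates must be strictly increasing in region {self.region}")
        n = len(self.dates)
        for name in ("tmean_c", "precip_mm", "pmin_hpa"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length does not match dates")
            setattr(self, name, arr)


@dataclass
class CovariateSet:
    """Standardized environmental covariates and hunting-period index per group-year.

    Arrays are (n_groups × n_years).  ``gdd_winter``, ``gdd_stage``,
    ``gdd_breed`` and ``snow_breed`` enter the fecundity predictor;
    ``storms`` the survival predictors; ``hunt_level`` is the protection
    period index h ∈ {0, 1, 2}.
    """

    gdd_winter: np.ndarray
    gdd_stage: np.ndarray
    gdd_breed: np.ndarray
    snow_breed: np.ndarray
    storms: np.ndarray
    hunt_level: np.ndarray = field(default=None)
    years: np.ndarray = field(default=None)

    def __post_init__(self):
        shp = np.asarray(self.gdd_winter).shape
        for name in ("gdd_winter", "gdd_stage", "gdd_breed", "snow_breed", "storms"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shp:
                raise ValueError("covariate arrays must share one (group × year) shape")
            setattr(self, name, arr)
        if self.years is None:
            self.years = np.arange(STUDY_FIRST_YEAR, STUDY_FIRST_YEAR + shp[1])
        self.years = np.asarray(self.years, dtype=int)
        if self.hunt_level is None:
            # same piecewise regime as hunting_period, but tolerant of years
            # outside the study span (synthetic series may extend past it)
            y = self.years
            self.hunt_level = np.where(y <= 2005, 0, np.where(y <= 2008, 1, 2))
        self.hunt_level = np.asarray(self.hunt_level, dtype=int)
        if np.any(np.diff(self.hunt_level) < 0):
            raise ValueError("hunting-period index must be non-decreasing in year")

    @property
    def n_groups(self) -> int:
        return self.gdd_winter.shape[0]

    @property
    def n_years(self) -> int:
        return self.gdd_winter.shape[1]

    def fecundity_design(self) -> np.ndarray:
        """Stack the four fecundity covariates: (4 × groups × years)."""
        return np.stack(
            [self.gdd_winter, self.gdd_stage, self.gdd_breed, self.snow_breed]
        )

    @classmethod
    def zeros(cls, n_groups: int, n_years: int, first_year: int = STUDY_FIRST_YEAR):
        z = np.zeros((n_groups, n_years))
        return cls(z, z.copy(), z.copy(), z.copy(), z.copy(),
                   years=np.arange(first_year, first_year + n_years))


# ---------------------------------------------------------------------------
# cleaning / derivation operations
# ---------------------------------------------------------------------------

def interpolate_counts(series: CountSeries) -> CountSeries:
    """Fill missing count cells by linear interpolation in time.

    Interior gaps are interpolated linearly between the nearest observed
    years and rounded to the nearest integer; leading/trailing gaps take the
    nearest observed value (no extrapolation).  Idempotent.
    """
    filled = np.empty_like(series.counts)
    for s, site in enumerate(series.sites):
        row = series.counts[s]
        obs = ~np.isnan(row)
        if not obs.any():
            raise ValueError(f"site {site!r} has no observed counts")
        idx = np.arange(len(row))
        interp = np.interp(idx, idx[obs], row[obs])  # np.interp clamps at the edges
        filled[s] = np.round(interp)
    return CountSeries(list(series.sites), series.years.copy(), filled)


def female_counts(count) -> int:
    """Halve a whole-flock count to females (even sex ratio), rounding half up."""
    arr = np.asarray(count)
    if np.any(arr < 0):
        raise ValueError("count must be nonnegative")
    halved = np.floor(arr / 2 + 0.5).astype(int)
    return int(halved) if np.isscalar(count) or arr.ndim == 0 else halved


def elsewhere_age_ratio(ratios, weights) -> float:
    """Count-weighted average age ratio across the pooled non-focal sites."""
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.shape != w.shape:
        raise ValueError("ratios and weights must align")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    tot = w.sum()
    if tot == 0:
        raise ValueError("all-zero weights: weighted age ratio undefined")
    return float((r * w).sum() / tot)


def juveniles_from_ratio(ratio: float, total_females: int) -> int:
    """Split a female count into juveniles using the juvenile:adult ratio r.

    With J/A = r and J + A = total, J = total · r/(1+r), rounded to nearest.
    """
    if ratio < 0 or total_females < 0:
        raise ValueError("ratio and total must be nonnegative")
    return int(round(total_females * ratio / (1.0 + ratio)))


def _window_slice(weather: DailyWeather, window) -> slice:
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    i = weather.dates.searchsorted(start, side="left")
    j = weather.dates.searchsorted(end, side="right")
    if j <= i:
        raise ValueError(f"empty weather window {window} in region {weather.region}")
    return slice(i, j)


def growing_degree_days(weather: DailyWeather, window, base_c: float = 0.0) -> float:
    """Cumulative growing degree days Σ max(0, T_d − base) over the window."""
    sl = _window_slice(weather, window)
    return float(np.clip(weather.tmean_c[sl] - base_c, 0.0, None).sum())


def cumulative_snow(weather: DailyWeather, window, snow_temp_c: float = 0.0) -> float:
    """Total precipitation on days whose mean temperature is below ``snow_temp_c``."""
    sl = _window_slice(weather, window)
    cold = weather.tmean_c[sl] < snow_temp_c
    return float(weather.precip_mm[sl][cold].sum())


def storm_days(weather: DailyWeather, window, threshold_hpa: float = 980.0) -> int:
    """Number of days whose minimum surface pressure drops below the threshold."""
    sl = _window_slice(weather, window)
    return int((weather.pmin_hpa[sl] < threshold_hpa).sum())


def hunting_period(winter_year: int) -> int:
    """Protection-period index for a winter year.

    0: hunting permitted outside Ireland/Scotland protections (1983–2005);
    1: additional protection in Iceland (2006–2008);
    2: additional protection in Iceland and Greenland (2009–2022).
    """
    y = int(winter_year)
    if not (STUDY_FIRST_YEAR <= y <= STUDY_LAST_YEAR):
        raise ValueError(f"winter year {y} outside study span "
                         f"{STUDY_FIRST_YEAR}–{STUDY_LAST_YEAR}")
    if y <= 2005:
        return 0
    if y <= 2008:
        return 1
    return 2


def standardize(series) -> np.ndarray:
    """Center and scale to unit (population) standard deviation.

    A constant series maps to all zeros so that a degenerate covariate drops
    out of the linear predictor rather than producing NaN.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# CSV readers (UTF-8, header row required)
# ---------------------------------------------------------------------------

def read_counts(path) -> CountSeries:
    """Read long-format ``counts.csv`` (site, year, count) into a CountSeries."""
    df = pd.read_csv(path)
    _require(df, path, {"site", "year", "count"})
    wide = df.pivot_table(index="site", columns="year", values="count", aggfunc="first")
    years = np.array(sorted(wide.columns))
    wide = wide.reindex(columns=years)
    return CountSeries(list(wide.index), years, wide.to_numpy(dtype=float))


def read_age_ratios(path) -> AgeRatioSeries:
    df = pd.read_csv(path)
    _require(df, path, {"site", "year", "ratio", "weight"})
    years = np.array(sorted(df["year"].unique()))
    rat = df.pivot_table(index="site", columns="year", values="ratio", aggfunc="first")
    wgt = df.pivot_table(index="site", columns="year", values="weight", aggfunc="first")
    rat = rat.reindex(columns=years)
    wgt = wgt.reindex(index=rat.index, columns=years)
    return AgeRatioSeries(list(rat.index), years,
                          rat.to_numpy(dtype=float), wgt.to_numpy(dtype=float))


def read_sites(path) -> SiteTable:
    df = pd.read_csv(path)
    _require(df, path, {"site", "group", "winter_region", "stage_region", "breed_region"})
    if df["site"].duplicated().any():
        dup = df.loc[df["site"].duplicated(), "site"].iloc[0]
        raise ValueError(f"site {dup!r} mapped to more than one group in {path}")
    return SiteTable(
        tuple(df["site"]), tuple(df["group"]), tuple(df["winter_region"]),
        tuple(df["stage_region"]), tuple(df["breed_region"]),
    )


def read_daily_weather(path, region: str | None = None) -> DailyWeather:
    df = pd.read_csv(path, parse_dates=["date"])
    _require(df, path, {"date", "tmean_c", "precip_mm", "pmin_hpa"})
    if region is None:
        region = str(df["region"].iloc[0]) if "region" in df else "unknown"
    return DailyWeather(region, pd.DatetimeIndex(df["date"]),
                        df["tmean_c"].to_numpy(), df["precip_mm"].to_numpy(),
                        df["pmin_hpa"].to_numpy())


def _require(df: pd.DataFrame, path, cols: set):
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
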