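"""Synthetic daily-weather generator and climate CSV I/O.

A climatic series is one growing season (April-October, 180 days) of five daily
variables: minimum and maximum temperature (degC), global radiation (MJ/m2),
reference evapotranspiration (mm) and precipitation (mm).  The generator
produces an ensemble of such seasons across sites and years with the structure
the subset-selection method relies on: smooth seasonal cycles with
autocorrelated anomalies for temperature and radiation, rain as a marked point
process (Bernoulli occurrence, gamma amounts) so that discrete rain *events*
exist for dynamic time warping to align, and evapotranspiration as a
Hargreaves-style function increasing in diurnal temperature range and
radiation.  Site profiles shift the climate (warm/dry "southern" versus
cool/wet "northern" sites) so that a clustering of seasons has real structure
to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEASON_LENGTH = 180

_CHANNELS = ("tmin", "tmax", "radiation", "evapotranspiration", "precipitation")

CSV_COLUMNS = ["site", "year", "day", "tmin", "tmax", "radiation", "etp", "precipitation"]


@dataclass(frozen=True)
class ClimateSeries:
    """One growing season of daily weather at a (site, year)."""

    site_id: str
    year: int
    tmin: np.ndarray
    tmax: np.ndarray
    radiation: np.ndarray
    evapotranspiration: np.ndarray
    precipitation: np.ndarray

    def __post_init__(self) -> None:
        for name in _CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (SEASON_LENGTH,):
                raise ValueError(
                    f"series ({self.site_id}, {self.year}): channel '{name}' has "
                    f"{arr.size} values, expected {SEASON_LENGTH}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(
                    f"series ({self.site_id}, {self.year}): non-finite values in '{name}'"
                )
        bad = np.nonzero(self.tmax < self.tmin)[0]
        if bad.size:
            raise ValueError(
                f"series ({self.site_id}, {self.year}): tmax < tmin on day {bad[0] + 1}"
            )
        for name in ("radiation", "evapotranspiration", "precipitation"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                day = int(np.nonzero(arr < 0)[0][0]) + 1
                raise ValueError(
                    f"series ({self.site_id}, {self.year}): negative {name} on day {day}"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.site_id, self.year)

    def channel(self, name: str) -> np.ndarray:
        """Return one of the five daily channels by name (tmin/tmax/radiation/
        evapotranspiration/precipitation)."""
        if name not in _CHANNELS:
            raise KeyError(f"unknown climate variable {name!r}; expected one of {_CHANNELS}")
        return getattr(self, name)

    def replace(self, **changes) -> "ClimateSeries":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ClimateSet:
    """An ordered collection of climatic series with unique (site, year) keys."""

    series: tuple[ClimateSeries, ...]

    def __post_init__(self) -> None:
        series = tuple(self.series)
        object.__setattr__(self, "series", series)
        if len(series) < 1:
            raise ValueError("a ClimateSet needs at least one series")
        keys = [s.key for s in series]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (site, year) pairs in ClimateSet")

    @property
    def N(self) -> int:
        return len(self.series)

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, i: int) -> ClimateSeries:
        return self.series[i]

    def labels(self) -> list[str]:
        """``site:year`` labels, in order."""
        return [f"{s.site_id}:{s.year}" for s in self.series]

    def channel_matrix(self, name: str) -> np.ndarray:
        """Stack one channel over all series into an (N, 180) array."""
        return np.stack([s.channel(name) for s in self.series])

    def subset(self, indices: Sequence[int]) -> "ClimateSet":
        return ClimateSet(tuple(self.series[i] for i in indices))


@dataclass(frozen=True)
class SiteProfile:
    """Climatological offsets of a site relative to the generator's baseline.

    ``temp_offset`` shifts daily temperatures (degC), ``radiation_offset``
    shifts daily radiation (MJ/m2), ``rain_prob`` is the daily probability of a
    rain event and ``rain_scale`` the gamma scale (mm) of event amounts.
    """

    name: str
    temp_offset: float = 0.0
    radiation_offset: float = 0.0
    rain_prob: float = 0.28
    rain_scale: float = 9.0


def default_site_profiles(n_sites: int = 5) -> tuple[SiteProfile, ...]:
    """Three cool/wet "northern" and two warm/dry "southern" site profiles.

    For ``n_sites != 5`` the five defaults are cycled with a small extra
    temperature offset so the keys stay unique.
    """
    base = (
        SiteProfile("north-1", temp_offset=-1.5, radiation_offset=-1.5, rain_prob=0.33, rain_scale=9.5),
        SiteProfile("north-2", temp_offset=-0.8, radiation_offset=-1.0, rain_prob=0.31, rain_scale=9.0),
        SiteProfile("north-3", temp_offset=-0.2, radiation_offset=-0.5, rain_prob=0.29, rain_scale=8.5),
        SiteProfile("south-1", temp_offset=2.2, radiation_offset=2.0, rain_prob=0.18, rain_scale=7.5),
        SiteProfile("south-2", temp_offset=2.8, radiation_offset=2.5, rain_prob=0.16, rain_scale=7.0),
    )
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    profiles = []
    for i in range(n_sites):
        p = base[i % len(base)]
        if i >= len(base):
            p = dataclasses.replace(p, name=f"{p.name}-{i // len(base)}", temp_offset=p.temp_offset + 0.1 * (i // len(base)))
        profiles.append(p)
    return tuple(profiles)


# Baseline seasonal cycle: day 1 = April 1; temperature peaks mid-July,
# radiation slightly earlier (late June).
_DAYS = np.arange(1, SEASON_LENGTH + 1)


def _seasonal_temperature(days: np.ndarray) -> np.ndarray:
    return 11.5 + 8.5 * np.sin(np.pi * (days + 18.0) / 215.0)


def _seasonal_radiation(days: np.ndarray) -> np.ndarray:
    return 13.0 + 9.0 * np.sin(np.pi * (days + 35.0) / 230.0)


def _generate_series(profile: SiteProfile, year: int, rng: np.random.Generator) -> ClimateSeries:
    n = SEASON_LENGTH
    # interannual anomalies: a season-wide temperature shift and a wet/dry-year
    # factor scaling the rain-event probability (real station records vary by a
    # factor of 2-3 in seasonal rainfall across years at one site)
    year_anom = rng.normal(0.0, 1.2)
    wetness = np.exp(rng.normal(0.0, 0.35))

    # AR(1) temperature anomaly, lag-1 correlation 0.7
    eps = rng.normal(0.0, 1.6, size=n)
    anom = np.empty(n)
    acc = 0.0
    for t in range(n):
        acc = 0.7 * acc + eps[t]
        anom[t] = acc

    # rain: Bernoulli occurrence with a mild early-season surplus, gamma amounts
    p_rain = np.clip(wetness * profile.rain_prob * (1.15 - 0.3 * _DAYS / n), 0.02, 0.95)
    wet = rng.random(n) < p_rain
    amounts = rng.gamma(shape=0.8, scale=profile.rain_scale, size=n)
    precipitation = np.where(wet, amounts, 0.0)

    # diurnal temperature range, compressed on wet (cloudy) days
    dtr = 8.0 + 2.0 * np.sin(np.pi * _DAYS / n) + rng.normal(0.0, 1.2, size=n)
    dtr = np.clip(dtr, 1.0, None)
    dtr = np.where(wet, 0.75 * dtr, dtr)

    tmean = _seasonal_temperature(_DAYS) + profile.temp_offset + year_anom + anom
    tmin = tmean - dtr / 2.0
    tmax = tmean + dtr / 2.0

    radiation = (
        _seasonal_radiation(_DAYS)
        + profile.radiation_offset
        + rng.normal(0.0, 2.0, size=n)
    )
    radiation = np.where(wet, 0.6 * radiation, radiation)
    radiation = np.clip(radiation, 0.5, None)

    # Hargreaves-style reference evapotranspiration proxy: increases with the
    # diurnal range and with radiation.
    etp = 0.0023 * (tmean + 17.8) * np.sqrt(dtr) * radiation
    etp = np.clip(etp, 0.0, None)

    return ClimateSeries(
        site_id=profile.name,
        year=year,
        tmin=tmin,
        tmax=tmax,
        radiation=radiation,
        evapotranspiration=etp,
        precipitation=precipitation,
    )


def generate_climate_set(
    n_sites: int = 5,
    years: Iterable[int] = range(1975, 2013),
    seed: int | None = None,
    site_profiles: Sequence[SiteProfile] | None = None,
) -> ClimateSet:
    """Generate one season per (site, year).

    Each (site, year) pair gets an independent random substream derived from
    ``seed``, so the output is bitwise reproducible and independent of
    generation order.
    """
    years = list(years)
    if not years:
        raise ValueError("year range is empty")
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    if site_profiles is None:
        site_profiles = default_site_profiles(n_sites)
    elif len(site_profiles) != n_sites:
        raise ValueError("len(site_profiles) must equal n_sites")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")

    series = []
    for si, profile in enumerate(site_profiles):
        for year in years:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), si, int(year)]))
            series.append(_generate_series(profile, year, rng))
    return ClimateSet(tuple(series))


def write_climate_csv(climate: ClimateSet, path) -> None:
    """Write a ClimateSet in long format (one row per site/year/day)."""
    frames = []
    for s in climate:
        frames.append(
            pd.DataFrame(
                {
                    "site": s.site_id,
                    "year": s.year,
                    "day": _DAYS,
                    "tmin": s.tmin,
                    "tmax": s.tmax,
                    "radiation": s.radiation,
                    "etp": s.evapotranspiration,
                    "precipitation": s.precipitation,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_climate_csv(path) -> ClimateSet:
    """Read a climate CSV written by :func:`write_climate_csv`.

    Validates the schema, the 180-day season length per (site, year) and the
    physical invariants (tmax >= tmin, nonnegative fluxes); errors name the
    offending series and day.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"climate CSV is missing columns: {missing}")
    for col in CSV_COLUMNS[2:]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in column '{col}'")
    series = []
    for (site, year), grp in df.groupby(["site", "year"], sort=False):
        grp = grp.sort_values("day")
        if len(grp) != SEASON_LENGTH or not np.array_equal(grp["day"].to_numpy(), _DAYS):
            raise ValueError(
                f"series ({site}, {year}) has {len(grp)} days, expected {SEASON_LENGTH} (1..180)"
            )
        series.append(
            ClimateSeries(
                site_id=str(site),
                year=int(year),
                tmin=grp["tmin"].to_numpy(float),
                tmax=grp["tmax"].to_numpy(float),
                radiation=grp["radiation"].to_numpy(float),
                evapotranspiration=grp["etp"].to_numpy(float),
                precipitation=grp["precipitation"].to_numpy(float),
            )
        )
    return ClimateSet(tuple(series))
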