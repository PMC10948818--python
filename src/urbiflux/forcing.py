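"""Synthetic hourly meteorological forcing.

Generates the driver series the flux model consumes: 2-m air temperature,
photosynthetically active radiation (PAR), vapor pressure deficit (VPD),
wind speed, precipitation and near-surface CO2 concentration, on an hourly
local-time axis.  Five summer climate archetypes (arid through marine)
emulate the continental east-west contrast in moisture regime; optional
heatwave windows superimpose a temperature (and VPD) excursion.

The generator is deliberately simple - diurnal sinusoids plus seeded daily
anomalies - and is not a radiation-transfer or boundary-layer model.  All
randomness flows from a single integer seed, and identical inputs give
bitwise-identical output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidArgumentError

__all__ = [
    "FORCING_COLUMNS",
    "HeatwaveWindow",
    "ClimateArchetype",
    "ARCHETYPES",
    "synthesize_forcing",
    "season_calendar",
    "validate_forcing",
]

#: Column schema of a forcing series (hourly DataFrame, DatetimeIndex).
FORCING_COLUMNS = ("T_air", "PAR", "VPD", "U", "precip", "CO2")

# Daily temperature-anomaly AR(1) process (degC, shared by all archetypes).
# Scaled so a monthly mean stays within ~0.5 degC of the archetype mean.
_ANOM_SD = 0.6
_ANOM_RHO = 0.5
# Diurnal peak hour of air temperature (local time).
_T_PEAK_HOUR = 15
# Hours into which convective precipitation is placed (afternoon only, so a
# rain event can never coincide with or immediately follow the nocturnal
# irrigation window).
_RAIN_HOURS = np.arange(12, 19)
# VPD excursion per degree of heatwave offset (kPa / degC).
_VPD_PER_DEGC = 0.08
# Amplitude of the diurnal CO2 cycle (ppm; nocturnal maximum).
_CO2_AMPLITUDE = 8.0


@dataclass(frozen=True)
class HeatwaveWindow:
    """A date range over which air temperature is offset upward."""

    start: dt.date
    end: dt.date
    t_offset: float  # degC added to T_air inside the window

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ConfigError(
                f"heatwave window reversed: start={self.start} end={self.end}"
            )

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass(frozen=True)
class ClimateArchetype:
    """Summer climate archetype parameterizing the forcing generator.

    Parameters
    ----------
    T_mean, T_amplitude
        Seasonal-mean 2-m air temperature and half-range of the diurnal
        cycle (degC).
    PAR_peak
        Clear-sky solar-noon PAR (W m-2).
    VPD_mean
        Scale of the vapor pressure deficit diurnal cycle (kPa).
    rain_probability, rain_depth
        Daily Bernoulli probability of a convective rain event and the mean
        of its exponentially distributed depth (mm).
    CO2_base
        Background CO2 concentration (ppm).
    U_mean
        Mean near-surface wind speed (m s-1).
    sunrise, sunset
        Local clock hours bounding the daylight half-sine of PAR.
    heatwave_windows
        Date ranges with a temperature offset added to T_air (and a
        proportional VPD excursion).
    """

    name: str
    T_mean: float
    T_amplitude: float
    PAR_peak: float
    VPD_mean: float
    rain_probability: float
    rain_depth: float
    CO2_base: float = 420.0
    U_mean: float = 3.0
    sunrise: int = 6
    sunset: int = 20
    heatwave_windows: tuple[HeatwaveWindow, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.T_amplitude <= 0:
            raise ConfigError("T_amplitude must be positive")
        if self.PAR_peak <= 0:
            raise ConfigError("PAR_peak must be positive")
        if not 0.0 <= self.rain_probability <= 1.0:
            raise ConfigError("rain_probability must be in [0, 1]")
        if self.CO2_base <= 0:
            raise ConfigError("CO2_base must be positive")
        if not 0 <= self.sunrise < self.sunset <= 24:
            raise ConfigError("require 0 <= sunrise < sunset <= 24")

    def with_heatwave(self, window: HeatwaveWindow) -> "ClimateArchetype":
        """Return a copy with an additional heatwave window."""
        return replace(self, heatwave_windows=self.heatwave_windows + (window,))


#: Packaged archetype presets.  The moisture contrast (arid: rare rain and
#: high VPD; humid_continental: frequent rain and moderate VPD) is what
#: drives the soil-water-dominant vs temperature-dominant respiration
#: responses in the paired-scenario module.
ARCHETYPES: dict[str, ClimateArchetype] = {
    a.name: a
    for a in (
        ClimateArchetype("arid", T_mean=33.0, T_amplitude=8.0, PAR_peak=950.0,
                         VPD_mean=2.4, rain_probability=0.03, rain_depth=4.0),
        ClimateArchetype("semi_arid", T_mean=28.0, T_amplitude=9.0,
                         PAR_peak=900.0, VPD_mean=1.7,
                         rain_probability=0.12, rain_depth=5.0),
        ClimateArchetype("humid_subtropical", T_mean=28.0, T_amplitude=5.0,
                         PAR_peak=850.0, VPD_mean=1.3,
                         rain_probability=0.55, rain_depth=10.0),
        ClimateArchetype("humid_continental", T_mean=24.0, T_amplitude=6.0,
                         PAR_peak=800.0, VPD_mean=1.1,
                         rain_probability=0.50, rain_depth=8.0),
        ClimateArchetype("marine", T_mean=18.0, T_amplitude=5.0,
                         PAR_peak=750.0, VPD_mean=0.8,
                         rain_probability=0.30, rain_depth=5.0),
    )
}


def get_archetype(name: str) -> ClimateArchetype:
    """Look up a packaged archetype by name."""
    try:
        return ARCHETYPES[name]
    except KeyError:
        raise ConfigError(
            f"unknown archetype {name!r}; available: {sorted(ARCHETYPES)}"
        ) from None


def season_calendar(start: dt.date, end: dt.date) -> int:
    """Inclusive day count of a season, e.g. May 1 - Aug 31 -> 123."""
    if end < start:
        raise InvalidArgumentError(f"reversed date range: {start} > {end}")
    return (end - start).days + 1


def synthesize_forcing(
    archetype: ClimateArchetype | str,
    start_date: dt.date,
    n_days: int,
    seed: int,
) -> pd.DataFrame:
    """Generate a seeded hourly forcing series.

    Returns a DataFrame with 24*n_days rows, DatetimeIndex at 1-h step
    (interval-start labeled, local time) and columns
    ``T_air, PAR, VPD, U, precip, CO2``.
    """
    if isinstance(archetype, str):
        archetype = get_archetype(archetype)
    if n_days < 1:
        raise InvalidArgumentError(f"n_days must be >= 1, got {n_days}")

    rng = np.random.default_rng(seed)
    a = archetype
    hours = np.arange(24)
    daylight = (hours > a.sunrise) & (hours < a.sunset)
    sun = np.where(
        daylight,
        np.sin(np.pi * (hours - a.sunrise) / (a.sunset - a.sunrise)),
        0.0,
    )
    diurnal_T = a.T_amplitude * np.cos(2 * np.pi * (hours - _T_PEAK_HOUR) / 24)

    frames = []
    anom = 0.0
    innov_sd = _ANOM_SD * np.sqrt(1 - _ANOM_RHO**2)
    for d in range(n_days):
        day = start_date + dt.timedelta(days=d)
        anom = _ANOM_RHO * anom + innov_sd * rng.standard_normal()
        hw = sum(w.t_offset for w in a.heatwave_windows if w.contains(day))

        rain_day = rng.random() < a.rain_probability
        precip = np.zeros(24)
        if rain_day:
            depth = rng.exponential(a.rain_depth)
            n_h = int(rng.integers(1, 4))
            at = rng.choice(_RAIN_HOURS, size=n_h, replace=False)
            precip[np.sort(at)] = depth / n_h
        cloud = 0.35 if rain_day else 1.0

        T_air = a.T_mean + anom + hw + diurnal_T
        PAR = a.PAR_peak * cloud * sun
        vpd_scale = 0.5 if rain_day else 1.0
        VPD = (a.VPD_mean * vpd_scale * (0.45 + 1.1 * sun) + _VPD_PER_DEGC * hw)
        VPD = VPD * np.exp(0.08 * rng.standard_normal(24))
        VPD = np.maximum(VPD, 0.02)
        U = np.maximum(a.U_mean + 0.8 * rng.standard_normal(24), 0.0)
        CO2 = a.CO2_base + _CO2_AMPLITUDE * np.cos(2 * np.pi * (hours - 4) / 24)

        idx = pd.date_range(pd.Timestamp(day), periods=24, freq="h")
        frames.append(
            pd.DataFrame(
                {"T_air": T_air, "PAR": PAR, "VPD": VPD, "U": U,
                 "precip": precip, "CO2": CO2},
                index=idx,
            )
        )
    out = pd.concat(frames)
    out.index.name = "time"
    return out


def validate_forcing(df: pd.DataFrame) -> pd.DataFrame:
    """Check a forcing series against the schema invariants.

    Raises SchemaError/DataError on violation; returns the frame unchanged.
    """
    from .errors import DataError, SchemaError

    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"forcing series missing column(s): {missing}")
    if not isinstance(df.index, pd.DatetimeIndex):
        raise DataError("forcing index must be a DatetimeIndex")
    if len(df) > 1:
        deltas = np.diff(df.index.asi8)
        if not np.all(deltas == 3600 * 10**9):
            raise DataError("forcing timestamps must increase at a 1-h step")
    if df[list(FORCING_COLUMNS)].isna().any().any():
        raise DataError("forcing contains NaN values")
    for col in ("PAR", "U", "precip", "CO2"):
        if (df[col] < 0).any():
            raise DataError(f"negative values in {col}")
    if (df["CO2"] <= 0).any():
        raise DataError("CO2 must be positive")
    return df
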