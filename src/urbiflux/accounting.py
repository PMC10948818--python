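"""Carbon accounting: unit conversions and vehicle-electrification
equivalents.

Converts an irrigation-induced NEE change (gCO2 m-2 d-1) applied over a
fraction of a region's urban area into tons of CO2 per day and per season,
and expresses that as the number of gasoline-to-battery-electric vehicle
(BEV) replacements with the same annual on-road emission change.  Also the
package's single home for gCO2 m-2 d-1 <-> umol CO2 m-2 s-1 conversions.

Default per-vehicle emissions follow U.S. DOE national-average on-road
figures: 15.7 kgCO2 d-1 for a gasoline passenger car vs 3.5 kgCO2 d-1 for
a BEV (power-mix average; manufacturing and charging-infrastructure
emissions excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "CO2_MOLAR_MASS",
    "GASOLINE_KG_PER_DAY",
    "BEV_KG_PER_DAY",
    "CONUS_URBAN_AREA_M2",
    "AccountingInputs",
    "flux_to_molar",
    "molar_to_flux",
    "per_vehicle_saving",
    "regional_release",
    "bev_equivalents",
    "equivalence_report",
]

#: Molar mass of CO2 (g mol-1).
CO2_MOLAR_MASS = 44.01
#: U.S. DOE national-average on-road emissions (kgCO2 per vehicle-day).
GASOLINE_KG_PER_DAY = 15.7
BEV_KG_PER_DAY = 3.5
#: Total urban area of the lower 48 states (m2).
CONUS_URBAN_AREA_M2 = 2.7e11

_SECONDS_PER_DAY = 86400.0


def flux_to_molar(flux):
    """gCO2 m-2 d-1 -> umol CO2 m-2 s-1 (sign preserved)."""
    return np.asarray(flux, dtype=float) / CO2_MOLAR_MASS * 1e6 / _SECONDS_PER_DAY


def molar_to_flux(molar):
    """umol CO2 m-2 s-1 -> gCO2 m-2 d-1; inverse of :func:`flux_to_molar`."""
    return np.asarray(molar, dtype=float) * CO2_MOLAR_MASS / 1e6 * _SECONDS_PER_DAY


@dataclass(frozen=True)
class AccountingInputs:
    """Inputs of the regional carbon-equivalence chain.

    ``dnee`` is the season-mean NEE change (gCO2 m-2 d-1, positive = extra
    release); ``irr_fraction`` the fraction of the urban area that irrigates
    as modeled (0.15 by default; reported estimates range up to 0.20);
    ``season_days`` the length of the irrigation season (123 for a
    May 1 - Aug 31 summer); ``vehicle_days`` the vehicle-use year (365).
    """

    dnee: float
    urban_area: float = CONUS_URBAN_AREA_M2
    irr_fraction: float = 0.15
    season_days: int = 123
    gas_daily: float = GASOLINE_KG_PER_DAY
    bev_daily: float = BEV_KG_PER_DAY
    vehicle_days: int = 365

    def __post_init__(self) -> None:
        if self.urban_area <= 0 or self.season_days <= 0 or self.vehicle_days <= 0:
            raise InvalidArgumentError("areas and day counts must be positive")
        if not 0.0 <= self.irr_fraction <= 1.0:
            raise InvalidArgumentError("irr_fraction must be in [0, 1]")


def per_vehicle_saving(
    gas_daily: float = GASOLINE_KG_PER_DAY,
    bev_daily: float = BEV_KG_PER_DAY,
    vehicle_days: int = 365,
) -> tuple[float, float]:
    """Per-vehicle CO2 saving of a gasoline-to-BEV replacement.

    Returns ``(daily kgCO2, annual tons CO2)``; with the default DOE
    figures, 12.2 kg d-1 and about 4.45 t yr-1.
    """
    if not gas_daily >= bev_daily >= 0:
        raise InvalidArgumentError(
            "require gas_daily >= bev_daily >= 0 (saving must be nonnegative)"
        )
    daily = gas_daily - bev_daily
    return daily, daily * vehicle_days / 1000.0


def regional_release(inputs: AccountingInputs) -> tuple[float, float]:
    """Regional CO2 release from the NEE change (tons per day, per season).

    ``daily = dnee * irr_fraction * urban_area * 1e-6``; negative values
    mean net additional sequestration.
    """
    daily = inputs.dnee * inputs.irr_fraction * inputs.urban_area * 1e-6
    return daily, daily * inputs.season_days


def bev_equivalents(seasonal_tons: float, annual_saving_tons: float) -> float:
    """Number of vehicle replacements equivalent to a seasonal CO2 change.

    Positive = the release offsets that many gasoline-to-BEV replacements;
    negative = the extra sequestration equals that many BEV adoptions.
    """
    if annual_saving_tons <= 0:
        raise InvalidArgumentError("annual per-vehicle saving must be positive")
    return seasonal_tons / annual_saving_tons


def equivalence_report(inputs: AccountingInputs) -> dict[str, float]:
    """Run the full accounting chain; raw (unrounded) values.

    Keys: per-vehicle saving (kg d-1, t yr-1), regional release (t d-1,
    t per season), BEV equivalents (vehicles), and the NEE change in molar
    units.
    """
    veh_daily, veh_annual = per_vehicle_saving(
        inputs.gas_daily, inputs.bev_daily, inputs.vehicle_days
    )
    rel_daily, rel_season = regional_release(inputs)
    return {
        "dnee_g_m2_d": inputs.dnee,
        "dnee_umol_m2_s": float(flux_to_molar(inputs.dnee)),
        "per_vehicle_saving_kg_d": veh_daily,
        "per_vehicle_saving_t_yr": veh_annual,
        "regional_release_t_d": rel_daily,
        "regional_release_t_season": rel_season,
        "bev_equivalents": bev_equivalents(rel_season, veh_annual),
    }
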