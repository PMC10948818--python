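"""Paired irrigation scenarios and co-benefit/tradeoff classification.

A scenario runs the soil bucket and the biogenic flux model twice over one
shared forcing series - identical in everything except whether the nightly
irrigation protocol is enabled - and diagnoses the daily-mean differences
(irrigated minus baseline): dT2m, dT_soil, dSWC, dGPP_u, dR_u, dNEE_u.

Because irrigation simultaneously wets (raising respiration and
photosynthesis) and cools the soil (lowering respiration), the sign of
dR_u depends on which driver wins.  ``decompose_dR`` separates the two by
counterfactual re-evaluation of the respiration function on mixed
trajectories - exact for any pluggable respiration form, with the
interaction left as an explicit residual - and ``classify_dominance``
labels the run soil-water-dominant or temperature-dominant.  The joint
(dGPP_u, dR_u) outcome is classified into five pathway categories from
strong co-benefit (GPP up, respiration down) to strong tradeoff.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .biogenic import (
    CanyonGeometry,
    TileWeights,
    VegTileParams,
    daily_means,
    ecosystem_respiration,
    run_fluxes,
    tile_aggregate,
)
from .errors import InvalidArgumentError
from .forcing import ClimateArchetype, get_archetype, synthesize_forcing
from .soil import IrrigationPolicy, SoilParams, air_temperature_response, run_soil

__all__ = [
    "CATEGORIES",
    "DOMINANCE_LABELS",
    "ScenarioDelta",
    "PairedRun",
    "DRDecomposition",
    "PathwayClass",
    "default_surface",
    "run_paired",
    "run_archetype_scenario",
    "decompose_dR",
    "classify_dominance",
    "classify_pathway",
    "classify_run",
    "gpp_share",
    "subset_means",
]

CATEGORIES = (
    "strong_cobenefit",
    "weak_cobenefit",
    "neutral",
    "weak_tradeoff",
    "strong_tradeoff",
)
DOMINANCE_LABELS = ("soil_water_dominant", "temperature_dominant", "balanced")

#: Default neutrality half-width on season-mean flux deltas (gCO2 m-2 d-1).
DEFAULT_EPS = 0.05
#: Default strong-tradeoff cutoff on the GPP offset share (-).
DEFAULT_SHARE_LO = 0.25
#: Default tie tolerance of the dominance comparison (gCO2 m-2 d-1).
DEFAULT_DOMINANCE_TOL = 0.01

# Per-density scaling of vegetation abundance (low, medium, high density):
# denser development means less canopy, less pervious soil, taller canyons.
_DENSITY_VEG_SCALE = (1.0, 0.70, 0.40)
_DENSITY_CANYONS = (
    CanyonGeometry(w=20.0, h=6.0, r=8.0),
    CanyonGeometry(w=20.0, h=10.0, r=10.0),
    CanyonGeometry(w=18.0, h=20.0, r=12.0),
)

# Low-density-tile vegetation abundance per climate archetype: arid cities
# carry sparse xeric canopies, humid cities dense ones.  (LAI, f_V, f_s)
_ARCHETYPE_VEG = {
    "arid": (1.6, 0.25, 0.35),
    "semi_arid": (2.0, 0.32, 0.38),
    "humid_subtropical": (3.2, 0.48, 0.48),
    "humid_continental": (3.5, 0.50, 0.50),
    "marine": (3.0, 0.45, 0.45),
}

# Climatological initial normalized soil moisture per archetype (summer
# equilibrium of the bucket under the archetype's rain/ET regime).
_ARCHETYPE_THETA0 = {
    "arid": 0.20,
    "semi_arid": 0.30,
    "humid_subtropical": 0.85,
    "humid_continental": 0.90,
    "marine": 0.50,
}


def default_surface(
    archetype: ClimateArchetype | str,
) -> tuple[SoilParams, IrrigationPolicy, tuple[VegTileParams, ...], TileWeights]:
    """Packaged surface configuration for a climate archetype.

    Returns (soil parameters, irrigation policy, three density tiles,
    tile weights).  Soil hydraulic and cooling constants are shared across
    archetypes; vegetation abundance scales with the archetype's moisture
    regime and with development density.
    """
    name = archetype if isinstance(archetype, str) else archetype.name
    if name not in _ARCHETYPE_VEG:
        from .errors import ConfigError

        raise ConfigError(
            f"no packaged surface for archetype {name!r}; "
            f"available: {sorted(_ARCHETYPE_VEG)}"
        )
    lai0, fv0, fs0 = _ARCHETYPE_VEG[name]
    tiles = tuple(
        VegTileParams(
            f_V=fv0 * s, f_s=fs0 * s, LAI=lai0 * s, canyon=c
        )
        for s, c in zip(_DENSITY_VEG_SCALE, _DENSITY_CANYONS)
    )
    soil = SoilParams(theta_init=_ARCHETYPE_THETA0[name])
    return soil, IrrigationPolicy(), tiles, TileWeights()


@dataclass(frozen=True)
class ScenarioDelta:
    """Daily-mean paired differences (irrigated minus baseline).

    ``daily`` has one row per day and columns
    ``dT2m, dTsoil, dSWC, dGPP, dR, dNEE`` (temperatures degC, dSWC in
    normalized moisture units, fluxes gCO2 m-2 d-1).  Season means are the
    unweighted mean of daily means.
    """

    daily: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("dT2m", "dTsoil", "dSWC", "dGPP", "dR", "dNEE")
                   if c not in self.daily.columns]
        if missing:
            raise InvalidArgumentError(f"delta table missing {missing}")

    @property
    def season(self) -> pd.Series:
        return self.daily.mean()

    def __getitem__(self, key: str) -> pd.Series:
        return self.daily[key]


@dataclass(frozen=True)
class PairedRun:
    """Everything produced by one with/without-irrigation experiment."""

    forcing: pd.DataFrame
    soil_base: pd.DataFrame
    soil_irr: pd.DataFrame
    flux_base: pd.DataFrame
    flux_irr: pd.DataFrame
    dT2m_hourly: pd.Series
    delta: ScenarioDelta
    soil_params: SoilParams
    tiles: tuple[VegTileParams, ...]
    weights: TileWeights


@dataclass(frozen=True)
class DRDecomposition:
    """Moisture/temperature split of the respiration change dR_u.

    All terms are season-mean fluxes in gCO2 m-2 d-1:
    ``moisture`` re-evaluates respiration with the irrigated moisture on
    the baseline temperature, ``temperature`` the converse, and
    ``residual = dR - moisture - temperature`` is the interaction.  Under
    wetting plus cooling, moisture >= 0 and temperature <= 0.
    """

    moisture: float
    temperature: float
    residual: float
    dR: float


@dataclass(frozen=True)
class PathwayClass:
    """Joint classification of a paired run."""

    category: str
    dominance: str
    gpp_share: float  # NaN when undefined

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidArgumentError(f"unknown category {self.category!r}")
        if self.dominance not in DOMINANCE_LABELS:
            raise InvalidArgumentError(f"unknown dominance {self.dominance!r}")


def run_paired(
    forcing: pd.DataFrame,
    soil_params: SoilParams,
    policy: IrrigationPolicy,
    tiles: Sequence[VegTileParams],
    weights: TileWeights,
) -> PairedRun:
    """Run the baseline and irrigated arms over one shared forcing series.

    The two arms differ only in ``policy.enabled``: the baseline arm runs
    with irrigation disabled, the irrigated arm with the supplied policy.
    Evaporative air cooling (``-cool_air * dET``) is fed back into the
    irrigated arm's leaf temperature.  If the supplied policy is itself
    disabled the arms are identical and every delta is zero.
    """
    base_policy = replace(policy, enabled=False)
    soil_base = run_soil(forcing, soil_params, base_policy)
    soil_irr = run_soil(forcing, soil_params, policy)

    dT2m_hourly = pd.Series(
        air_temperature_response(
            soil_irr["ET"].to_numpy(), soil_base["ET"].to_numpy(), soil_params
        ),
        index=forcing.index,
        name="dT2m",
    )
    T_air_irr = forcing["T_air"] + dT2m_hourly

    flux_base = run_fluxes(forcing, soil_base, tiles, weights)
    flux_irr = run_fluxes(forcing, soil_irr, tiles, weights, T_air=T_air_irr)

    d_flux = daily_means(flux_irr - flux_base)  # gCO2 m-2 d-1
    dGPP = d_flux["GPP_u"]
    dR = d_flux["R_u"]
    daily = pd.DataFrame(
        {
            "dT2m": dT2m_hourly.resample("D").mean(),
            "dTsoil": (soil_irr["T_soil"] - soil_base["T_soil"]).resample("D").mean(),
            "dSWC": (soil_irr["theta"] - soil_base["theta"]).resample("D").mean(),
            "dGPP": dGPP,
            "dR": dR,
            "dNEE": dR - dGPP,
        }
    )
    daily.index.name = "day"
    return PairedRun(
        forcing=forcing,
        soil_base=soil_base,
        soil_irr=soil_irr,
        flux_base=flux_base,
        flux_irr=flux_irr,
        dT2m_hourly=dT2m_hourly,
        delta=ScenarioDelta(daily),
        soil_params=soil_params,
        tiles=tuple(tiles),
        weights=weights,
    )


def run_archetype_scenario(
    archetype: ClimateArchetype | str,
    start_date: dt.date,
    n_days: int,
    seed: int,
) -> PairedRun:
    """Convenience wrapper: synthesize forcing for an archetype and run the
    paired experiment with the packaged surface configuration."""
    arch = get_archetype(archetype) if isinstance(archetype, str) else archetype
    forcing = synthesize_forcing(arch, start_date, n_days, seed)
    soil_params, policy, tiles, weights = default_surface(arch.name)
    return run_paired(forcing, soil_params, policy, tiles, weights)


def _aggregate_respiration(
    T_soil: np.ndarray,
    theta: np.ndarray,
    tiles: Sequence[VegTileParams],
    weights: TileWeights,
) -> np.ndarray:
    return tile_aggregate(
        weights, [ecosystem_respiration(T_soil, theta, p) for p in tiles]
    )


def decompose_dR(run: PairedRun) -> DRDecomposition:
    """Split the season-mean dR_u into moisture and temperature terms.

    The respiration function is re-evaluated hourly on mixed trajectories:
    the moisture term swaps in the irrigated soil moisture at baseline soil
    temperature, the temperature term swaps in the irrigated temperature at
    baseline moisture.  The interaction residual makes the three terms sum
    to dR_u exactly for any respiration formulation.
    """
    T_b = run.soil_base["T_soil"].to_numpy()
    T_i = run.soil_irr["T_soil"].to_numpy()
    th_b = run.soil_base["theta"].to_numpy()
    th_i = run.soil_irr["theta"].to_numpy()
    tiles, weights = run.tiles, run.weights

    r_bb = _aggregate_respiration(T_b, th_b, tiles, weights)
    r_bi = _aggregate_respiration(T_b, th_i, tiles, weights)
    r_ib = _aggregate_respiration(T_i, th_b, tiles, weights)
    r_ii = _aggregate_respiration(T_i, th_i, tiles, weights)

    moisture = float(np.mean(r_bi - r_bb)) * 24.0
    temperature = float(np.mean(r_ib - r_bb)) * 24.0
    dR = float(np.mean(r_ii - r_bb)) * 24.0
    return DRDecomposition(
        moisture=moisture,
        temperature=temperature,
        residual=dR - moisture - temperature,
        dR=dR,
    )


def classify_dominance(
    moisture: float, temperature: float, tol: float = DEFAULT_DOMINANCE_TOL
) -> str:
    """Which driver controls the respiration change.

    Soil-water dominant when the moisture term outweighs the temperature
    term (respiration tends to rise after irrigation), temperature dominant
    in the converse case, balanced when the magnitudes agree within
    ``tol``.
    """
    m, t = abs(moisture), abs(temperature)
    if m > t + tol:
        return "soil_water_dominant"
    if t > m + tol:
        return "temperature_dominant"
    return "balanced"


def classify_pathway(
    dGPP: float,
    dR: float,
    eps: float = DEFAULT_EPS,
    share_lo: float = DEFAULT_SHARE_LO,
) -> str:
    """Five-way co-benefit/tradeoff category of season-mean (dGPP, dR).

    With dNEE = dR - dGPP:

    * ``neutral`` - |dNEE| <= eps.
    * co-benefit side (dNEE < -eps): ``strong_cobenefit`` when GPP rises
      and respiration falls simultaneously (dGPP > eps and dR < -eps),
      else ``weak_cobenefit``.
    * tradeoff side (dNEE > eps): ``strong_tradeoff`` when GPP itself
      drops (dGPP < -eps) or when a large respiration increase (dR > eps)
      is offset by almost no GPP gain (offset share below ``share_lo``);
      else ``weak_tradeoff``.

    Total on the (dGPP, dR) plane: every input maps to exactly one
    category.
    """
    if not (math.isfinite(dGPP) and math.isfinite(dR)):
        raise InvalidArgumentError("dGPP and dR must be finite")
    dNEE = dR - dGPP
    if abs(dNEE) <= eps:
        return "neutral"
    if dNEE < 0:
        if dGPP > eps and dR < -eps:
            return "strong_cobenefit"
        return "weak_cobenefit"
    gain = max(dGPP, 0.0)
    offset_share = gain / (gain + max(dR, 0.0)) if gain + max(dR, 0.0) > 0 else 0.0
    if dGPP < -eps or (dR > eps and offset_share < share_lo):
        return "strong_tradeoff"
    return "weak_tradeoff"


def gpp_share(dGPP: float, dR: float) -> float:
    """Contribution of the GPP gain to a co-benefit dNEE reduction.

    ``share = max(dGPP, 0) / (max(dGPP, 0) + max(-dR, 0))``, the fraction
    of the NEE improvement delivered by extra photosynthesis rather than by
    suppressed respiration.  NaN when the denominator is zero (no
    improving component).
    """
    num = max(dGPP, 0.0)
    den = num + max(-dR, 0.0)
    if den == 0.0:
        return float("nan")
    return num / den


def classify_run(
    run: PairedRun,
    eps: float = DEFAULT_EPS,
    share_lo: float = DEFAULT_SHARE_LO,
    tol: float = DEFAULT_DOMINANCE_TOL,
) -> PathwayClass:
    """Full pathway classification of a paired run's season means."""
    season = run.delta.season
    dGPP, dR = float(season["dGPP"]), float(season["dR"])
    dec = decompose_dR(run)
    return PathwayClass(
        category=classify_pathway(dGPP, dR, eps=eps, share_lo=share_lo),
        dominance=classify_dominance(dec.moisture, dec.temperature, tol=tol),
        gpp_share=gpp_share(dGPP, dR),
    )


def subset_means(
    delta: ScenarioDelta,
    windows: Iterable[tuple[dt.date, dt.date]],
) -> pd.DataFrame:
    """Daily-mean deltas averaged inside and outside date windows.

    ``windows`` is an iterable of inclusive (start, end) date pairs (or
    objects with ``start``/``end`` attributes, e.g. heatwave windows).
    Returns a two-row DataFrame indexed ``inside``/``outside``.  Windows
    that do not intersect the run raise InvalidArgumentError.
    """
    days = delta.daily.index
    mask = np.zeros(len(days), dtype=bool)
    for w in windows:
        start, end = (w.start, w.end) if hasattr(w, "start") else w
        mask |= (days >= pd.Timestamp(start)) & (days <= pd.Timestamp(end))
    if not mask.any():
        raise InvalidArgumentError("windows do not intersect the run period")
    inside = delta.daily[mask].mean()
    outside = (
        delta.daily[~mask].mean() if (~mask).any()
        else pd.Series(np.nan, index=delta.daily.columns)
    )
    return pd.DataFrame({"inside": inside, "outside": outside}).T
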