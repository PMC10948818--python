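"""Irrigated urban soil water/temperature bucket.

A single-layer volumetric bucket between wilting point and field capacity,
driven by hourly forcing.  Water enters as precipitation and as nightly
irrigation (21:00-22:00 local time by default, stopping once soil water
reaches field capacity, so the scheme never produces runoff or excess soil
water); it leaves as evapotranspiration ``ET = et_coef * VPD * theta`` and
as linear-reservoir drainage above a threshold.  Soil temperature relaxes
toward a transform of air temperature minus an evaporative-cooling term
``cool_soil * ET``; the 2-m air response to an irrigation-induced ET change
is the smaller ``-cool_air * dET``.  This bucket is a declared desk-scale
stand-in for a full canyon energy balance: it conserves water exactly and
reproduces the directional couplings (wetter and cooler soil after
irrigation, soil cooling exceeding air cooling), not absolute energetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError
from .forcing import FORCING_COLUMNS, validate_forcing

__all__ = [
    "SoilParams",
    "SoilState",
    "IrrigationPolicy",
    "irrigation_input",
    "evapotranspiration",
    "step_soil",
    "run_soil",
    "air_temperature_response",
]

#: Columns of the soil trajectory DataFrame produced by :func:`run_soil`.
SOIL_COLUMNS = (
    "swc", "theta", "T_soil", "ET", "irrigation", "drainage", "precip",
    "latent_cooling", "clamped",
)


@dataclass(frozen=True)
class SoilParams:
    """Bucket hydraulics and thermal coupling constants.

    Parameters
    ----------
    swc_fc, swc_wilt
        Volumetric water content at field capacity and wilting point
        (m3 m-3); normalized soil moisture is
        ``theta = (swc - swc_wilt) / (swc_fc - swc_wilt)``.
    depth
        Bucket depth (m); one unit of theta spans
        ``(swc_fc - swc_wilt) * depth * 1000`` mm of water.
    drain_coef
        Linear-reservoir drainage constant (d-1) applied to storage above
        ``drain_threshold``.
    drain_threshold
        Volumetric content above which drainage operates; ``None`` means
        field capacity, so the conservative irrigation scheme produces no
        drainage at all.
    et_coef
        Potential-evapotranspiration scaling (mm h-1 per kPa of VPD at
        theta = 1).
    cool_soil, cool_air
        Evaporative cooling sensitivities of soil and 2-m air temperature
        (degC per mm h-1 of latent water flux); ``cool_soil >= cool_air``
        mirrors the stronger soil response to irrigation.
    t_gain, t_offset
        Soil-temperature equilibrium ``T_eq = t_offset + t_gain * T_air
        - cool_soil * ET``.
    tau
        Soil thermal relaxation time (h).
    theta_init
        Default initial normalized moisture (climatological; avoids long
        spin-up toward the archetype's wet- or dry-season equilibrium).
    """

    swc_fc: float = 0.32
    swc_wilt: float = 0.10
    depth: float = 0.40
    drain_coef: float = 4.0
    drain_threshold: float | None = None
    et_coef: float = 0.16
    cool_soil: float = 20.0
    cool_air: float = 0.8
    t_gain: float = 1.0
    t_offset: float = 2.0
    tau: float = 4.0
    theta_init: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 < self.swc_wilt < self.swc_fc < 1.0:
            raise InvalidArgumentError(
                f"require 0 < swc_wilt < swc_fc < 1, got "
                f"swc_wilt={self.swc_wilt}, swc_fc={self.swc_fc}"
            )
        if self.depth <= 0:
            raise InvalidArgumentError("depth must be positive")
        if not self.cool_soil >= self.cool_air >= 0:
            raise InvalidArgumentError(
                "require cool_soil >= cool_air >= 0 (soil cools more than air)"
            )
        if self.et_coef < 0 or self.drain_coef < 0 or self.tau <= 0:
            raise InvalidArgumentError("nonpositive rate/relaxation constant")

    @property
    def span_mm(self) -> float:
        """Water depth (mm) spanned by one unit of normalized moisture."""
        return (self.swc_fc - self.swc_wilt) * self.depth * 1000.0

    def theta(self, swc: float | np.ndarray) -> float | np.ndarray:
        """Normalized soil moisture in [0, 1]."""
        return (swc - self.swc_wilt) / (self.swc_fc - self.swc_wilt)


@dataclass(frozen=True)
class SoilState:
    """Instantaneous bucket state."""

    swc: float  # volumetric water content, m3 m-3
    T_soil: float  # surface-layer soil temperature, degC


@dataclass(frozen=True)
class IrrigationPolicy:
    """Nightly irrigation protocol.

    Water is applied at ``rate`` (mm h-1) during the local-time clock window
    ``[window_start, window_end)`` and stops once soil water reaches
    ``target`` (defaults to field capacity), so it can never overfill the
    bucket or generate runoff.
    """

    enabled: bool = True
    window_start: int = 21
    window_end: int = 22
    rate: float = 10.0
    target: float | None = None  # None -> field capacity

    def __post_init__(self) -> None:
        if not (0 <= self.window_start < 24 and 0 < self.window_end <= 24):
            raise InvalidArgumentError("irrigation window must lie in [0, 24)")
        if self.window_end <= self.window_start:
            raise InvalidArgumentError("window_end must exceed window_start")
        if self.rate < 0:
            raise InvalidArgumentError("irrigation rate must be >= 0")

    def in_window(self, t: pd.Timestamp) -> bool:
        return self.window_start <= t.hour < self.window_end

    def swc_target(self, params: SoilParams) -> float:
        tgt = params.swc_fc if self.target is None else self.target
        if tgt > params.swc_fc:
            raise InvalidArgumentError("irrigation target exceeds field capacity")
        return tgt


def irrigation_input(
    state: SoilState,
    policy: IrrigationPolicy,
    t: pd.Timestamp,
    dt: float,
    params: SoilParams,
) -> float:
    """Irrigation water applied over one step (mm).

    Zero outside the window or when disabled; otherwise the lesser of the
    application capacity ``rate * dt`` and the depth needed to reach the
    stop target, so the target is never exceeded.
    """
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    if not policy.enabled or not policy.in_window(pd.Timestamp(t)):
        return 0.0
    deficit_mm = max(0.0, (policy.swc_target(params) - state.swc)) * params.depth * 1000.0
    return min(policy.rate * dt, deficit_mm)


def evapotranspiration(
    state: SoilState, forcing: Mapping[str, float], params: SoilParams
) -> float:
    """Latent water flux ET = et_coef * VPD * beta(theta) (mm h-1).

    The moisture stress factor is linear, beta(theta) = theta: zero at
    wilting point, unstressed at field capacity.
    """
    vpd = float(forcing["VPD"])
    if vpd < 0:
        raise InvalidArgumentError(f"negative VPD: {vpd}")
    theta = float(np.clip(params.theta(state.swc), 0.0, 1.0))
    return params.et_coef * vpd * theta


def step_soil(
    state: SoilState,
    forcing: Mapping[str, float],
    params: SoilParams,
    policy: IrrigationPolicy,
    t: pd.Timestamp,
    dt: float = 1.0,
) -> tuple[SoilState, dict[str, float]]:
    """Advance the bucket one step; return (new state, diagnostics).

    The water balance closes exactly:
    ``d(swc * depth * 1000) = precip*dt + irrigation - ET*dt - drainage``
    (all in mm).  ET is limited to the water available above wilting point,
    and storage pushed above field capacity (heavy rain) is shed to the
    drainage diagnostic; both limitations set the ``clamped`` flag.
    """
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    vals = [float(forcing[c]) for c in ("T_air", "VPD", "precip")]
    if any(np.isnan(v) for v in vals):
        raise DataError(f"NaN forcing at {t}")
    T_air, _, precip = vals

    wilt_mm = params.swc_wilt * params.depth * 1000.0
    fc_mm = params.swc_fc * params.depth * 1000.0
    S = state.swc * params.depth * 1000.0

    irr = irrigation_input(state, policy, t, dt, params)
    et_rate = evapotranspiration(state, forcing, params)
    et_demand = et_rate * dt
    available = max(0.0, S - wilt_mm) + precip * dt + irr
    clamped = False
    et = et_demand
    if et_demand > available:
        et = available
        clamped = True

    delta_mm = precip * dt + irr - et
    S_new = S + delta_mm

    thr_mm = (
        fc_mm if params.drain_threshold is None
        else params.drain_threshold * params.depth * 1000.0
    )
    drainage = 0.0
    if S_new > thr_mm:
        drainage = min(
            S_new - thr_mm, (params.drain_coef / 24.0) * (S_new - thr_mm) * dt
        )
        S_new -= drainage
    if S_new > fc_mm:
        drainage += S_new - fc_mm
        S_new = fc_mm
        clamped = True

    # increment form: a zero-flux step leaves swc bitwise unchanged
    swc_new = state.swc + (delta_mm - drainage) / (params.depth * 1000.0)
    if swc_new > params.swc_fc:
        drainage += (swc_new - params.swc_fc) * params.depth * 1000.0
        swc_new = params.swc_fc

    et_actual_rate = et / dt
    cooling = params.cool_soil * et_actual_rate
    T_eq = params.t_offset + params.t_gain * T_air - cooling
    T_new = state.T_soil + (dt / params.tau) * (T_eq - state.T_soil)

    new_state = SoilState(swc=swc_new, T_soil=T_new)
    diag = {
        "ET": et_actual_rate,
        "irrigation": irr,
        "drainage": drainage,
        "precip": precip * dt,
        "latent_cooling": cooling,
        "clamped": float(clamped),
    }
    return new_state, diag


def initial_state(
    params: SoilParams, T_air0: float, theta0: float | None = None
) -> SoilState:
    """Default initial state: climatological moisture (``params.theta_init``
    unless overridden), soil in thermal equilibrium with the first forcing
    hour (before any evaporative cooling)."""
    if theta0 is None:
        theta0 = params.theta_init
    swc0 = params.swc_wilt + theta0 * (params.swc_fc - params.swc_wilt)
    return SoilState(swc=swc0, T_soil=params.t_offset + params.t_gain * T_air0)


def run_soil(
    forcing: pd.DataFrame,
    params: SoilParams,
    policy: IrrigationPolicy,
    init: SoilState | None = None,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Integrate the bucket over a forcing series.

    Returns an hourly DataFrame (same index as the forcing) with state
    columns ``swc, theta, T_soil`` and per-step diagnostics
    ``ET, irrigation, drainage, precip, latent_cooling, clamped``.
    State columns are end-of-step values.
    """
    validate_forcing(forcing)
    state = init or initial_state(params, float(forcing["T_air"].iloc[0]))
    rows = np.empty((len(forcing), len(SOIL_COLUMNS)))
    cols = {c: i for i, c in enumerate(SOIL_COLUMNS)}
    records = forcing[list(FORCING_COLUMNS)].to_dict("records")
    for i, (t, rec) in enumerate(zip(forcing.index, records)):
        state, diag = step_soil(state, rec, params, policy, t, dt)
        rows[i, cols["swc"]] = state.swc
        rows[i, cols["theta"]] = np.clip(params.theta(state.swc), 0.0, 1.0)
        rows[i, cols["T_soil"]] = state.T_soil
        for k in ("ET", "irrigation", "drainage", "precip",
                  "latent_cooling", "clamped"):
            rows[i, cols[k]] = diag[k]
    out = pd.DataFrame(rows, columns=list(SOIL_COLUMNS), index=forcing.index)
    out.index.name = "time"
    return out


def air_temperature_response(
    ET_on: float | np.ndarray,
    ET_off: float | np.ndarray,
    params: SoilParams,
) -> float | np.ndarray:
    """2-m air temperature change from an irrigation-induced ET change.

    ``dT2m = -cool_air * (ET_on - ET_off)``; nonpositive whenever
    irrigation raises ET.
    """
    on = np.asarray(ET_on, dtype=float)
    off = np.asarray(ET_off, dtype=float)
    if (on < 0).any() or (off < 0).any():
        raise InvalidArgumentError("latent fluxes must be >= 0")
    out = -params.cool_air * (on - off)
    if np.isscalar(ET_on) and np.isscalar(ET_off):
        return float(out)
    return out
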