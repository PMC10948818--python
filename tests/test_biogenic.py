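"""Flux equations: leaf/canopy GPP, Q10 respiration, tiling, NEE."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import simpson

from urbiflux import (
    CanyonGeometry,
    TileWeights,
    VegTileParams,
    canopy_gpp,
    ecosystem_respiration,
    leaf_gpp,
    net_ecosystem_exchange,
    run_fluxes,
    run_soil,
    synthesize_forcing,
    tile_aggregate,
)
from urbiflux.biogenic import daily_means
from urbiflux.errors import InvalidArgumentError
from urbiflux.scenario import default_surface

PARAMS = VegTileParams()
DRIVERS = dict(T_sk=25.0, CO2=420.0, U=3.0, theta=0.8)


def _a_cap(p, T_sk, CO2, U, theta):
    fT = np.exp(-(((T_sk - p.T_opt) / p.T_width) ** 2))
    fC = CO2 / (CO2 + p.K_C)
    fU = min(1.0, U / p.u_ref)
    return p.A_max * fT * fC * fU * theta


class TestLeafGpp:
    def test_dark_and_dry_limits(self):
        assert leaf_gpp(0.0, **DRIVERS, params=PARAMS) == 0.0
        assert leaf_gpp(400.0, 25.0, 420.0, 3.0, 0.0, PARAMS) == 0.0

    def test_light_saturation_approaches_cap(self):
        cap = _a_cap(PARAMS, **{k: DRIVERS[k] for k in ("T_sk", "CO2", "U", "theta")})
        assert leaf_gpp(1e5, **DRIVERS, params=PARAMS) == pytest.approx(cap, rel=1e-9)
        assert leaf_gpp(400.0, **DRIVERS, params=PARAMS) < cap

    @pytest.mark.parametrize("driver, grid", [
        ("PAR", [0, 50, 200, 600, 1000]),
        ("CO2", [200, 350, 500, 800]),
        ("U", [0.1, 0.5, 1.5, 3.0, 6.0]),
        ("theta", [0.0, 0.2, 0.5, 0.8, 1.0]),
    ])
    def test_monotone_nondecreasing_in_each_driver(self, driver, grid):
        vals = []
        for g in grid:
            kw = dict(PAR_leaf=400.0, **DRIVERS)
            if driver == "PAR":
                kw["PAR_leaf"] = g
            else:
                kw[driver] = g
            vals.append(leaf_gpp(**kw, params=PARAMS))
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invalid_drivers(self):
        with pytest.raises(InvalidArgumentError):
            leaf_gpp(-1.0, **DRIVERS, params=PARAMS)
        with pytest.raises(InvalidArgumentError):
            leaf_gpp(100.0, 25.0, 0.0, 3.0, 0.5, PARAMS)


class TestCanopyGpp:
    FORCING = {"PAR": 400.0, "CO2": 420.0, "U": 3.0}

    def test_no_extinction_limit_is_exact(self):
        p = dataclasses.replace(PARAMS, k_ext=0.0, LAI=3.0, canyon=None)
        got = canopy_gpp(self.FORCING, 25.0, 0.8, p)
        leaf = leaf_gpp(400.0, 25.0, 420.0, 3.0, 0.8, p)
        assert got == pytest.approx(p.f_V * 3.0 * leaf, rel=1e-12)

    def test_zero_lai(self):
        p = dataclasses.replace(PARAMS, LAI=0.0)
        assert canopy_gpp(self.FORCING, 25.0, 0.8, p) == 0.0

    def test_bounded_by_top_of_canopy_rate(self):
        got = canopy_gpp(self.FORCING, 25.0, 0.8, PARAMS)
        top = leaf_gpp(400.0 * PARAMS.sky_view, 25.0, 420.0, 3.0, 0.8, PARAMS)
        assert 0.0 < got <= PARAMS.f_V * PARAMS.LAI * top

    def test_quadrature_matches_brute_force(self):
        """Fixed-order quadrature vs a 10^4-point fine-grid integral across
        randomized parameter/driver draws, to 1e-6 relative."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            p = dataclasses.replace(
                PARAMS,
                LAI=rng.uniform(0.5, 6.0),
                k_ext=rng.uniform(0.0, 1.2),
                A_max=rng.uniform(0.5, 4.0),
                eps=rng.uniform(0.002, 0.02),
                canyon=None,
            )
            par = rng.uniform(20.0, 1000.0)
            theta = rng.uniform(0.05, 1.0)
            T_sk = rng.uniform(5.0, 40.0)
            forcing = {"PAR": par, "CO2": 420.0, "U": 3.0}
            got = canopy_gpp(forcing, T_sk, theta, p)
            depths = np.linspace(0.0, p.LAI, 10_001)
            f = leaf_gpp(par * np.exp(-p.k_ext * depths), T_sk, 420.0, 3.0, theta, p)
            ref = p.f_V * simpson(f, x=depths)
            assert got == pytest.approx(ref, rel=1e-6)

    def test_canyon_sky_view_attenuates(self):
        open_p = dataclasses.replace(PARAMS, canyon=None)
        canyon_p = dataclasses.replace(PARAMS, canyon=CanyonGeometry(20, 10, 10))
        assert canyon_p.sky_view == pytest.approx(0.5)
        assert canopy_gpp(self.FORCING, 25.0, 0.8, canyon_p) < canopy_gpp(
            self.FORCING, 25.0, 0.8, open_p
        )


class TestRespiration:
    def test_reference_point(self):
        p = dataclasses.replace(PARAMS, LAI=PARAMS.LAI_ref)
        got = ecosystem_respiration(p.T_ref, 1.0, p)
        assert got == pytest.approx(p.f_s * p.R_ref, rel=1e-12)

    def test_q10_ratio(self):
        r_warm = ecosystem_respiration(PARAMS.T_ref + 10.0, 0.7, PARAMS)
        r_ref = ecosystem_respiration(PARAMS.T_ref, 0.7, PARAMS)
        assert r_warm / r_ref == pytest.approx(PARAMS.Q10, rel=1e-12)

    def test_dry_soil_limit(self):
        # the saturating moisture response vanishes at the wilting point
        assert ecosystem_respiration(30.0, 0.0, PARAMS) == 0.0

    def test_strictly_increasing_in_temperature_and_moisture(self):
        ts = [ecosystem_respiration(t, 0.6, PARAMS) for t in (10, 20, 30, 40)]
        assert all(b > a for a, b in zip(ts, ts[1:]))
        ms = [ecosystem_respiration(25.0, th, PARAMS)
              for th in (0.1, 0.4, 0.7, 0.95, 1.0)]
        assert all(b > a for a, b in zip(ms, ms[1:]))

    def test_moisture_response_saturates_toward_field_capacity(self):
        low = ecosystem_respiration(25.0, 0.2, PARAMS) - ecosystem_respiration(25.0, 0.1, PARAMS)
        high = ecosystem_respiration(25.0, 1.0, PARAMS) - ecosystem_respiration(25.0, 0.9, PARAMS)
        assert high < low


class TestTilingAndNee:
    def test_weighted_sum(self):
        w = TileWeights(0.2, 0.5, 0.3)
        assert tile_aggregate(w, (10.0, 6.0, 2.0)) == pytest.approx(5.6)

    def test_identical_tiles_collapse(self):
        w = TileWeights(0.2, 0.5, 0.3)  # sums to 1
        assert tile_aggregate(w, (7.0, 7.0, 7.0)) == pytest.approx(7.0)

    def test_zero_weight_ignores_tile(self):
        w = TileWeights(0.5, 0.5, 0.0)
        assert tile_aggregate(w, (1.0, 2.0, 999.0)) == pytest.approx(1.5)

    def test_overweight_rejected(self):
        with pytest.raises(InvalidArgumentError):
            TileWeights(0.5, 0.5, 0.3)

    def test_nee_sign_convention(self):
        assert net_ecosystem_exchange(3.0, 2.0) == 1.0  # net release
        assert net_ecosystem_exchange(2.0, 2.0) == 0.0
        with pytest.raises(InvalidArgumentError):
            net_ecosystem_exchange(-1.0, 0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_daily_aggregation_is_linear(self, seed):
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2015-05-01", periods=48, freq="h")
        df = pd.DataFrame(
            {"GPP_u": rng.uniform(0, 2, 48), "R_u": rng.uniform(0, 2, 48)},
            index=idx,
        )
        df["NEE_u"] = df["R_u"] - df["GPP_u"]
        daily = daily_means(df)
        np.testing.assert_allclose(
            daily["NEE_u"], daily["R_u"] - daily["GPP_u"], atol=1e-12
        )


@pytest.fixture(scope="module")
def setup():
    forcing = synthesize_forcing("arid", dt.date(2015, 5, 1), 10, seed=3)
    soil_p, policy, tiles, weights = default_surface("arid")
    soil = run_soil(forcing, soil_p, policy)
    return forcing, soil, tiles, weights


class TestRunFluxes:
    def test_constant_drivers_give_constant_fluxes(self):
        idx = pd.date_range("2015-05-01", periods=24, freq="h")
        forcing = pd.DataFrame(
            {"T_air": 25.0, "PAR": 400.0, "VPD": 1.0, "U": 3.0,
             "precip": 0.0, "CO2": 420.0},
            index=idx,
        )
        soil = pd.DataFrame({"theta": 0.7, "T_soil": 24.0}, index=idx)
        _, _, tiles, weights = default_surface("arid")
        flux = run_fluxes(forcing, soil, tiles, weights)
        assert flux.nunique().max() == 1

    def test_nee_identity_every_hour(self, setup):
        forcing, soil, tiles, weights = setup
        flux = run_fluxes(forcing, soil, tiles, weights)
        np.testing.assert_array_equal(
            flux["NEE_u"].to_numpy(), (flux["R_u"] - flux["GPP_u"]).to_numpy()
        )

    def test_gpp_linear_in_vegetation_fraction(self, setup):
        forcing, soil, _, weights = setup
        tiles1 = tuple(VegTileParams(f_V=0.2, f_s=0.3, LAI=2.0) for _ in range(3))
        tiles2 = tuple(VegTileParams(f_V=0.4, f_s=0.3, LAI=2.0) for _ in range(3))
        f1 = run_fluxes(forcing, soil, tiles1, weights)
        f2 = run_fluxes(forcing, soil, tiles2, weights)
        np.testing.assert_allclose(f2["GPP_u"], 2.0 * f1["GPP_u"], rtol=1e-12)

    def test_gpp_zero_at_night(self, setup):
        forcing, soil, tiles, weights = setup
        flux = run_fluxes(forcing, soil, tiles, weights)
        night = forcing["PAR"] == 0
        assert (flux.loc[night, "GPP_u"] == 0).all()

    def test_misaligned_axes_rejected(self, setup):
        forcing, soil, tiles, weights = setup
        with pytest.raises(InvalidArgumentError, match="time axes"):
            run_fluxes(forcing.iloc[:-3], soil, tiles, weights)

    def test_matches_independent_reimplementation(self, setup):
        """Daily GPP_u within 1e-9 of a from-scratch loop evaluation of the
        canopy integral (fine-grid Simpson), tiling and NEE closure."""
        forcing, soil, tiles, weights = setup
        flux = run_fluxes(forcing, soil, tiles, weights)

        depth_grid = np.linspace(0.0, 1.0, 4001)
        gpp_ref = np.zeros(len(forcing))
        r_ref = np.zeros(len(forcing))
        for i, (_, row) in enumerate(zip(forcing.index, forcing.itertuples())):
            th = soil["theta"].iloc[i]
            ts = soil["T_soil"].iloc[i]
            for w, p in zip(weights.as_tuple(), tiles):
                depths = depth_grid * p.LAI
                par = row.PAR * p.sky_view * np.exp(-p.k_ext * depths)
                f = leaf_gpp(par, row.T_air + p.t_sk_offset, row.CO2, row.U, th, p)
                gpp_ref[i] += w * p.f_V * simpson(f, x=depths)
                r_ref[i] += w * ecosystem_respiration(ts, th, p)
        daily = daily_means(flux)
        daily_ref = daily_means(
            pd.DataFrame({"GPP_u": gpp_ref, "R_u": r_ref}, index=forcing.index)
        )
        np.testing.assert_allclose(daily["GPP_u"], daily_ref["GPP_u"], rtol=1e-9)
        np.testing.assert_allclose(daily["R_u"], daily_ref["R_u"], rtol=1e-12)
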