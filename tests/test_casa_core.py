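"""CASA model components against scalar oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casacarbon import casa_core
from casacarbon.casa_core import (StressCoefficients, annual_heat_index,
                                  annual_npp, apar, fpar,
                                  light_use_efficiency, optimum_temperature,
                                  simple_ratio, temperature_stress,
                                  thornthwaite_pet, water_stress)
from casacarbon.geodata import CLASS_CODES, GridSpec, LandUseMap

from conftest import make_year


class TestSimpleRatio:
    @pytest.mark.parametrize("ndvi,expected,tol", [
        (0.0, 1.0, 1e-12),
        (0.5, 3.0, 1e-12),
        (0.0765, 1.166, 5e-4),  # reproduces the tabulated SRmin at NDVImin
    ])
    def test_known_values(self, ndvi, expected, tol):
        assert simple_ratio(ndvi) == pytest.approx(expected, abs=tol)

    def test_clamped_near_one(self):
        assert np.isfinite(simple_ratio(1.0))
        assert simple_ratio(1.0) == pytest.approx(2.0 / 1e-6, rel=1e-3)

    @given(st.floats(-0.99, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_monotone(self, ndvi):
        assert simple_ratio(ndvi + 0.005) > simple_ratio(ndvi)


def _scalar_fpar(ndvi, row, fpar_min=0.001, fpar_max=0.950):
    """Independent scalar re-derivation of the two-stretch mean."""
    def stretch(v, lo, hi):
        s = (v - lo) * (fpar_max - fpar_min) / (hi - lo) + fpar_min
        return min(max(s, fpar_min), fpar_max)
    sr = (1 + min(ndvi, 1 - 1e-6)) / (1 - min(ndvi, 1 - 1e-6))
    return 0.5 * (stretch(ndvi, row["ndvi_min"], row["ndvi_max"])
                  + stretch(sr, row["sr_min"], row["sr_max"]))


class TestFpar:
    @pytest.mark.parametrize("cls", sorted(CLASS_CODES))
    def test_class_ndvi_max_hits_fpar_max(self, params, cls):
        row = params.table.loc[cls]
        code = CLASS_CODES[cls]
        # at the class NDVI maximum the SR stretch also saturates after clipping
        if simple_ratio(row["ndvi_max"]) >= row["sr_max"]:
            assert fpar(row["ndvi_max"], code, params) == pytest.approx(0.950, abs=1e-12)
        else:  # tabulated SRmax exceeds SR(NDVImax) for some classes
            assert fpar(row["ndvi_max"], code, params) <= 0.950

    @pytest.mark.parametrize("cls", sorted(CLASS_CODES))
    def test_class_ndvi_min_hits_fpar_min(self, params, cls):
        row = params.table.loc[cls]
        value = fpar(row["ndvi_min"], CLASS_CODES[cls], params)
        # SR(NDVImin) = 1.1657 < tabulated SRmin 1.166, so both stretches clip low
        assert value == pytest.approx(0.001, abs=1e-12)

    def test_grassland_midpoint_hand_oracle(self, params):
        # hand evaluation with the grassland row: FPAR_NDVI = 0.4755,
        # SR(0.3709) = 2.179 -> FPAR_SR = 0.0852, mean = 0.2804
        value = fpar(0.3709, CLASS_CODES["grassland"], params)
        assert value == pytest.approx(0.2804, abs=5e-4)
        assert value == pytest.approx(
            _scalar_fpar(0.3709, params.table.loc["grassland"]), abs=1e-12)

    def test_unknown_class_code(self, params):
        with pytest.raises(KeyError):
            fpar(0.3, 11, params)

    @given(ndvi=st.floats(-1.0, 1.0), code=st.integers(1, 10))
    @settings(max_examples=300, deadline=None)
    def test_bounds_property(self, params, ndvi, code):
        value = float(fpar(ndvi, code, params))
        assert 0.001 <= value <= 0.950
        assert value == pytest.approx(
            _scalar_fpar(ndvi, params.table.iloc[code - 1]), abs=1e-12)


class TestApar:
    @pytest.mark.parametrize("sol,f,expected", [
        (100.0, 0.5, 25.0),
        (0.0, 0.9, 0.0),
        (120.4, 0.2804, 120.4 * 0.2804 * 0.5),
    ])
    def test_direct_product(self, sol, f, expected):
        assert apar(sol, f) == pytest.approx(expected, abs=1e-12)


class TestOptimumTemperature:
    def test_selects_peak_ndvi_month(self, spec8):
        ndvi = [np.full(spec8.shape, 0.1)] * 12
        ndvi[6] = np.full(spec8.shape, 0.9)  # July peak
        temp = [np.full(spec8.shape, float(m)) for m in range(12)]
        temp[6] = np.full(spec8.shape, 28.7)
        assert np.all(optimum_temperature(ndvi, temp) == 28.7)

    def test_constant_ndvi_ties_to_january(self, spec8):
        ndvi = [np.full(spec8.shape, 0.4)] * 12
        temp = [np.full(spec8.shape, float(m + 1)) for m in range(12)]
        assert np.all(optimum_temperature(ndvi, temp) == 1.0)

    def test_matches_argmax_oracle(self, rng):
        spec = GridSpec(5, 5)
        ndvi = [rng.uniform(0, 1, spec.shape) for _ in range(12)]
        temp = [rng.uniform(-5, 35, spec.shape) for _ in range(12)]
        t_opt = optimum_temperature(ndvi, temp)
        for i in range(5):
            for j in range(5):
                series = [ndvi[m][i, j] for m in range(12)]
                best = max(range(12), key=lambda m: (series[m], -m))
                assert t_opt[i, j] == temp[best][i, j]

    def test_all_nodata_pixel(self, spec8):
        ndvi = [np.full(spec8.shape, np.nan)] * 12
        temp = [np.full(spec8.shape, 10.0)] * 12
        assert np.all(np.isnan(optimum_temperature(ndvi, temp)))

    def test_incomplete_year_rejected(self, spec8):
        with pytest.raises(ValueError, match="12-month"):
            optimum_temperature([np.zeros(spec8.shape)] * 11,
                                [np.zeros(spec8.shape)] * 11)


class TestTemperatureStress:
    def test_teps1_closed_form_at_topt_20(self):
        t1, _ = temperature_stress(20.0, 20.0)
        assert t1 == pytest.approx(0.8 + 0.4 - 0.2, abs=1e-12)

    def test_cold_cutoff(self):
        t1, _ = temperature_stress(-15.0, 20.0)
        assert t1 == 0.0

    def test_teps1_floor(self):
        t1, _ = temperature_stress(20.0, 100.0)  # quadratic goes negative
        assert t1 == 0.0

    def test_teps2_scalar_oracle_at_optimum(self):
        _, t2 = temperature_stress(20.0, 20.0)
        expected = 1.1814 / (1 + math.exp(-2.0)) / (1 + math.exp(-3.0))
        assert t2 == pytest.approx(expected, abs=1e-12)
        assert t2 == pytest.approx(0.991, abs=5e-4)

    @given(t=st.floats(-30, 45), topt=st.floats(0, 35))
    @settings(max_examples=200, deadline=None)
    def test_scalar_oracle_everywhere(self, t, topt):
        t1, t2 = temperature_stress(t, topt)
        exp_t1 = 0.0 if t <= -10 else max(0.8 + 0.02 * topt - 0.0005 * topt ** 2, 0.0)
        exp_t2 = 1.1814 / (1 + math.exp(0.2 * (topt - 10 - t))) \
            / (1 + math.exp(0.3 * (-topt - 10 + t)))
        assert t1 == pytest.approx(exp_t1, abs=1e-12)
        assert t2 == pytest.approx(exp_t2, rel=1e-12)


def _scalar_water_stress(p, t, heat):
    """Scalar oracle for the moisture-stress closure."""
    if t <= 0 or heat <= 0:
        pet = 0.0
    else:
        a = 6.75e-7 * heat ** 3 - 7.71e-5 * heat ** 2 + 1.792e-2 * heat + 0.49239
        pet = 16.0 * (10.0 * t / heat) ** a
    if pet <= 0 or p <= 0:
        return 0.5
    rn = math.sqrt(pet * p) * (0.369 + 0.598 * math.sqrt(pet / p))
    denom = (p + rn) * (p ** 2 + rn ** 2)
    if rn <= 0 or denom <= 0 or not math.isfinite(denom):
        return 0.5  # under/overflow for vanishing precipitation: dry floor
    eet = (p * rn * (p ** 2 + rn ** 2 + p * rn)) / denom
    return min(max(0.5 + 0.5 * eet / pet, 0.5), 1.0)


class TestWaterStress:
    def test_dry_floor_zero_precip(self):
        heat = float(annual_heat_index([np.full((1, 1), 15.0)] * 12)[0, 0])
        assert water_stress(0.0, 20.0, heat) == 0.5

    def test_cold_month_pet_zero(self):
        heat = float(annual_heat_index([np.full((1, 1), 15.0)] * 12)[0, 0])
        assert water_stress(100.0, -5.0, heat) == 0.5

    def test_saturates_at_one_for_wet_months(self):
        heat = float(annual_heat_index([np.full((1, 1), 18.0)] * 12)[0, 0])
        assert water_stress(800.0, 20.0, heat) == pytest.approx(1.0, abs=1e-6)

    @given(p=st.floats(0, 600), t=st.floats(-10, 40))
    @settings(max_examples=200, deadline=None)
    def test_scalar_oracle_and_bounds(self, p, t):
        heat = 80.0  # a typical subtropical annual heat index
        w = float(water_stress(p, t, heat))
        assert 0.5 <= w <= 1.0
        assert w == pytest.approx(_scalar_water_stress(p, t, heat), abs=1e-12)

    def test_thornthwaite_zero_below_freezing(self):
        assert thornthwaite_pet(-3.0, 80.0) == 0.0
        assert thornthwaite_pet(20.0, 0.0) == 0.0


class TestLightUseEfficiency:
    def _stress(self, t1, t2, w):
        return StressCoefficients(t_eps1=np.asarray(t1), t_eps2=np.asarray(t2),
                                  w_eps=np.asarray(w), t_opt=np.asarray(20.0))

    def test_unstressed_equals_eps_max(self, params):
        eps = light_use_efficiency(self._stress(1.0, 1.0, 1.0),
                                   params.table.at["arboreal_forest", "eps_max"])
        assert eps == pytest.approx(0.985, abs=1e-12)

    def test_zero_stress_annihilates(self):
        assert light_use_efficiency(self._stress(0.0, 0.9, 0.8), 0.821) == 0.0

    def test_product_oracle(self):
        eps = light_use_efficiency(self._stress(0.9, 0.95, 0.75), 0.821)
        assert eps == pytest.approx(0.9 * 0.95 * 0.75 * 0.821, abs=1e-12)

    def test_nonpositive_eps_max_rejected(self):
        with pytest.raises(ValueError, match="eps_max"):
            light_use_efficiency(self._stress(1, 1, 1), 0.0)


def _scalar_annual_npp(ndvi, precip, temp, rad, code, row, fpar_min=0.001,
                       fpar_max=0.950):
    """Per-pixel scalar re-implementation of the full monthly chain."""
    best = max(range(12), key=lambda m: (ndvi[m], -m))
    t_opt = temp[best]
    heat = sum((max(t, 0.0) / 5.0) ** 1.514 for t in temp)
    total = 0.0
    for m in range(12):
        f = _scalar_fpar(ndvi[m], row, fpar_min, fpar_max)
        a = rad[m] * f * 0.5
        t1 = 0.0 if temp[m] <= -10 else max(0.8 + 0.02 * t_opt - 0.0005 * t_opt ** 2, 0.0)
        t2 = 1.1814 / (1 + math.exp(0.2 * (t_opt - 10 - temp[m]))) \
            / (1 + math.exp(0.3 * (-t_opt - 10 + temp[m])))
        w = _scalar_water_stress(precip[m], temp[m], heat)
        total += max(a * t1 * t2 * w * row["eps_max"], 0.0)
    return total


class TestAnnualNpp:
    def _landuse(self, spec, rng=None, code=None):
        if code is not None:
            classes = np.full(spec.shape, code, dtype=np.uint8)
        else:
            classes = rng.integers(1, 11, spec.shape).astype(np.uint8)
        return LandUseMap(epoch_year=2000, classes=classes, spec=spec)

    def test_zero_radiation_gives_zero_npp(self, spec8, rng, params):
        ndvi, precip, temp, _ = make_year(rng, spec8)
        zero = np.zeros((12,) + spec8.shape)
        out = annual_npp(list(ndvi), list(precip), list(temp), list(zero),
                         self._landuse(spec8, code=3), params)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_linearity_in_radiation(self, spec8, rng, params):
        ndvi, precip, temp, rad = make_year(rng, spec8)
        lu = self._landuse(spec8, rng=rng)
        base = annual_npp(list(ndvi), list(precip), list(temp), list(rad), lu, params)
        double = annual_npp(list(ndvi), list(precip), list(temp), list(2 * rad),
                            lu, params)
        np.testing.assert_allclose(double.values, 2 * base.values, rtol=1e-12)

    def test_single_pixel_matches_scalar_chain(self, rng, params):
        spec = GridSpec(1, 1)
        ndvi, precip, temp, rad = make_year(rng, spec)
        lu = self._landuse(spec, code=CLASS_CODES["dry_land"])
        out = annual_npp(list(ndvi), list(precip), list(temp), list(rad), lu, params)
        expected = _scalar_annual_npp(
            [float(x) for x in ndvi[:, 0, 0]], [float(x) for x in precip[:, 0, 0]],
            [float(x) for x in temp[:, 0, 0]], [float(x) for x in rad[:, 0, 0]],
            2, params.table.loc["dry_land"])
        assert out.values[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_raster_equals_scalar_oracle_8x8(self, spec8, rng, params):
        ndvi, precip, temp, rad = make_year(rng, spec8)
        lu = self._landuse(spec8, rng=rng)
        out = annual_npp(list(ndvi), list(precip), list(temp), list(rad), lu, params)
        from casacarbon.geodata import CLASS_NAMES
        for i in range(8):
            for j in range(8):
                code = int(lu.classes[i, j])
                expected = _scalar_annual_npp(
                    list(map(float, ndvi[:, i, j])), list(map(float, precip[:, i, j])),
                    list(map(float, temp[:, i, j])), list(map(float, rad[:, i, j])),
                    code, params.table.loc[CLASS_NAMES[code]])
                assert out.values[i, j] == pytest.approx(expected, rel=1e-10)

    def test_incomplete_year_rejected(self, spec8, rng, params):
        ndvi, precip, temp, rad = make_year(rng, spec8)
        with pytest.raises(ValueError, match="incomplete year"):
            annual_npp(list(ndvi)[:11], list(precip), list(temp), list(rad),
                       self._landuse(spec8, code=3), params)

    def test_landuse_nodata_propagates(self, spec8, rng, params):
        ndvi, precip, temp, rad = make_year(rng, spec8)
        classes = np.full(spec8.shape, 3, dtype=np.uint8)
        classes[0, 0] = 0
        lu = LandUseMap(epoch_year=2000, classes=classes, spec=spec8)
        out = annual_npp(list(ndvi), list(precip), list(temp), list(rad), lu, params)
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[1:]).all()

    def test_monotone_in_stress_via_moisture(self, spec8, rng, params):
        # wetter month-by-month conditions never lower annual NPP
        ndvi, precip, temp, rad = make_year(rng, spec8)
        lu = self._landuse(spec8, code=3)
        dry = annual_npp(list(ndvi), list(0.3 * precip), list(temp), list(rad), lu, params)
        wet = annual_npp(list(ndvi), list(precip), list(temp), list(rad), lu, params)
        assert np.all(wet.values >= dry.values - 1e-12)

    def test_arboreal_forest_highest_under_identical_inputs(self, rng, params):
        spec = GridSpec(1, 1)
        ndvi, precip, temp, rad = make_year(rng, spec)
        npp = {}
        for name, code in CLASS_CODES.items():
            lu = self._landuse(spec, code=code)
            npp[name] = annual_npp(list(ndvi), list(precip), list(temp),
                                   list(rad), lu, params).values[0, 0]
        assert max(npp, key=npp.get) == "arboreal_forest"
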