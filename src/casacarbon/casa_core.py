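"""The CASA light-use-efficiency model: monthly NPP from NDVI and climate.

Monthly net primary productivity is the product of absorbed
photosynthetically active radiation and a realized light-use efficiency::

    NPP(x, t) = APAR(x, t) * eps(x, t)
    APAR(x, t) = SOL(x, t) * FPAR(x, t) * 0.5
    eps(x, t)  = Teps1(x, t) * Teps2(x, t) * Weps(x, t) * eps_max(class(x))

FPAR is the mean of two linear stretches — one on NDVI, one on the simple
ratio SR = (1+NDVI)/(1−NDVI) — each rescaled between per-class (min, max)
limits onto the global [FPAR_min, FPAR_max] band and clipped to it.

The temperature stresses follow the standard CASA-China forms around the
optimum temperature Topt (mean temperature of the month of peak NDVI in the
pixel's year). The moisture stress is Weps = 0.5 + 0.5*EET/PET, with EET
from the regional evapotranspiration closure driven by precipitation and a
surface net-radiation proxy, and PET from the Thornthwaite monthly
temperature method (per-pixel annual heat index). All stress formulas are
unit-tested against scalar oracles.

Annual NPP (gC·m⁻²·yr⁻¹) is the sum of the 12 monthly grids; negative
monthly values (impossible in this formulation, but reachable through
degenerate stress inputs) are floored at zero. Nodata propagates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geodata import CasaParams, GridSpec, LandUseMap, MonthlyGrid

__all__ = [
    "StressCoefficients",
    "NppGrid",
    "simple_ratio",
    "fpar",
    "apar",
    "optimum_temperature",
    "temperature_stress",
    "annual_heat_index",
    "thornthwaite_pet",
    "water_stress",
    "light_use_efficiency",
    "monthly_npp",
    "annual_npp",
]

#: NDVI is clamped below 1 by this margin before the simple-ratio transform.
NDVI_CLAMP_DELTA = 1.0e-6

#: Monthly mean temperature at or below which photosynthesis is shut off.
T_COLD_CUTOFF = -10.0


@dataclass
class StressCoefficients:
    """Per-pixel multiplicative stress factors for one month.

    ``t_eps1``/``t_eps2`` are the temperature stresses (dimensionless,
    roughly [0, 1.2]); ``w_eps`` is the moisture stress, in [0.5, 1] by
    construction; ``t_opt`` is the pixel's optimum temperature (°C).
    """

    t_eps1: np.ndarray
    t_eps2: np.ndarray
    w_eps: np.ndarray
    t_opt: np.ndarray


@dataclass
class NppGrid:
    """Annual NPP in gC·m⁻², optionally with the 12 monthly components."""

    year: int
    values: np.ndarray
    spec: GridSpec
    monthly: np.ndarray | None = None  # (12, rows, cols) if retained


def simple_ratio(ndvi):
    """Simple ratio SR = (1 + NDVI) / (1 − NDVI), monotone in NDVI.

    NDVI is clamped at ``1 − 1e-6`` first, so the transform never blows up.
    """
    ndvi = np.minimum(np.asarray(ndvi, dtype=np.float64), 1.0 - NDVI_CLAMP_DELTA)
    return (1.0 + ndvi) / (1.0 - ndvi)


def _stretch(values, lo, hi, fpar_min, fpar_max):
    """Linear rescale of [lo, hi] onto [fpar_min, fpar_max], clipped."""
    scaled = (values - lo) * (fpar_max - fpar_min) / (hi - lo) + fpar_min
    return np.clip(scaled, fpar_min, fpar_max)


def fpar(ndvi, lu_class, params: CasaParams):
    """Fraction of absorbed PAR: mean of the NDVI and SR linear stretches.

    Parameters
    ----------
    ndvi
        NDVI value(s), scalar or array.
    lu_class
        Land-use class code(s) (scalar or array, broadcastable with *ndvi*).
    params
        Validated CASA parameter set providing the per-class stretch limits.

    Returns
    -------
    FPAR in ``[params.fpar_min, params.fpar_max]``; NaN where either input
    is nodata.
    """
    ndvi = np.asarray(ndvi, dtype=np.float64)
    codes = np.asarray(lu_class)
    if codes.dtype.kind in "ui" or codes.dtype.kind == "f":
        codes = codes.astype(np.intp)
    else:
        raise TypeError("lu_class must be integer-coded")
    if np.any((codes < 0) | (codes > 10)):
        raise KeyError(f"unknown land-use class code(s): "
                       f"{sorted(np.unique(codes[(codes < 0) | (codes > 10)]).tolist())}")
    ndvi_min = params.lookup("ndvi_min")[codes]
    ndvi_max = params.lookup("ndvi_max")[codes]
    sr_min = params.lookup("sr_min")[codes]
    sr_max = params.lookup("sr_max")[codes]
    f_ndvi = _stretch(ndvi, ndvi_min, ndvi_max, params.fpar_min, params.fpar_max)
    f_sr = _stretch(simple_ratio(ndvi), sr_min, sr_max, params.fpar_min, params.fpar_max)
    return (f_ndvi + f_sr) / 2.0


def apar(sol, fpar_values):
    """Absorbed PAR (MJ·m⁻²): SOL × FPAR × 0.5.

    The factor 0.5 is the photosynthetically active fraction of total solar
    radiation.
    """
    return np.asarray(sol, dtype=np.float64) * np.asarray(fpar_values) * 0.5


def optimum_temperature(ndvi_months: Sequence[np.ndarray],
                        temp_months: Sequence[np.ndarray]) -> np.ndarray:
    """Optimum temperature: mean T of the month attaining the NDVI maximum.

    Ties break to the earliest month. A pixel with NDVI nodata in all 12
    months comes back NaN.
    """
    if len(ndvi_months) != 12 or len(temp_months) != 12:
        raise ValueError("optimum_temperature needs complete 12-month inputs")
    ndvi = np.stack([np.asarray(m, dtype=np.float64) for m in ndvi_months])
    temp = np.stack([np.asarray(m, dtype=np.float64) for m in temp_months])
    filled = np.where(np.isnan(ndvi), -np.inf, ndvi)
    best_month = filled.argmax(axis=0)  # argmax returns first max: earliest month
    t_opt = np.take_along_axis(temp, best_month[None], axis=0)[0]
    t_opt = np.where(np.all(np.isnan(ndvi), axis=0), np.nan, t_opt)
    return t_opt


def temperature_stress(t_month, t_opt):
    """Temperature stress pair (Teps1, Teps2).

    Teps1 = 0.8 + 0.02·Topt − 0.0005·Topt², floored at 0, and set to 0 for
    monthly means at or below −10 °C (photosynthetic shutdown).
    Teps2 penalizes departures of the monthly temperature from Topt with an
    asymmetric double-logistic, peaking near Topt.
    """
    t_month = np.asarray(t_month, dtype=np.float64)
    t_opt = np.asarray(t_opt, dtype=np.float64)
    t1 = 0.8 + 0.02 * t_opt - 0.0005 * t_opt ** 2
    t1 = np.maximum(t1, 0.0)
    t1 = np.where(t_month <= T_COLD_CUTOFF, 0.0, t1)
    t1 = np.where(np.isnan(t_month) | np.isnan(t_opt), np.nan, t1)
    t2 = 1.1814 / (1.0 + np.exp(0.2 * (t_opt - 10.0 - t_month))) \
        / (1.0 + np.exp(0.3 * (-t_opt - 10.0 + t_month)))
    return t1, t2


def annual_heat_index(temp_months: Sequence[np.ndarray]) -> np.ndarray:
    """Thornthwaite annual heat index I = Σ_m (T_m / 5)^1.514 over T_m > 0."""
    if len(temp_months) != 12:
        raise ValueError("heat index needs 12 monthly temperature grids")
    temp = np.stack([np.asarray(m, dtype=np.float64) for m in temp_months])
    warm = np.clip(temp, 0.0, None)
    return np.sum((warm / 5.0) ** 1.514, axis=0)


def thornthwaite_pet(t_month, heat_index):
    """Thornthwaite monthly potential evapotranspiration (mm).

    PET = 16 · (10·T / I)^a with a the cubic function of the annual heat
    index I; zero for T ≤ 0 or I = 0. Day-length/latitude correction is
    omitted (uniform study grid).
    """
    t = np.asarray(t_month, dtype=np.float64)
    i = np.asarray(heat_index, dtype=np.float64)
    a = (6.75e-7 * i ** 3) - (7.71e-5 * i ** 2) + (1.792e-2 * i) + 0.49239
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * np.clip(t, 0.0, None) / np.where(i > 0, i, np.nan)) ** a
    pet = np.where((t <= 0) | (i <= 0), 0.0, pet)
    return np.where(np.isnan(t), np.nan, pet)


def water_stress(precip_month, t_month, heat_index):
    """Moisture stress Weps = 0.5 + 0.5·EET/PET, clipped to [0.5, 1].

    EET is the regional-evapotranspiration closure

        EET = P·Rn·(P² + Rn² + P·Rn) / ((P + Rn)·(P² + Rn²))

    with surface net-radiation proxy
    Rn = √(PET·P) · (0.369 + 0.598·√(PET/P)) (Rn = 0 when P = 0), and PET
    the Thornthwaite monthly estimate. PET = 0 (cold month) gives the dry
    floor 0.5.
    """
    p = np.asarray(precip_month, dtype=np.float64)
    pet = thornthwaite_pet(t_month, heat_index)
    with np.errstate(all="ignore"):
        rn = np.sqrt(pet * p) * (0.369 + 0.598 * np.sqrt(pet / np.where(p > 0, p, np.nan)))
        rn = np.where(p > 0, rn, 0.0)
        denom = (p + rn) * (p ** 2 + rn ** 2)
        eet = (p * rn * (p ** 2 + rn ** 2 + p * rn)) \
            / np.where(denom > 0, denom, np.nan)
        # denom under/overflows for vanishing precipitation: treat as dry
        eet = np.where((p > 0) & (rn > 0) & (denom > 0), eet, 0.0)
        ratio = np.where(pet > 0, eet / np.where(pet > 0, pet, np.nan), 0.0)
    w = np.clip(0.5 + 0.5 * ratio, 0.5, 1.0)
    w = np.where(np.isfinite(w), w, 0.5)
    return np.where(np.isnan(p) | np.isnan(np.asarray(t_month, dtype=np.float64)), np.nan, w)


def light_use_efficiency(stress: StressCoefficients, eps_max):
    """Realized light-use efficiency (gC/MJ): product of stresses × eps_max."""
    eps_max = np.asarray(eps_max, dtype=np.float64)
    if np.nanmin(eps_max, initial=np.inf) <= 0:
        raise ValueError("eps_max must be positive")
    return stress.t_eps1 * stress.t_eps2 * stress.w_eps * eps_max


def monthly_npp(ndvi, sol, t_month, precip, t_opt, heat_index,
                lu_classes, params: CasaParams):
    """Monthly NPP grid (gC·m⁻²) for one month of one year."""
    f = fpar(ndvi, lu_classes, params)
    a = apar(sol, f)
    t1, t2 = temperature_stress(t_month, t_opt)
    w = water_stress(precip, t_month, heat_index)
    eps_max = params.lookup("eps_max")[np.asarray(lu_classes, dtype=np.intp)]
    eps = light_use_efficiency(
        StressCoefficients(t_eps1=t1, t_eps2=t2, w_eps=w, t_opt=np.asarray(t_opt)),
        eps_max)
    return np.maximum(a * eps, 0.0)


def annual_npp(ndvi_months: Sequence[np.ndarray],
               precip_months: Sequence[np.ndarray],
               temp_months: Sequence[np.ndarray],
               rad_months: Sequence[np.ndarray],
               land_use: LandUseMap,
               params: CasaParams,
               year: int = 0,
               keep_monthly: bool = False) -> NppGrid:
    """Run the full model for one year.

    Parameters
    ----------
    ndvi_months, precip_months, temp_months, rad_months
        Twelve grids each (January..December) on the land-use map's grid.
    land_use
        Class map driving parameter lookup. Nodata land-use pixels yield
        NaN NPP.
    params
        CASA parameter set.
    keep_monthly
        Retain the 12 monthly NPP grids on the result.

    Returns
    -------
    NppGrid with annual values = Σ of the monthly grids.
    """
    for name, months in (("ndvi", ndvi_months), ("precipitation", precip_months),
                         ("temperature", temp_months), ("radiation", rad_months)):
        if len(months) != 12:
            raise ValueError(f"incomplete year: {name} has {len(months)} months")
    spec = land_use.spec
    ndvi_months = [_values(m, spec) for m in ndvi_months]
    precip_months = [_values(m, spec) for m in precip_months]
    temp_months = [_values(m, spec) for m in temp_months]
    rad_months = [_values(m, spec) for m in rad_months]

    t_opt = optimum_temperature(ndvi_months, temp_months)
    heat = annual_heat_index(temp_months)
    lu_nodata = land_use.mask

    monthly = np.empty((12, spec.n_rows, spec.n_cols))
    for m in range(12):
        npp = monthly_npp(ndvi_months[m], rad_months[m], temp_months[m],
                          precip_months[m], t_opt, heat,
                          land_use.classes, params)
        npp = np.where(lu_nodata, np.nan, npp)
        monthly[m] = npp
    annual = monthly.sum(axis=0)  # plain sum: any nodata month propagates
    return NppGrid(year=year, values=annual, spec=spec,
                   monthly=monthly if keep_monthly else None)


def _values(month, spec: GridSpec) -> np.ndarray:
    """Accept MonthlyGrid or bare array; enforce the session GridSpec."""
    if isinstance(month, MonthlyGrid):
        spec.require_same(month.spec)
        return month.values
    arr = np.asarray(month, dtype=np.float64)
    spec.validate_array(arr)
    return arr
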