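"""Six-scenario counterfactual engine for carbon-sequestration change.

Total carbon sequestration is CS = NPP × Area, reported in units of
10¹⁰ gC. The change between the two study epochs decomposes as

    ΔAll     = ΔClimate + ΔLUCC                  (by construction)
    ΔLUCC    = ΔAfforestation + ΔUrbanization + ΔOthers

via eight model runs: the two factual years plus six counterfactuals —

    A    climate held at 2000; NDVI and land use from 2015
    B/C/D  exactly one of precipitation / temperature / radiation held at
           2000, everything else (incl. NDVI, land use) from 2015
    E/F  as A, but NDVI (and, by default, land-use class) restored to 2000
         on the afforestation (E) / urbanization (F) pixels

and the subtractions ΔLUCC = CS_A − CS_2000, ΔClimate = CS_2015 − CS_A,
ΔPrecip/Temp/Rad = CS_2015 − CS_{B/C/D}, ΔAfforestation = CS_A − CS_E,
ΔUrbanization = CS_A − CS_F, ΔOthers = ΔLUCC − ΔAfforestation −
ΔUrbanization.

The single-variable climate effects are not forced to sum to ΔClimate: on
interacting inputs their gap is reported as ``interaction_residual``, never
silently absorbed. Climate–land-use interaction is carried by ΔClimate
(ΔLUCC is measured at 2000 climate, ΔClimate is the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .casa_core import NppGrid, annual_npp
from .geodata import CasaParams, GridSpec, LandUseMap
from .landuse import ChangeMasks

__all__ = [
    "SCENARIO_IDS",
    "EpochBundle",
    "ScenarioInput",
    "EffectLedger",
    "carbon_sequestration",
    "build_scenario",
    "run_scenario",
    "decompose",
    "ledger_report",
]

SCENARIO_IDS = ("factual2000", "factual2015", "A", "B", "C", "D", "E", "F")

_TO_1E10_GC = 1.0e10


@dataclass
class EpochBundle:
    """All model inputs for one epoch: 12 months × 3 climate vars + NDVI + land use.

    Climate and NDVI arrays have shape (12, rows, cols), January first.
    """

    year: int
    precip: np.ndarray
    temp: np.ndarray
    rad: np.ndarray
    ndvi: np.ndarray
    landuse: LandUseMap

    def __post_init__(self) -> None:
        spec = self.landuse.spec
        for name in ("precip", "temp", "rad", "ndvi"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (12,) + spec.shape:
                raise ValueError(
                    f"{name} must have shape (12, {spec.n_rows}, {spec.n_cols}), "
                    f"got {arr.shape}")
            setattr(self, name, arr)

    @property
    def spec(self) -> GridSpec:
        return self.landuse.spec


@dataclass
class ScenarioInput:
    """A fully resolved input bundle for one scenario run."""

    scenario_id: str
    bundle: EpochBundle


def carbon_sequestration(npp, spec: GridSpec,
                         region_mask: np.ndarray | None = None,
                         method: str = "pixel_sum",
                         area_m2: float | None = None) -> float:
    """Total carbon sequestration over a region, in 10¹⁰ gC.

    Parameters
    ----------
    npp
        Annual NPP grid (gC·m⁻²) or :class:`NppGrid`.
    region_mask
        Boolean grid selecting the region; None = whole grid.
    method
        ``"pixel_sum"`` — Σ NPP × pixel_area over valid region pixels;
        ``"mean_area"`` — regional mean NPP × total region area (the
        arithmetic behind published regional totals). Both agree exactly
        on gap-free regions.
    area_m2
        Override for the region area in m² (``mean_area`` only); defaults
        to valid-pixel count × pixel_area.
    """
    values = npp.values if isinstance(npp, NppGrid) else np.asarray(npp, dtype=np.float64)
    spec.validate_array(values)
    if region_mask is None:
        region_mask = np.ones(spec.shape, dtype=bool)
    else:
        region_mask = np.asarray(region_mask, dtype=bool)
        spec.validate_array(region_mask)
    if not region_mask.any():
        raise ValueError("empty region mask")
    sel = region_mask & ~np.isnan(values)
    if not sel.any():
        raise ValueError("region contains no valid (non-nodata) pixels")
    if method == "pixel_sum":
        total = float(values[sel].sum()) * spec.pixel_area
    elif method == "mean_area":
        area = float(area_m2) if area_m2 is not None else sel.sum() * spec.pixel_area
        total = float(values[sel].mean()) * area
    else:
        raise ValueError(f"unknown method {method!r}")
    return total / _TO_1E10_GC


def _masked_restore(bundle_2015: EpochBundle, bundle_2000: EpochBundle,
                    mask: np.ndarray, restore: str) -> EpochBundle:
    """Restore NDVI (and optionally land-use class) to 2000 inside *mask*."""
    ndvi = np.where(mask[None], bundle_2000.ndvi, bundle_2015.ndvi)
    if restore == "ndvi_and_class":
        classes = np.where(mask, bundle_2000.landuse.classes,
                           bundle_2015.landuse.classes)
        lu = LandUseMap(epoch_year=bundle_2015.landuse.epoch_year,
                        classes=classes, spec=bundle_2015.spec)
    elif restore == "ndvi_only":
        lu = bundle_2015.landuse
    else:
        raise ValueError(f"unknown restore mode {restore!r}")
    return replace(bundle_2015, ndvi=ndvi, landuse=lu)


def build_scenario(scenario_id: str, data_2000: EpochBundle,
                   data_2015: EpochBundle, masks: ChangeMasks | None = None,
                   restore: str = "ndvi_and_class") -> ScenarioInput:
    """Resolve one scenario's input bundle from the two factual epochs.

    ``restore`` controls whether scenarios E/F roll back only the NDVI
    (``"ndvi_only"``) or, consistently, the land-use class and hence the
    CASA parameters too (``"ndvi_and_class"``, default).
    """
    data_2000.spec.require_same(data_2015.spec)
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(f"undefined scenario id {scenario_id!r}")
    if scenario_id == "factual2000":
        return ScenarioInput(scenario_id, data_2000)
    if scenario_id == "factual2015":
        return ScenarioInput(scenario_id, data_2015)
    if scenario_id == "A":
        bundle = replace(data_2015, precip=data_2000.precip,
                         temp=data_2000.temp, rad=data_2000.rad)
    elif scenario_id == "B":
        bundle = replace(data_2015, precip=data_2000.precip)
    elif scenario_id == "C":
        bundle = replace(data_2015, temp=data_2000.temp)
    elif scenario_id == "D":
        bundle = replace(data_2015, rad=data_2000.rad)
    else:  # E / F: scenario A plus a masked rollback
        if masks is None:
            raise ValueError(f"scenario {scenario_id} requires change masks")
        masks.spec.require_same(data_2015.spec)
        mask = masks.afforestation if scenario_id == "E" else masks.urbanization
        bundle = replace(data_2015, precip=data_2000.precip,
                         temp=data_2000.temp, rad=data_2000.rad)
        bundle = _masked_restore(bundle, data_2000, mask, restore)
    return ScenarioInput(scenario_id, bundle)


def run_scenario(scenario: ScenarioInput, params: CasaParams) -> NppGrid:
    """Run the CASA model on a resolved scenario input."""
    b = scenario.bundle
    return annual_npp(list(b.ndvi), list(b.precip), list(b.temp), list(b.rad),
                      b.landuse, params, year=b.year)


@dataclass
class EffectLedger:
    """Per-region CS totals and the nine Δ terms, all in 10¹⁰ gC.

    The identities ΔAll = ΔClimate + ΔLUCC and
    ΔOthers = ΔLUCC − ΔAfforestation − ΔUrbanization hold exactly by
    construction; ``interaction_residual`` = ΔClimate − (ΔPrecip + ΔTemp +
    ΔRad) measures how non-additive the single-variable climate effects
    are.
    """

    region: str
    cs_2000: float
    cs_2015: float
    cs_a: float
    cs_b: float
    cs_c: float
    cs_d: float
    cs_e: float
    cs_f: float

    @property
    def d_all(self) -> float:
        return self.cs_2015 - self.cs_2000

    @property
    def d_lucc(self) -> float:
        return self.cs_a - self.cs_2000

    @property
    def d_climate(self) -> float:
        return self.cs_2015 - self.cs_a

    @property
    def d_precip(self) -> float:
        return self.cs_2015 - self.cs_b

    @property
    def d_temp(self) -> float:
        return self.cs_2015 - self.cs_c

    @property
    def d_rad(self) -> float:
        return self.cs_2015 - self.cs_d

    @property
    def d_afforest(self) -> float:
        return self.cs_a - self.cs_e

    @property
    def d_urban(self) -> float:
        return self.cs_a - self.cs_f

    @property
    def d_others(self) -> float:
        return self.d_lucc - self.d_afforest - self.d_urban

    @property
    def interaction_residual(self) -> float:
        return self.d_climate - (self.d_precip + self.d_temp + self.d_rad)


def decompose(data_2000: EpochBundle, data_2015: EpochBundle,
              masks: ChangeMasks, params: CasaParams,
              region_masks: Mapping[str, np.ndarray] | None = None,
              restore: str = "ndvi_and_class",
              cs_method: str = "pixel_sum") -> dict[str, EffectLedger]:
    """Run all eight scenarios and assemble one effect ledger per region.

    ``region_masks`` maps region names to boolean grids; None means a
    single ledger for the whole grid under the name ``"all"``. A failure in
    any scenario run aborts with the scenario id in the error message.
    """
    spec = data_2000.spec
    if region_masks is None:
        region_masks = {"all": np.ones(spec.shape, dtype=bool)}
    npp: dict[str, NppGrid] = {}
    for sid in SCENARIO_IDS:
        try:
            scenario = build_scenario(sid, data_2000, data_2015, masks, restore)
            npp[sid] = run_scenario(scenario, params)
        except Exception as exc:
            raise RuntimeError(f"scenario {sid!r} failed: {exc}") from exc
    ledgers: dict[str, EffectLedger] = {}
    for name, mask in region_masks.items():
        cs = {sid: carbon_sequestration(npp[sid], spec, mask, method=cs_method)
              for sid in SCENARIO_IDS}
        ledgers[name] = EffectLedger(
            region=name, cs_2000=cs["factual2000"], cs_2015=cs["factual2015"],
            cs_a=cs["A"], cs_b=cs["B"], cs_c=cs["C"], cs_d=cs["D"],
            cs_e=cs["E"], cs_f=cs["F"])
    return ledgers


_REPORT_COLUMNS = [
    "cs_2000", "cs_2015", "d_all", "d_climate", "d_precip", "d_temp", "d_rad",
    "d_lucc", "d_afforest", "d_urban", "d_others", "interaction_residual",
]


def ledger_report(ledgers: Mapping[str, EffectLedger]) -> pd.DataFrame:
    """Tabulate ledgers: one row per region, all quantities in 10¹⁰ gC."""
    rows = {name: {col: getattr(led, col) for col in _REPORT_COLUMNS}
            for name, led in ledgers.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df[_REPORT_COLUMNS]
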