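"""Grid contracts, domain types and raster/parameter-table I/O.

All raster math in this package happens on plain numpy arrays carried by a
small set of typed containers. A single :class:`GridSpec` describes the
common grid of one analysis session; every stacked grid must share it, and
mixing specs is a hard error everywhere downstream.

Continuous grids use ``NaN`` as the in-memory nodata representation; the
integer-coded land-use grid uses 0. The nodata sentinel of the spec only
appears at the file boundary.

Rasters are stored as single-band TIFF files with the grid spec serialized
as JSON into the ImageDescription tag (transform, pixel area, nodata). The
affine transform is a six-tuple ``(a, b, c, d, e, f)`` mapping column/row to
projected x/y, GDAL-style: ``x = a*col + b*row + c``, ``y = d*col + e*row + f``.
An equal-area projection is assumed so that ``pixel_area`` (m² per pixel) is
uniform; geographic (degree) rasters are out of contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "CLASS_I_GROUPS",
    "FOREST_CODES",
    "BUILT_UP_CODE",
    "GridSpec",
    "GridSpecMismatch",
    "MonthlyGrid",
    "LandUseMap",
    "CasaParams",
    "load_casa_params",
    "read_grid",
    "write_grid",
    "read_landuse",
    "write_landuse",
    "monthly_mvc",
]

# ---------------------------------------------------------------------------
# land-use classification (10 level-II classes, 6 level-I groups)
# ---------------------------------------------------------------------------

CLASS_CODES: dict[str, int] = {
    "paddy_field": 1,
    "dry_land": 2,
    "arboreal_forest": 3,
    "shrub": 4,
    "open_forestland_1": 5,
    "open_forestland_2": 6,
    "grassland": 7,
    "water": 8,
    "built_up": 9,
    "bare_land": 10,
}

CLASS_NAMES: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}

#: fixed level-II -> level-I aggregation (crop = paddy + dry; forest = the
#: four forest subclasses; the rest map one-to-one)
CLASS_I_GROUPS: dict[str, tuple[int, ...]] = {
    "crop": (1, 2),
    "forest": (3, 4, 5, 6),
    "grassland": (7,),
    "water": (8,),
    "built_up": (9,),
    "bare": (10,),
}

FOREST_CODES: frozenset[int] = frozenset(CLASS_I_GROUPS["forest"])
BUILT_UP_CODE: int = CLASS_CODES["built_up"]

_LANDUSE_NODATA = 0

VARIABLES = ("precipitation", "temperature", "radiation", "ndvi")


class GridSpecMismatch(ValueError):
    """Raised when two grids that must share a GridSpec do not."""


@dataclass(frozen=True)
class GridSpec:
    """Shape, georeference and nodata contract of the common analysis grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; pixel (0, 0) is the top-left corner, rows run north to
        south (row-major storage).
    pixel_area
        Area of one pixel in m². Uniform across the grid (equal-area
        projection assumed); used for every area-weighted sum.
    transform
        GDAL-style affine six-tuple mapping (col, row) to projected (x, y).
    nodata
        Sentinel written to files for missing pixels.
    """

    n_rows: int
    n_cols: int
    pixel_area: float = 1.0e6
    transform: tuple[float, float, float, float, float, float] = (
        1000.0, 0.0, 0.0, 0.0, -1000.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.pixel_area > 0:
            raise ValueError(f"pixel_area must be positive, got {self.pixel_area}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def require_same(self, other: "GridSpec") -> None:
        """Raise :class:`GridSpecMismatch` unless *other* equals self."""
        if other != self:
            raise GridSpecMismatch(f"grid specs differ: {self} vs {other}")

    def validate_array(self, values: np.ndarray) -> None:
        if values.shape != self.shape:
            raise GridSpecMismatch(
                f"array shape {values.shape} does not match grid {self.shape}")

    def to_json(self) -> str:
        return json.dumps({
            "n_rows": self.n_rows, "n_cols": self.n_cols,
            "pixel_area": self.pixel_area,
            "transform": list(self.transform), "nodata": self.nodata,
        })

    @classmethod
    def from_json(cls, text: str) -> "GridSpec":
        d = json.loads(text)
        return cls(int(d["n_rows"]), int(d["n_cols"]), float(d["pixel_area"]),
                   tuple(float(t) for t in d["transform"]), float(d["nodata"]))


@dataclass
class MonthlyGrid:
    """One variable on the common grid for one (year, month).

    ``values`` is float64 with NaN marking nodata. NDVI is cleaned on
    construction: values outside [-1, 1] become NaN (sensor fill would
    otherwise poison maximum-value composites). Negative precipitation or
    radiation is rejected outright.
    """

    variable: str
    year: int
    month: int
    values: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}; expected one of {VARIABLES}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1..12, got {self.month}")
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spec.validate_array(self.values)
        if self.variable == "ndvi":
            bad = (self.values < -1.0) | (self.values > 1.0)
            if bad.any():
                self.values = np.where(bad, np.nan, self.values)
        elif self.variable in ("precipitation", "radiation"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValueError(f"{self.variable} must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where the pixel is nodata."""
        return np.isnan(self.values)


@dataclass
class LandUseMap:
    """Categorical grid over the 10 level-II land-use classes for one epoch."""

    epoch_year: int
    classes: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        self.spec.validate_array(self.classes)
        valid = set(CLASS_NAMES) | {_LANDUSE_NODATA}
        present = set(np.unique(self.classes).tolist())
        if not present <= valid:
            raise ValueError(f"invalid land-use codes present: {sorted(present - valid)}")

    @property
    def mask(self) -> np.ndarray:
        return self.classes == _LANDUSE_NODATA

    def class_i(self) -> np.ndarray:
        """Aggregate to level-I groups, returned as a small-int grid.

        Codes: 0 nodata, 1 crop, 2 forest, 3 grassland, 4 water,
        5 built_up, 6 bare.
        """
        lut = np.zeros(11, dtype=np.uint8)
        for i, (_, codes) in enumerate(CLASS_I_GROUPS.items(), start=1):
            for c in codes:
                lut[c] = i
        return lut[self.classes]


# ---------------------------------------------------------------------------
# CASA parameter table
# ---------------------------------------------------------------------------

_PARAM_COLUMNS = ("ndvi_min", "ndvi_max", "sr_min", "sr_max", "eps_max")

# Published calibration for the Wuhan City Circle: per-class NDVI and simple-
# ratio stretch limits and maximum light-use efficiency (gC per MJ APAR).
# SR limits are stored verbatim as independent parameters; they are NOT
# derivable from the NDVI limits through the simple-ratio formula for every
# class, so no such derivation is attempted.
_DEFAULT_PARAMS: dict[str, tuple[float, float, float, float, float]] = {
    # class: (ndvi_min, ndvi_max, sr_min, sr_max, eps_max)
    "paddy_field":       (0.0765, 0.7994, 1.166, 14.393, 0.729),
    "dry_land":          (0.0765, 0.8824, 1.166, 17.002, 0.821),
    "arboreal_forest":   (0.0765, 0.8979, 1.166, 18.793, 0.985),
    "shrub":             (0.0765, 0.8983, 1.166, 18.666, 0.756),
    "open_forestland_1": (0.0765, 0.8889, 1.166, 18.589, 0.779),
    "open_forestland_2": (0.0765, 0.7994, 1.166, 14.393, 0.679),
    "grassland":         (0.0765, 0.6653, 1.166, 12.576, 0.429),
    "water":             (0.0765, 0.5044, 1.166, 8.970, 0.429),
    "built_up":          (0.0765, 0.5044, 1.166, 8.970, 0.429),
    "bare_land":         (0.0765, 0.5044, 1.166, 8.970, 0.429),
}

FPAR_MIN = 0.001
FPAR_MAX = 0.950


@dataclass
class CasaParams:
    """Per-land-use CASA parameters plus the global FPAR bounds.

    ``table`` is indexed by class name with columns
    ``ndvi_min, ndvi_max, sr_min, sr_max, eps_max``.
    """

    table: pd.DataFrame
    fpar_min: float = FPAR_MIN
    fpar_max: float = FPAR_MAX

    def __post_init__(self) -> None:
        missing = set(CLASS_CODES) - set(self.table.index)
        if missing:
            raise ValueError(f"parameter table missing classes: {sorted(missing)}")
        extra = set(self.table.index) - set(CLASS_CODES)
        if extra:
            raise ValueError(f"parameter table has unknown classes: {sorted(extra)}")
        missing_cols = set(_PARAM_COLUMNS) - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"parameter table missing columns: {sorted(missing_cols)}")
        t = self.table
        if not (t["ndvi_min"] < t["ndvi_max"]).all():
            raise ValueError("ndvi_min must be < ndvi_max for every class")
        if not (t["sr_min"] < t["sr_max"]).all():
            raise ValueError("sr_min must be < sr_max for every class")
        if not (t["eps_max"] > 0).all():
            raise ValueError("eps_max must be positive for every class")
        if not 0 <= self.fpar_min < self.fpar_max:
            raise ValueError("need 0 <= fpar_min < fpar_max")

    def lookup(self, column: str) -> np.ndarray:
        """Per-class lookup vector indexable by class code (index 0 = NaN)."""
        out = np.full(11, np.nan)
        for name, code in CLASS_CODES.items():
            out[code] = self.table.at[name, column]
        return out

    def for_class(self, lu_class: int | str) -> pd.Series:
        name = lu_class if isinstance(lu_class, str) else CLASS_NAMES.get(int(lu_class))
        if name not in self.table.index:
            raise KeyError(f"unknown land-use class {lu_class!r}")
        return self.table.loc[name]


def load_casa_params(path: str | Path | None = None) -> CasaParams:
    """Load the CASA parameter table from CSV, or the built-in calibration.

    The CSV must carry the header
    ``class,ndvi_min,ndvi_max,sr_min,sr_max,eps_max`` with one row per
    land-use class.
    """
    if path is None:
        table = pd.DataFrame.from_dict(
            _DEFAULT_PARAMS, orient="index", columns=list(_PARAM_COLUMNS))
        table.index.name = "class"
        return CasaParams(table)
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise ValueError("parameter CSV must have a 'class' column")
    df = df.set_index("class")
    return CasaParams(df[list(_PARAM_COLUMNS)].astype(float))


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def write_grid(path: str | Path, grid: MonthlyGrid) -> None:
    """Write a continuous grid as single-band float32 TIFF.

    The grid spec travels in the ImageDescription tag; NaN is replaced by
    the spec's nodata sentinel on disk.
    """
    values = grid.values.astype(np.float32)
    values = np.where(np.isnan(values), np.float32(grid.spec.nodata), values)
    meta = {"spec": json.loads(grid.spec.to_json()), "variable": grid.variable,
            "year": grid.year, "month": grid.month}
    tifffile.imwrite(str(path), values, description=json.dumps(meta))


def _read_tiff(path: str | Path) -> tuple[np.ndarray, dict]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"raster not found: {p}")
    with tifffile.TiffFile(str(p)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        desc = page.description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return values, meta


def read_grid(path: str | Path, variable: str | None = None,
              spec: GridSpec | None = None) -> MonthlyGrid:
    """Read a continuous grid written by :func:`write_grid`.

    If *spec* is given, the file's grid spec must match it exactly
    (:class:`GridSpecMismatch` otherwise). Nodata pixels come back as NaN.
    """
    values, meta = _read_tiff(path)
    file_spec = GridSpec.from_json(json.dumps(meta["spec"])) if "spec" in meta else None
    if file_spec is None:
        if spec is None:
            raise ValueError(f"{path}: no embedded grid spec and none supplied")
        file_spec = spec
    if spec is not None:
        spec.require_same(file_spec)
    values = np.asarray(values, dtype=np.float64)
    values = np.where(values == file_spec.nodata, np.nan, values)
    return MonthlyGrid(
        variable=variable or meta.get("variable", "ndvi"),
        year=int(meta.get("year", 0)), month=int(meta.get("month", 1)),
        values=values, spec=file_spec)


def write_array(path: str | Path, values: np.ndarray, spec: GridSpec,
                name: str = "derived") -> None:
    """Write a derived continuous grid (NPP, slope, p-value, ...) as TIFF."""
    spec.validate_array(np.asarray(values))
    out = np.asarray(values, dtype=np.float32)
    out = np.where(np.isnan(out), np.float32(spec.nodata), out)
    meta = {"spec": json.loads(spec.to_json()), "name": name}
    tifffile.imwrite(str(path), out, description=json.dumps(meta))


def read_array(path: str | Path, spec: GridSpec | None = None
               ) -> tuple[np.ndarray, GridSpec]:
    """Read a derived grid written by :func:`write_array` (NaN for nodata)."""
    values, meta = _read_tiff(path)
    file_spec = GridSpec.from_json(json.dumps(meta["spec"])) if "spec" in meta else spec
    if file_spec is None:
        raise ValueError(f"{path}: no embedded grid spec and none supplied")
    if spec is not None:
        spec.require_same(file_spec)
    values = np.asarray(values, dtype=np.float64)
    return np.where(values == file_spec.nodata, np.nan, values), file_spec


def write_landuse(path: str | Path, lu: LandUseMap) -> None:
    meta = {"spec": json.loads(lu.spec.to_json()), "epoch_year": lu.epoch_year}
    tifffile.imwrite(str(path), lu.classes.astype(np.uint8),
                     description=json.dumps(meta))


def read_landuse(path: str | Path, spec: GridSpec | None = None) -> LandUseMap:
    values, meta = _read_tiff(path)
    file_spec = GridSpec.from_json(json.dumps(meta["spec"])) if "spec" in meta else spec
    if file_spec is None:
        raise ValueError(f"{path}: no embedded grid spec and none supplied")
    if spec is not None:
        spec.require_same(file_spec)
    return LandUseMap(epoch_year=int(meta.get("epoch_year", 0)),
                      classes=values, spec=file_spec)


# ---------------------------------------------------------------------------
# maximum-value compositing
# ---------------------------------------------------------------------------

def monthly_mvc(composites: Sequence[MonthlyGrid]) -> MonthlyGrid:
    """Per-pixel maximum over sub-monthly NDVI composites (cloud screening).

    A pixel is nodata in the result only if it is nodata in every composite.
    All composites must share one GridSpec and (year, month).
    """
    comps = list(composites)
    if not comps:
        raise ValueError("monthly_mvc needs at least one composite")
    first = comps[0]
    for g in comps[1:]:
        first.spec.require_same(g.spec)
    stack = np.stack([g.values for g in comps])
    filled = np.where(np.isnan(stack), -np.inf, stack)
    values = filled.max(axis=0)
    values[np.all(np.isnan(stack), axis=0)] = np.nan
    return MonthlyGrid(variable=first.variable, year=first.year,
                       month=first.month, values=values, spec=first.spec)
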