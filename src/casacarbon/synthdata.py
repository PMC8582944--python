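"""Seeded generator of co-registered synthetic model inputs.

The study's real drivers (downscaled satellite NDVI, interpolated monthly
climate surfaces, Landsat-derived land-use maps) are not redistributable,
so this module fabricates a desk-scale scene with the same statistical
structure: spatially smooth climate fields with a mid-subtropical monsoon
seasonal cycle and configurable interannual trends; per-class NDVI
seasonal cycles bounded by the CASA calibration ranges; and a land-use
pair whose second epoch differs by contiguous afforestation, urbanization
and crop→water patches.

Everything is deterministic under a fixed (config, seed): noise fields are
drawn from ``numpy.random.default_rng(config.seed)`` streams and patch
geometry from the separate ``layout_seed``, so changing the noise seed
never moves the patches.

Defaults describe the emulated region: a 64×64 grid of 1 km² pixels,
January mean ~3.7 °C and July ~28.7 °C, ~1269 mm annual precipitation,
~4713 MJ·m⁻² annual radiation, and the weak observed interannual trends
(+0.005 °C·yr⁻¹, +10 mm·yr⁻¹, +1.72 MJ·m⁻²·yr⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .geodata import CLASS_CODES, GridSpec, LandUseMap, load_casa_params
from .landuse import ChangeMasks, change_masks
from .scenarios import EpochBundle

__all__ = [
    "SynthConfig",
    "Scene",
    "generate_landuse_pair",
    "generate_climate",
    "generate_ndvi",
    "generate_scene",
    "make_single_factor_pair",
    "quadrant_regions",
]

SINGLE_FACTORS = ("precipitation", "temperature", "radiation",
                  "afforestation", "urbanization")

#: per-class NDVI annual mean and seasonal peak-to-trough amplitude
_NDVI_PROFILE: dict[str, tuple[float, float]] = {
    "paddy_field": (0.45, 0.25),
    "dry_land": (0.42, 0.22),
    "arboreal_forest": (0.62, 0.20),
    "shrub": (0.55, 0.20),
    "open_forestland_1": (0.50, 0.20),
    "open_forestland_2": (0.45, 0.20),
    "grassland": (0.40, 0.20),
    "water": (0.12, 0.02),
    "built_up": (0.22, 0.05),
    "bare_land": (0.15, 0.03),
}

_BASE_CLASSES = ("paddy_field", "dry_land", "arboreal_forest",
                 "grassland", "water", "built_up")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic scene; defaults are the emulated study conditions."""

    n_rows: int = 64
    n_cols: int = 64
    pixel_area: float = 1.0e6  # m² (1 km² pixels)
    year_start: int = 2000
    year_end: int = 2015
    seed: int = 0          # noise streams
    layout_seed: int = 7   # base map + patch geometry

    # climate seasonal baselines and interannual trends
    temp_mean: float = 16.2            # °C annual mean
    temp_seasonal_amp: float = 12.5    # °C half-range (Jan 3.7, Jul 28.7)
    temp_trend: float = 0.005          # °C per year
    temp_noise: float = 0.5            # °C monthly noise s.d.
    precip_annual: float = 1269.0      # mm per year
    precip_seasonal_amp: float = 0.8   # relative summer concentration
    precip_trend: float = 10.0         # mm per year (annual total)
    precip_noise: float = 0.15         # relative monthly noise s.d.
    rad_annual: float = 4713.0         # MJ·m⁻² per year
    rad_seasonal_amp: float = 0.55     # relative seasonal swing
    rad_trend: float = 1.72            # MJ·m⁻² per year (annual total)
    rad_noise: float = 0.04            # relative monthly noise s.d.

    # spatial structure (separable low-pass of white noise)
    spatial_sigma: float = 4.0         # pixels
    temp_spatial_amp: float = 1.0      # °C
    precip_spatial_amp: float = 0.10   # relative
    rad_spatial_amp: float = 0.04      # relative

    # NDVI
    ndvi_trend: float = 0.002          # per year, vegetated classes
    ndvi_noise: float = 0.02           # monthly noise s.d.
    ndvi_seasonal_scale: float = 1.0   # multiplies per-class seasonal amplitude

    # land-use change patches (side length in pixels)
    n_afforest_patches: int = 2
    afforest_patch_size: int = 4
    n_urban_patches: int = 2
    urban_patch_size: int = 4
    n_other_patches: int = 1
    other_patch_size: int = 3

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.pixel_area)


@dataclass
class Scene:
    """A fully generated multi-year input scene."""

    config: SynthConfig
    spec: GridSpec
    lu_2000: LandUseMap
    lu_2015: LandUseMap
    masks: ChangeMasks
    climate: dict[str, dict[int, np.ndarray]]  # var -> year -> (12, H, W)
    ndvi: dict[int, np.ndarray]                # year -> (12, H, W)

    def bundle(self, year: int) -> EpochBundle:
        """Epoch bundle for one of the two epoch years."""
        lu = self.lu_2000 if year == self.config.year_start else self.lu_2015
        return EpochBundle(
            year=year, precip=self.climate["precipitation"][year],
            temp=self.climate["temperature"][year],
            rad=self.climate["radiation"][year],
            ndvi=self.ndvi[year], landuse=lu)


def _season(month_idx: np.ndarray | float) -> np.ndarray | float:
    """−1 in January, +1 in July (0-based month index)."""
    return -np.cos(2.0 * np.pi * np.asarray(month_idx) / 12.0)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance spatially smooth field from low-passed white noise."""
    white = rng.standard_normal(shape)
    if sigma <= 0:
        return white
    f = gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


# ---------------------------------------------------------------------------
# land use
# ---------------------------------------------------------------------------

def _base_map(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Contiguous-ish base map: quantile slices of a smooth field."""
    f = _smooth_field(rng, (config.n_rows, config.n_cols), config.spatial_sigma)
    # fractions of the scene per base class (crop-dominated lowland mosaic)
    fractions = (0.25, 0.20, 0.25, 0.10, 0.12, 0.08)
    edges = np.quantile(f, np.cumsum(fractions)[:-1])
    idx = np.searchsorted(edges, f, side="right")
    codes = np.array([CLASS_CODES[name] for name in _BASE_CLASSES], dtype=np.uint8)
    return codes[idx]


def _place_patches(rng: np.random.Generator, occupied: np.ndarray,
                   n_patches: int, size: int) -> list[tuple[int, int]]:
    """Non-overlapping top-left corners for size×size patches."""
    rows, cols = occupied.shape
    if size > rows or size > cols:
        raise ValueError("patch does not fit the grid")
    corners: list[tuple[int, int]] = []
    for _ in range(n_patches):
        for _attempt in range(1000):
            r = int(rng.integers(0, rows - size + 1))
            c = int(rng.integers(0, cols - size + 1))
            if not occupied[r:r + size, c:c + size].any():
                occupied[r:r + size, c:c + size] = True
                corners.append((r, c))
                break
        else:
            raise ValueError("could not place patches: grid over-subscribed")
    return corners


def generate_landuse_pair(config: SynthConfig
                          ) -> tuple[LandUseMap, LandUseMap, ChangeMasks]:
    """Two epoch maps differing by the configured contiguous patches.

    Afforestation patches are forced to crop in the first epoch and become
    arboreal forest; urbanization patches go paddy→built-up; "other"
    patches go dry land→water. The returned truth masks equal
    :func:`casacarbon.landuse.change_masks` recomputed on the pair.
    """
    rng = np.random.default_rng(config.layout_seed)
    base = _base_map(config, rng)
    occupied = np.zeros(base.shape, dtype=bool)
    aff = _place_patches(rng, occupied, config.n_afforest_patches,
                         config.afforest_patch_size)
    urb = _place_patches(rng, occupied, config.n_urban_patches,
                         config.urban_patch_size)
    oth = _place_patches(rng, occupied, config.n_other_patches,
                         config.other_patch_size)

    a = base.copy()
    b = base.copy()
    for (r, c), s in [(p, config.afforest_patch_size) for p in aff]:
        a[r:r + s, c:c + s] = CLASS_CODES["dry_land"]
        b[r:r + s, c:c + s] = CLASS_CODES["arboreal_forest"]
    for (r, c), s in [(p, config.urban_patch_size) for p in urb]:
        a[r:r + s, c:c + s] = CLASS_CODES["paddy_field"]
        b[r:r + s, c:c + s] = CLASS_CODES["built_up"]
    for (r, c), s in [(p, config.other_patch_size) for p in oth]:
        a[r:r + s, c:c + s] = CLASS_CODES["dry_land"]
        b[r:r + s, c:c + s] = CLASS_CODES["water"]

    spec = config.spec
    lu_a = LandUseMap(epoch_year=config.year_start, classes=a, spec=spec)
    lu_b = LandUseMap(epoch_year=config.year_end, classes=b, spec=spec)
    return lu_a, lu_b, change_masks(lu_a, lu_b)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def generate_climate(config: SynthConfig
                     ) -> dict[str, dict[int, np.ndarray]]:
    """Monthly precipitation / temperature / radiation grids for all years.

    Each variable is (smooth spatial field) + (sinusoidal seasonality)
    + (linear interannual trend) + (seeded Gaussian noise); precipitation
    and radiation are clipped at zero.
    """
    shape = (config.n_rows, config.n_cols)
    field_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    f_temp = _smooth_field(field_rng, shape, config.spatial_sigma)
    f_precip = _smooth_field(field_rng, shape, config.spatial_sigma)
    f_rad = _smooth_field(field_rng, shape, config.spatial_sigma)

    months = np.arange(12)
    season = _season(months)  # (12,)
    out: dict[str, dict[int, np.ndarray]] = {
        "precipitation": {}, "temperature": {}, "radiation": {}}
    for year in config.years:
        dy = year - config.year_start
        noise = noise_rng.standard_normal((3, 12) + shape)

        t = (config.temp_mean + config.temp_seasonal_amp * season[:, None, None]
             + config.temp_trend * dy
             + config.temp_spatial_amp * f_temp[None]
             + config.temp_noise * noise[0])

        p_month = config.precip_annual / 12.0
        p = (p_month * (1.0 + config.precip_seasonal_amp * season[:, None, None])
             + config.precip_trend / 12.0 * dy)
        p = p * (1.0 + config.precip_spatial_amp * f_precip[None])
        p = p * (1.0 + config.precip_noise * noise[1])
        p = np.clip(p, 0.0, None)

        r_month = config.rad_annual / 12.0
        r = (r_month * (1.0 + config.rad_seasonal_amp * season[:, None, None])
             + config.rad_trend / 12.0 * dy)
        r = r * (1.0 + config.rad_spatial_amp * f_rad[None])
        r = r * (1.0 + config.rad_noise * noise[2])
        r = np.clip(r, 0.0, None)

        out["temperature"][year] = t
        out["precipitation"][year] = p
        out["radiation"][year] = r
    return out


# ---------------------------------------------------------------------------
# NDVI
# ---------------------------------------------------------------------------

def generate_ndvi(landuse: LandUseMap, config: SynthConfig,
                  year: int | None = None,
                  noise: np.ndarray | None = None) -> np.ndarray:
    """Twelve monthly NDVI grids consistent with a land-use map.

    Per-class annual mean + seasonal cycle + interannual trend + noise,
    clipped into the class's CASA calibration range — a built-up pixel can
    never exceed that class's NDVI maximum. The noise field is independent
    of the class map, so two maps differing on a patch produce NDVI stacks
    that differ only on that patch (given the same noise).
    """
    params = load_casa_params()
    dy = 0 if year is None else year - config.year_start
    shape = (12, config.n_rows, config.n_cols)
    if noise is None:
        seed = np.random.SeedSequence([config.seed, 3, max(dy, 0)])
        noise = np.random.default_rng(seed).standard_normal(shape)
    base = np.zeros(11)
    amp = np.zeros(11)
    lo = np.full(11, -1.0)
    hi = np.full(11, 1.0)
    trend_on = np.zeros(11)
    for name, code in CLASS_CODES.items():
        b, a = _NDVI_PROFILE[name]
        base[code], amp[code] = b, a
        lo[code] = params.table.at[name, "ndvi_min"]
        hi[code] = params.table.at[name, "ndvi_max"]
        trend_on[code] = 1.0 if name not in ("water", "built_up", "bare_land") else 0.0

    codes = landuse.classes.astype(np.intp)
    season = _season(np.arange(12))[:, None, None]
    values = (base[codes][None]
              + 0.5 * config.ndvi_seasonal_scale * amp[codes][None] * season
              + config.ndvi_trend * dy * trend_on[codes][None]
              + config.ndvi_noise * noise)
    values = np.clip(values, lo[codes][None], hi[codes][None])
    return values


# ---------------------------------------------------------------------------
# whole scenes and factorial pairs
# ---------------------------------------------------------------------------

def generate_scene(config: SynthConfig = SynthConfig()) -> Scene:
    """Generate the full multi-year scene (land-use pair, climate, NDVI).

    NDVI follows the first-epoch map for the first half of the period and
    the second-epoch map afterwards (the scene has only two land-use
    snapshots, like the study design it emulates).
    """
    lu_a, lu_b, masks = generate_landuse_pair(config)
    climate = generate_climate(config)
    mid = (config.year_start + config.year_end + 1) // 2
    ndvi = {year: generate_ndvi(lu_a if year < mid else lu_b, config, year)
            for year in config.years}
    return Scene(config=config, spec=config.spec, lu_2000=lu_a, lu_2015=lu_b,
                 masks=masks, climate=climate, ndvi=ndvi)


def make_single_factor_pair(factor: str, config: SynthConfig = SynthConfig()
                            ) -> tuple[EpochBundle, EpochBundle]:
    """Two epoch bundles differing ONLY in the named factor.

    Climate factors shift the 2015 copy of that variable (temperature
    +1 °C; precipitation and radiation +20%); land-use factors apply only
    the matching patch type, with NDVI regenerated from the same noise so
    non-patch pixels stay bit-identical. Feeding the pair to
    :func:`casacarbon.scenarios.decompose` must isolate the matching Δ
    term with all others exactly zero.
    """
    if factor not in SINGLE_FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {SINGLE_FACTORS}")

    if factor in ("afforestation", "urbanization"):
        patch_cfg = replace(
            config,
            n_afforest_patches=config.n_afforest_patches if factor == "afforestation" else 0,
            n_urban_patches=config.n_urban_patches if factor == "urbanization" else 0,
            n_other_patches=0)
    else:
        patch_cfg = replace(config, n_afforest_patches=0, n_urban_patches=0,
                            n_other_patches=0)
    lu_a, lu_b, _ = generate_landuse_pair(patch_cfg)
    climate = generate_climate(replace(patch_cfg, year_end=patch_cfg.year_start))
    base_climate = {var: climate[var][patch_cfg.year_start] for var in climate}

    noise = np.random.default_rng(
        np.random.SeedSequence([config.seed, 3, 0])
    ).standard_normal((12, config.n_rows, config.n_cols))
    ndvi_a = generate_ndvi(lu_a, patch_cfg, noise=noise)
    ndvi_b = generate_ndvi(lu_b, patch_cfg, noise=noise)

    precip_b, temp_b, rad_b = (base_climate["precipitation"].copy(),
                               base_climate["temperature"].copy(),
                               base_climate["radiation"].copy())
    if factor == "temperature":
        temp_b = temp_b + 1.0
    elif factor == "precipitation":
        precip_b = precip_b * 1.2
    elif factor == "radiation":
        rad_b = rad_b * 1.2

    b2000 = EpochBundle(year=config.year_start,
                        precip=base_climate["precipitation"],
                        temp=base_climate["temperature"],
                        rad=base_climate["radiation"],
                        ndvi=ndvi_a, landuse=lu_a)
    b2015 = EpochBundle(year=config.year_end, precip=precip_b, temp=temp_b,
                        rad=rad_b, ndvi=ndvi_b, landuse=lu_b)
    return b2000, b2015


def quadrant_regions(spec: GridSpec) -> dict[str, np.ndarray]:
    """Four disjoint, exhaustive quadrant masks (stand-in city regions)."""
    r2, c2 = spec.n_rows // 2, spec.n_cols // 2
    out = {}
    for name, (rs, cs) in {
        "NW": (slice(None, r2), slice(None, c2)),
        "NE": (slice(None, r2), slice(c2, None)),
        "SW": (slice(r2, None), slice(None, c2)),
        "SE": (slice(r2, None), slice(c2, None)),
    }.items():
        m = np.zeros(spec.shape, dtype=bool)
        m[rs, cs] = True
        out[name] = m
    return out
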