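# Methods

## The CASA light-use-efficiency model

Monthly NPP is the product of absorbed photosynthetically active
radiation (APAR) and a realized light-use efficiency ε. APAR is
SOL × FPAR × 0.5, the constant 0.5 being the photosynthetically active
fraction of total shortwave radiation. FPAR is estimated as the mean of
two linear stretches, one on NDVI and one on the simple ratio
SR = (1+NDVI)/(1−NDVI); each stretch rescales the per-land-use-class
interval [min, max] onto the global band [FPARmin, FPARmax] =
[0.001, 0.950] and is clipped to that band, so FPAR is bounded by
construction. NDVI is clamped at 1 − 10⁻⁶ before the SR transform to keep
it finite.

The per-class stretch limits and εmax come from a published calibration
for a mid-subtropical, crop/forest-dominated region (ten land-use
classes; arboreal forest εmax = 0.985 gC/MJ, all classes share
NDVImin = 0.0765 and SRmin = 1.166). The tabulated SR limits are **not**
consistent with applying the SR formula to the NDVI limits for every
class (e.g. dry land: SR(0.8824) ≈ 16.0 versus the tabulated 17.002), so
they are stored and used verbatim as independent parameters. One visible
consequence: at a class's NDVI maximum the NDVI-side stretch saturates at
0.950 but the SR-side stretch usually does not, so the two-stretch mean
reaches 0.950 only for the classes whose tabulated SRmax is attained
(shrub, within rounding). At the NDVI minimum both stretches clip to
0.001 exactly, because SR(NDVImin) = 1.1657 < SRmin. A second
consequence is that the per-class NPP ranking under identical inputs is
not simply the εmax ranking — the class-dependent FPAR stretch interferes
— although arboreal forest remains the most productive class, which is
the scientifically meaningful ordering.

### Stress factors

The calibration source does not fix the stress formulations, so this
package adopts the standard CASA-China forms and documents them as its
own choice:

* **Temperature.** Topt is the per-pixel mean temperature of the month
  attaining the annual NDVI maximum (ties break to the earliest month).
  Tε1 = 0.8 + 0.02·Topt − 0.0005·Topt², floored at 0 and set to 0 in
  months with mean temperature ≤ −10 °C;
  Tε2 = 1.1814 / (1 + e^{0.2(Topt−10−T)}) / (1 + e^{0.3(−Topt−10+T)}),
  an asymmetric double-logistic peaking near Topt.
* **Moisture.** Wε = 0.5 + 0.5·EET/PET, clipped to [0.5, 1]. EET is the
  regional evapotranspiration closure
  EET = P·Rn·(P² + Rn² + P·Rn) / ((P + Rn)·(P² + Rn²)) with net-radiation
  proxy Rn = √(PET·P)·(0.369 + 0.598·√(PET/P)) (Rn = 0 when P = 0), and
  PET is the Thornthwaite monthly estimate
  PET = 16·(10·T/I)^a with the per-pixel annual heat index
  I = Σ_m (T_m/5)^1.514 over months with T > 0 and the usual cubic
  exponent a(I). The day-length/latitude correction of Thornthwaite is
  omitted: it is a smooth multiplicative factor near 1 at subtropical
  latitudes and the moisture stress only uses PET through the bounded
  ratio EET/PET. PET = 0 (cold month) or P = 0 gives the dry floor 0.5.
  Although the module signature of the published scenario design lists
  radiation among the moisture-stress drivers, this closure never uses
  it; the implementation takes (precipitation, temperature, heat index).

Numerical guards: vanishing-but-positive precipitation can underflow the
closure's denominator (or overflow PET/P); both cases are mapped to the
dry floor 0.5. Negative monthly NPP cannot arise from the formulation
itself but is floored at 0 to guard degenerate stress inputs. Nodata
(NaN) propagates through every step; a pixel with any nodata month has
nodata annual NPP.

## Grids and I/O

All grids in one analysis share a single `GridSpec` (shape, affine
transform, uniform pixel area in m², nodata sentinel); mixing specs is a
hard error everywhere. An equal-area projection is assumed — area math
always uses `pixel_area`, never degrees — which is a documented
limitation for geographic rasters. Rasters are written as single-band
TIFF (float32 continuous, uint8 land use) with the grid spec serialized
into the ImageDescription tag; true GeoTIFF geo-tags are not written, so
files are self-describing within this package but carry no CRS metadata
for GIS software. Sub-monthly NDVI composites are reduced by per-pixel
maximum-value compositing; a pixel is nodata only if nodata in every
composite. NDVI outside [−1, 1] (sensor fill) is set to nodata before
compositing so fill values cannot poison the maxima.

## Scenario decomposition

Eight runs: factual 2000 and 2015, plus
A (climate held at 2000, NDVI/land use 2015),
B/C/D (exactly one of precipitation/temperature/radiation held at 2000),
E/F (as A with NDVI restored to 2000 on the afforestation/urbanization
mask). The deltas are the subtractions listed in `scenarios.py`; the
identities ΔAll = ΔClimate + ΔLUCC and ΔOthers = ΔLUCC − ΔAfforestation −
ΔUrbanization hold exactly by construction. Design choices:

* In E/F the land-use **class** (hence the CASA parameters) is restored
  together with the NDVI by default, because a pixel's class and NDVI
  must be consistent for the FPAR stretch; `restore="ndvi_only"` gives
  the literal NDVI-only rollback.
* Scenario B is a 2015 run with precipitation held at 2000, parallel to
  C/D, so that ΔPrecipitation = CS2015 − CSB is meaningful.
* The climate–land-use interaction is carried by ΔClimate (ΔLUCC is
  measured at 2000 climate and ΔClimate is the remainder); the
  non-additivity of the single-variable climate effects is reported as
  `interaction_residual = ΔClimate − (ΔPrecip + ΔTemp + ΔRad)`, never
  forced to zero.
* CS supports both pixel-sum and regional-mean × area arithmetic; they
  coincide on gap-free regions. Published regional totals are
  mean × total-area arithmetic, which is what the reference checks use.
* Afforestation means any non-forest level-I class becoming one of the
  four forest subclasses; urbanization means anything (including forest)
  becoming built-up land. Non-vegetated classes (water, built-up, bare)
  run through the model with their calibrated parameters rather than
  being masked out.

## Statistics

Annual series are fit by OLS on the year index 0..n−1 (slope units
unchanged versus calendar years); significance is the two-sided t-test on
the slope with n−2 df. Change types at α = 0.05: significant
increase/decrease need both a signed slope and p ≤ α; everything else —
including an exactly flat series, for which p is defined as 1 — is "no
change". No multiple-testing correction is applied across pixels.
Spearman correlation uses average ranks for ties; per-pixel correlation
p-values are not computed. Endpoint change summaries use the first and
last years only, not fitted values.

## Synthetic data

The generator fabricates what the analysis assumes and nothing more:

* **Climate** — a smooth spatial field (separable Gaussian low-pass of
  white noise, σ = 4 px) plus a sinusoidal seasonal cycle plus a linear
  interannual trend plus truncated Gaussian noise; precipitation and
  radiation are clipped at 0. Defaults emulate the study region: annual
  mean temperature 16.2 °C with January 3.7 / July 28.7 °C, 1269 mm
  annual precipitation, 4713 MJ·m⁻² annual radiation, and the weak
  observed trends (+0.005 °C, +10 mm, +1.72 MJ·m⁻² per year).
* **Land use** — a quantile-sliced smooth field gives a crop-dominated
  six-class mosaic; the second epoch differs by contiguous patches:
  crop→forest (afforestation), paddy→built-up (urbanization) and
  dry→water ("other"), two 4×4, two 4×4 and one 3×3 patch by default.
  Patch geometry is driven by a separate `layout_seed` so noise seeds
  never move the patches.
* **NDVI** — per-class annual mean and seasonal amplitude (forest
  greener than grassland, water/built-up nearly flat), a small
  interannual greening trend on vegetated classes, Gaussian noise, all
  clipped into the class's calibration range — a built-up pixel can
  never exceed 0.5044.

The default scene is 64×64 pixels of 1 km², 2000–2015; a full 16-year
CASA run plus the eight-scenario decomposition takes well under a minute.
`make_single_factor_pair` builds bundle pairs that differ in exactly one
factor (bit-identical elsewhere), the factorial oracle used to verify
that the decomposition isolates exactly one Δ term.

What the generator does **not** emulate: sensor artifacts, cloud
contamination, classification error, spatially correlated *temporal*
noise, and climate–vegetation feedback (NDVI is generated independently
of the climate fields). Passing tests therefore demonstrate the
correctness of the arithmetic and the decomposition logic under the
stated statistical structure, not the realism of CASA itself on any
particular real landscape.

## Reference tables

`casacarbon.refdata` bundles the published city-level summaries for the
Wuhan City Circle study region (nine cities' annual NPP 2000–2015, the
per-city climate- and land-use-effect components, the 57,930 km² study
area and the two regional mean NPP values). They are inputs for worked
examples and arithmetic cross-checks; the pixel-level rasters behind them
are not redistributable, so raster-level headline figures (for example a
region-wide ΔClimate) cannot be recomputed here and are out of scope.

## Known limitations

* No reprojection, resampling, or geographic-coordinate support.
* Soil effects, heterotrophic respiration (NEP), CO₂ fertilization and
  nitrogen deposition are outside the model.
* Uniform pixel area assumes an equal-area projection.
* The moisture-stress/PET variant is a declared choice among the several
  used in the CASA literature; alternative variants would shift absolute
  NPP levels while leaving the decomposition identities intact.
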