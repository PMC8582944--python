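# casacarbon

Tools for estimating terrestrial net primary productivity (NPP) with the
CASA (Carnegie–Ames–Stanford Approach) light-use-efficiency model and for
decomposing the change in total carbon sequestration between two epochs
into climate effects (precipitation, temperature, radiation) and land-use
effects (afforestation, urbanization, other transitions). It is aimed at
regional carbon-cycle analyses driven by monthly NDVI and climate rasters
plus categorical land-use maps — the kind of data stack used to study
urbanizing regions such as the Wuhan City Circle (central China,
~57,930 km²).

## Model

Monthly NPP per pixel *x* and month *t* is

```
NPP(x,t)  = APAR(x,t) · ε(x,t)
APAR(x,t) = SOL(x,t) · FPAR(x,t) · 0.5
ε(x,t)    = Tε1(x,t) · Tε2(x,t) · Wε(x,t) · εmax(class(x))
```

where SOL is total solar radiation (MJ·m⁻²), FPAR is the fraction of
photosynthetically active radiation absorbed by the canopy — the mean of
two linear stretches, one on NDVI and one on the simple ratio
SR = (1+NDVI)/(1−NDVI), each rescaled between per-land-use (min, max)
limits onto [0.001, 0.950] — and εmax is the per-class maximum light-use
efficiency (gC/MJ). Tε1, Tε2 are temperature stresses around the optimum
temperature Topt (mean temperature of the month of peak NDVI), and Wε is
the moisture stress 0.5 + 0.5·EET/PET built from a regional
evapotranspiration closure and Thornthwaite monthly PET. Annual NPP is the
sum of the 12 monthly grids.

Total carbon sequestration is CS = NPP × Area (10¹⁰ gC). Change between
two epochs is decomposed with eight model runs (two factual years and six
counterfactual scenarios A–F) into

```
ΔAll  = ΔClimate + ΔLUCC
ΔLUCC = ΔAfforestation + ΔUrbanization + ΔOthers
```

with single-variable climate effects ΔPrecipitation / ΔTemperature /
ΔRadiation from scenarios that hold one variable at the first epoch.
Pixel-wise trend statistics (OLS slope, two-sided t-test, three-way change
classification at α = 0.05) and Spearman NPP–climate correlations round
out the analysis. A seeded synthetic-data generator produces co-registered
scenes (climate + NDVI + land-use pair) so the whole pipeline runs without
any external rasters.

## Worked example

```python
from casacarbon import (SynthConfig, generate_scene, load_casa_params,
                        decompose, ledger_report)

cfg = SynthConfig(seed=42)           # 64x64 grid of 1 km2 pixels, 2000-2015
scene = generate_scene(cfg)
params = load_casa_params()          # built-in per-class CASA calibration
ledgers = decompose(scene.bundle(2000), scene.bundle(2015),
                    scene.masks, params)
print(ledger_report(ledgers).round(2).T)
```

prints (all quantities in 10¹⁰ gC):

```
region                   all
cs_2000               147.55
cs_2015               161.72
d_all                  14.17
d_climate               2.77
d_precip                2.23
d_temp                 -0.18
d_rad                   0.73
d_lucc                 11.40
d_afforest              1.13
d_urban                -0.82
d_others               11.08
interaction_residual   -0.02
```

Reading: total carbon sequestration of the synthetic scene rose by
14.17 × 10¹⁰ gC between the two epochs; 2.77 of that is attributable to
climate change (mostly precipitation) and 11.40 to land-use change, of
which afforestation contributed +1.13, urbanization −0.82 and all other
transitions +11.08. The interaction residual is the gap between ΔClimate
and the sum of the three single-variable climate effects; it is reported,
never silently absorbed.

A `casacarbon` console script exposes the stages
(`simulate-data`, `npp`, `landuse`, `trends`, `decompose`) for shell use;
see `casacarbon --help`.

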