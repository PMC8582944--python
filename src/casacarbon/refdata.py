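"""Published reference figures for the Wuhan City Circle study region.

These small tables are the printed, city-level summary statistics of the
2000–2015 carbon-dynamics study of the Wuhan City Circle (nine cities,
~57,930 km²). They serve as inputs for worked examples and arithmetic
cross-checks — endpoint changes, trend rates, extrema, ledger row sums —
not as outputs of this package's model runs (the underlying rasters are
not redistributable).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "STUDY_AREA_KM2",
    "REGIONAL_MEAN_NPP",
    "city_annual_npp",
    "climate_effect_components",
    "lucc_effect_components",
]

#: Study-region area (km²) behind the regional CS = mean NPP × area totals.
STUDY_AREA_KM2 = 57_930.0

#: Regional mean annual NPP (gC·m⁻²) for the two epoch years.
REGIONAL_MEAN_NPP = {2000: 522.63, 2015: 615.82}

_CITIES = ["Ezhou", "Huanggang", "Huangshi", "Qianjiang", "Tianmen",
           "Wuhan", "Xianning", "Xiantao", "Xiaogan"]

_CITY_NPP = {
    2000: [412.82, 533.29, 481.37, 596.26, 597.56, 441.18, 531.69, 568.28, 563.21],
    2001: [447.21, 575.40, 526.53, 602.73, 598.01, 446.40, 566.70, 564.88, 572.87],
    2002: [410.72, 548.25, 503.81, 601.13, 596.05, 432.62, 547.29, 562.07, 553.36],
    2003: [399.02, 564.40, 542.19, 538.07, 571.96, 417.63, 585.89, 533.39, 543.78],
    2004: [523.80, 672.87, 603.71, 641.69, 669.17, 503.49, 638.52, 630.06, 648.63],
    2005: [470.33, 621.09, 531.77, 647.30, 656.35, 473.77, 569.00, 607.78, 596.03],
    2006: [528.62, 679.09, 611.07, 727.34, 735.14, 529.47, 679.10, 677.11, 679.78],
    2007: [507.29, 652.44, 591.75, 676.03, 682.65, 493.87, 670.15, 629.17, 632.62],
    2008: [479.46, 657.24, 606.67, 646.33, 660.78, 489.34, 646.11, 620.52, 637.29],
    2009: [461.16, 604.68, 578.31, 576.58, 596.67, 442.00, 620.19, 556.56, 589.39],
    2010: [505.42, 635.98, 623.56, 637.93, 682.79, 494.46, 659.56, 599.60, 665.57],
    2011: [475.27, 592.30, 613.61, 645.82, 677.41, 458.98, 663.37, 610.14, 603.63],
    2012: [478.37, 670.99, 573.03, 604.10, 658.06, 474.44, 621.01, 565.48, 620.55],
    2013: [501.86, 706.65, 625.04, 691.18, 737.28, 508.86, 675.53, 647.66, 698.63],
    2014: [440.79, 678.92, 572.63, 619.46, 693.14, 459.57, 667.87, 569.05, 636.27],
    2015: [433.54, 668.06, 575.46, 664.90, 699.78, 463.12, 651.85, 578.37, 656.51],
}

# Published per-city climate-effect components (10^10 gC), 2000–2015:
# single-variable effects of precipitation, temperature and radiation.
_CLIMATE_COMPONENTS = {
    "Ezhou":     (-0.04, -0.07, 9.13),
    "Huanggang": (5.34, 20.3, -5.46),
    "Huangshi":  (-1.53, -6.90, 1.84),
    "Qianjiang": (-11.5, -13.6, 10.9),
    "Tianmen":   (-10.0, -11.3, 9.04),
    "Wuhan":     (10.4, 13.1, -11.3),
    "Xianning":  (-31.0, -52.7, 31.9),
    "Xiantao":   (-2.38, -4.35, 1.52),
    "Xiaogan":   (-30.4, -22.8, 28.5),
}

# Published per-city land-use-effect components (10^10 gC), 2000–2015:
# afforestation, urbanization and the remainder of other transitions.
_LUCC_COMPONENTS = {
    "Ezhou":     (0.09, -0.33, 7.20),
    "Huanggang": (0.18, -2.04, 164.0),
    "Huangshi":  (0.16, -1.15, 21.6),
    "Qianjiang": (0.51, -0.04, 27.2),
    "Tianmen":   (0.96, 0.21, 33.8),
    "Wuhan":     (0.97, -0.8, 35.2),
    "Xianning":  (0.94, -2.64, 87.7),
    "Xiantao":   (0.86, 0.28, 12.2),
    "Xiaogan":   (1.38, 0.22, 90.8),
}


def city_annual_npp() -> pd.DataFrame:
    """Published annual mean NPP (gC·m⁻²) per city, 2000–2015.

    Index: year; columns: the nine cities of the Wuhan City Circle.
    """
    df = pd.DataFrame.from_dict(_CITY_NPP, orient="index", columns=_CITIES)
    df.index.name = "year"
    return df


def climate_effect_components() -> pd.DataFrame:
    """Published single-variable climate effects on CS (10¹⁰ gC) per city."""
    df = pd.DataFrame.from_dict(
        _CLIMATE_COMPONENTS, orient="index",
        columns=["d_precip", "d_temp", "d_rad"])
    df.index.name = "city"
    return df


def lucc_effect_components() -> pd.DataFrame:
    """Published land-use-change effect components on CS (10¹⁰ gC) per city."""
    df = pd.DataFrame.from_dict(
        _LUCC_COMPONENTS, orient="index",
        columns=["d_afforest", "d_urban", "d_others"])
    df.index.name = "city"
    return df
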