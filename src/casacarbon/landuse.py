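"""Land-use change accounting: transition matrices and change masks.

Change between the two epochs is summarized two ways: a full 10×10
cross-tabulated transition matrix in km² (optionally aggregated to the six
level-I groups), and boolean masks for the two processes the scenario
engine treats specially — afforestation (any non-forest level-I class
becoming forest) and urbanization (anything becoming built-up land,
including forest loss to the city). Pixels that are nodata in either epoch
are excluded from both products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import (BUILT_UP_CODE, CLASS_I_GROUPS, CLASS_NAMES,
                      FOREST_CODES, GridSpec, LandUseMap)

__all__ = ["ChangeMasks", "transition_matrix", "change_masks", "aggregate_class_i"]

_KM2 = 1.0e6  # m² per km²


@dataclass
class ChangeMasks:
    """Boolean grids flagging afforestation and urbanization pixels.

    The two masks are disjoint by construction (a pixel cannot end the
    period as both forest and built-up land) and both are disjoint from the
    unchanged set.
    """

    afforestation: np.ndarray
    urbanization: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        self.afforestation = np.asarray(self.afforestation, dtype=bool)
        self.urbanization = np.asarray(self.urbanization, dtype=bool)
        self.spec.validate_array(self.afforestation)
        self.spec.validate_array(self.urbanization)
        if np.any(self.afforestation & self.urbanization):
            raise ValueError("afforestation and urbanization masks overlap")


def _common_valid(lu_a: LandUseMap, lu_b: LandUseMap) -> np.ndarray:
    lu_a.spec.require_same(lu_b.spec)
    return ~(lu_a.mask | lu_b.mask)


def transition_matrix(lu_a: LandUseMap, lu_b: LandUseMap,
                      spec: GridSpec | None = None) -> pd.DataFrame:
    """Cross-tabulate land-use change between two epochs, in km².

    Rows are the first-epoch class, columns the second-epoch class; the
    diagonal is the unchanged area. Cell values are pixel counts × pixel
    area. The grand total equals the common non-nodata area.
    """
    if spec is not None:
        spec.require_same(lu_a.spec)
    valid = _common_valid(lu_a, lu_b)
    a = lu_a.classes[valid].astype(np.intp)
    b = lu_b.classes[valid].astype(np.intp)
    counts = np.zeros((11, 11), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    names = [CLASS_NAMES[c] for c in range(1, 11)]
    area = counts[1:, 1:] * lu_a.spec.pixel_area / _KM2
    return pd.DataFrame(area, index=pd.Index(names, name=lu_a.epoch_year),
                        columns=pd.Index(names, name=lu_b.epoch_year))


def change_masks(lu_a: LandUseMap, lu_b: LandUseMap) -> ChangeMasks:
    """Afforestation and urbanization masks between two epochs.

    Afforestation: level-I class not forest in epoch A, any of the four
    forest subclasses in epoch B. Urbanization: not built-up in A, built-up
    in B — transitions out of forest into built-up count as urbanization,
    not as (negative) afforestation.
    """
    valid = _common_valid(lu_a, lu_b)
    forest_a = np.isin(lu_a.classes, list(FOREST_CODES))
    forest_b = np.isin(lu_b.classes, list(FOREST_CODES))
    afforestation = valid & ~forest_a & forest_b
    urbanization = valid & (lu_a.classes != BUILT_UP_CODE) & (lu_b.classes == BUILT_UP_CODE)
    return ChangeMasks(afforestation=afforestation, urbanization=urbanization,
                       spec=lu_a.spec)


def aggregate_class_i(matrix: pd.DataFrame) -> pd.DataFrame:
    """Block-sum a 10×10 transition matrix to the six level-I groups.

    Totals are conserved; e.g. a paddy→dry cell folds into the crop→crop
    diagonal.
    """
    lut = {}
    for group, codes in CLASS_I_GROUPS.items():
        for c in codes:
            lut[CLASS_NAMES[c]] = group
    groups = list(CLASS_I_GROUPS)
    out = (matrix.rename(index=lut, columns=lut)
                 .groupby(level=0, sort=False).sum()
                 .T.groupby(level=0, sort=False).sum().T)
    return out.reindex(index=groups, columns=groups, fill_value=0.0)
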