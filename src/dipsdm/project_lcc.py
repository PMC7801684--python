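"""Binarization of suitability maps and post-hoc land-cover correction.

Continuous suitability projections are binarized at the maxSSS threshold,
then corrected post-hoc against a static contemporary land-cover map: cells
whose land-cover class is reclassified as 'unsuitable' are forced to 0.
Applying land cover after modelling (rather than as a covariate) avoids the
temporal mismatch between historical occurrence records and present-day
land cover; the same mask applies to current and future scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_rasters import RasterGrid, cell_area_km2


@dataclass
class LandCoverMap:
    classes: RasterGrid            # integer class ids
    reclass: dict[int, int]        # class id -> 1 (suitable) / 0 (unsuitable)

    def __post_init__(self) -> None:
        present = np.unique(self.classes.values[self.classes.valid_mask])
        missing = [int(c) for c in present if int(c) not in self.reclass]
        if missing:
            raise ValueError(f"classes missing from reclass table: {missing}")

    @classmethod
    def from_table(cls, classes: RasterGrid, table: pd.DataFrame) -> "LandCoverMap":
        return cls(classes, dict(zip(table["class_id"].astype(int), table["suitable"].astype(int))))

    def unsuitable_mask(self) -> np.ndarray:
        mask = np.zeros(self.classes.shape, dtype=bool)
        for cid, ok in self.reclass.items():
            if not ok:
                mask |= self.classes.values == cid
        return mask


@dataclass
class BinaryMap:
    grid: RasterGrid               # values in {0, 1} (+ nodata)
    species: str
    scenario_id: str
    threshold_used: float
    lcc_applied: bool = False


def binarize(
    suitability: RasterGrid,
    threshold: float,
    species: str = "",
    scenario_id: str = "",
) -> BinaryMap:
    """Cell = 1 iff suitability >= threshold; nodata propagates."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    valid = suitability.valid_mask
    vals = np.where(valid, (np.nan_to_num(suitability.values, nan=-np.inf) >= threshold), 0)
    vals = vals.astype(np.int16)
    vals = np.where(valid, vals, -1)
    return BinaryMap(
        grid=suitability.like(vals, nodata=-1),
        species=species,
        scenario_id=scenario_id,
        threshold_used=float(threshold),
    )


def apply_lcc(bin_map: BinaryMap, lc: LandCoverMap) -> BinaryMap:
    """Zero out cells on unsuitable land-cover classes (idempotent)."""
    if not bin_map.grid.same_registration(lc.classes):
        raise ValueError("land cover must be co-registered with the binary map")
    vals = bin_map.grid.values.copy()
    vals[lc.unsuitable_mask() & (vals == 1)] = 0
    return replace(bin_map, grid=bin_map.grid.like(vals, nodata=bin_map.grid.nodata),
                   lcc_applied=True)


def suitable_area_km2(bin_map: BinaryMap, within_mask: RasterGrid | None = None) -> float:
    """Total area of 1-cells (optionally intersected with a 0/1 mask),
    rounded to the nearest km²."""
    sel = bin_map.grid.values == 1
    if within_mask is not None:
        if not bin_map.grid.same_registration(within_mask):
            raise ValueError("mask must be co-registered")
        sel &= within_mask.values == 1
    area = cell_area_km2(bin_map.grid)
    return float(np.round(area[sel].sum()))
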