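"""Loss/stable/gain classification, richness stacking, protected-area
overlap and elevation-shift profiles.

A cell suitable now but not in the future is a *loss*; newly suitable is a
*gain* (full dispersal assumed — a ``no_dispersal`` switch empties gains for
sensitivity analysis); suitable in both is *stable*, i.e. the species'
in-situ climate macrorefugium.  Stable cells stacked over species give a
richness surface whose overlap with the protected-area mask quantifies how
well refugia are protected.  Elevation profiles count suitable cells in
50 m bins and scale by the species' peak current-scenario bin count, so 1
always marks the current peak elevation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_rasters import RasterGrid, cell_area_km2
from .project_lcc import BinaryMap

CHANGE_CODES = {"never": 0, "loss": 1, "stable": 2, "gain": 3}


@dataclass
class ChangeMap:
    grid: RasterGrid               # codes per CHANGE_CODES (+ nodata -1)
    species: str
    scenario_pair: tuple[str, str]

    def counts(self) -> dict[str, int]:
        v = self.grid.values
        return {name: int((v == code).sum()) for name, code in CHANGE_CODES.items()}

    def category_mask(self, category: str) -> np.ndarray:
        return self.grid.values == CHANGE_CODES[category]


def classify_change(
    current: BinaryMap, future: BinaryMap, no_dispersal: bool = False
) -> ChangeMap:
    """Per-cell change category between two binary maps of one species."""
    if current.species != future.species:
        raise ValueError("maps describe different species")
    if current.lcc_applied != future.lcc_applied:
        raise ValueError("mismatched land-cover-correction state")
    if not current.grid.same_registration(future.grid):
        raise ValueError("maps must be co-registered")
    c = current.grid.values
    f = future.grid.values
    valid = (c != -1) & (f != -1)
    codes = np.full(c.shape, -1, dtype=np.int16)
    codes[valid & (c == 0) & (f == 0)] = CHANGE_CODES["never"]
    codes[valid & (c == 1) & (f == 0)] = CHANGE_CODES["loss"]
    codes[valid & (c == 1) & (f == 1)] = CHANGE_CODES["stable"]
    gain_code = CHANGE_CODES["never"] if no_dispersal else CHANGE_CODES["gain"]
    codes[valid & (c == 0) & (f == 1)] = gain_code
    return ChangeMap(
        grid=current.grid.like(codes, nodata=-1),
        species=current.species,
        scenario_pair=(current.scenario_id, future.scenario_id),
    )


def stack_richness(
    maps: list[BinaryMap] | list[ChangeMap], category: str | None = None
) -> RasterGrid:
    """Per-cell count of species covering the cell.

    For BinaryMaps the covered set is the 1-cells; for ChangeMaps pass the
    category to stack (e.g. ``"stable"``).
    """
    if not maps:
        raise ValueError("no maps to stack")
    species = [m.species for m in maps]
    if len(species) != len(set(species)):
        raise ValueError("duplicate species in stack")
    tmpl = maps[0].grid
    total = np.zeros(tmpl.shape, dtype=np.int32)
    for m in maps:
        if not m.grid.same_registration(tmpl):
            raise ValueError("maps must be co-registered")
        if isinstance(m, ChangeMap):
            if category is None:
                raise ValueError("category required when stacking ChangeMaps")
            total += m.category_mask(category).astype(np.int32)
        else:
            total += (m.grid.values == 1).astype(np.int32)
    return tmpl.like(total)


def area_by_richness(
    richness: RasterGrid,
    pa_mask: RasterGrid | None = None,
    min_area_km2: float = 50.0,
) -> pd.DataFrame:
    """Total area, protected area and proportion protected per richness
    level >= 1; the proportion is suppressed (NaN) below ``min_area_km2``."""
    area = cell_area_km2(richness)
    levels = np.unique(richness.values[richness.valid_mask & (richness.values >= 1)])
    rows = []
    for lev in levels:
        sel = richness.values == lev
        total = float(area[sel].sum())
        in_pa = float(area[sel & (pa_mask.values == 1)].sum()) if pa_mask is not None else np.nan
        prop = in_pa / total if (pa_mask is not None and total >= min_area_km2) else np.nan
        rows.append({"richness": int(lev), "area_km2": total,
                     "area_pa_km2": in_pa, "prop_protected": prop})
    return pd.DataFrame(rows, columns=["richness", "area_km2", "area_pa_km2", "prop_protected"])


@dataclass
class ElevationProfile:
    bin_edges_m: np.ndarray        # half-open [k*50, (k+1)*50)
    scaled: dict[str, np.ndarray]  # category -> per-bin scaled frequency
    scale_constant: float          # max current-scenario bin count

    @property
    def bin_centers_m(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_m[:-1] + self.bin_edges_m[1:])


def _bin_counts(dem_vals: np.ndarray, mask: np.ndarray, edges: np.ndarray) -> np.ndarray:
    elev = np.clip(dem_vals[mask], 0.0, edges[-1] - 1e-9)
    counts, _ = np.histogram(elev, bins=edges)
    return counts.astype(float)


def elevation_profile(
    change: ChangeMap | BinaryMap,
    dem: RasterGrid,
    bin_m: float = 50.0,
) -> ElevationProfile:
    """Per-bin scaled frequencies of suitable cells along elevation.

    For a ChangeMap, categories loss/stable/gain are profiled and *current*
    = loss + stable; for a BinaryMap only *current* is produced.  All values
    are scaled by the maximum current-scenario bin count, so the current
    profile peaks at exactly 1 (cells below sea level clamp into bin 0).
    """
    if not change.grid.same_registration(dem):
        raise ValueError("DEM must be co-registered")
    dem_vals = np.asarray(dem.values, dtype=float)
    top = max(float(np.nanmax(dem_vals)), bin_m)
    edges = np.arange(0.0, np.ceil(top / bin_m) * bin_m + bin_m, bin_m)
    dem_ok = dem.valid_mask
    if isinstance(change, ChangeMap):
        masks = {cat: change.category_mask(cat) & dem_ok for cat in ("loss", "stable", "gain")}
        counts = {cat: _bin_counts(dem_vals, m, edges) for cat, m in masks.items()}
        counts["current"] = counts["loss"] + counts["stable"]
    else:
        counts = {"current": _bin_counts(dem_vals, (change.grid.values == 1) & dem_ok, edges)}
    scale = counts["current"].max()
    scale = scale if scale > 0 else 1.0
    return ElevationProfile(
        bin_edges_m=edges,
        scaled={cat: c / scale for cat, c in counts.items()},
        scale_constant=float(scale),
    )


def average_profiles(profiles: list[ElevationProfile]) -> ElevationProfile:
    """Per-bin arithmetic mean of the per-species scaled profiles.

    Profiles are padded with zero bins up to the longest edge vector (a
    species absent from high bins contributes zeros there); genuinely
    inconsistent bin widths raise.
    """
    if not profiles:
        raise ValueError("no profiles")
    widths = {float(np.diff(p.bin_edges_m)[0]) for p in profiles}
    if len(widths) != 1:
        raise ValueError("inconsistent bin widths")
    longest = max(profiles, key=lambda p: len(p.bin_edges_m))
    edges = longest.bin_edges_m
    n_bins = len(edges) - 1
    cats = sorted({c for p in profiles for c in p.scaled})
    mean = {}
    for cat in cats:
        acc = np.zeros(n_bins)
        for p in profiles:
            v = p.scaled.get(cat, np.zeros(len(p.bin_edges_m) - 1))
            acc[: len(v)] += v
        mean[cat] = acc / len(profiles)
    return ElevationProfile(bin_edges_m=edges, scaled=mean, scale_constant=np.nan)
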