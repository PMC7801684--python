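"""Raster data model and I/O shared by every pipeline stage.

The pipeline is raster-only: every spatial input (environmental layers, land
cover, protected areas, elevation) is a single-band grid, and all masks are
cell-aligned.  Two coordinate modes are supported:

* ``"planar-km"`` — a flat landscape with kilometre units (synthetic mode);
  distances are Euclidean and every cell has area ``dx * dy``.
* ``"lonlat-deg"`` — geographic coordinates in degrees; distances are
  great-circle (haversine) and cell areas follow the spherical-band formula,
  so they shrink with latitude.

Grid convention: origin at the top-left corner, row index increases
southward, and a cell's value refers to its centre.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

EARTH_RADIUS_KM = 6371.0088

# GeoTIFF / GDAL tag codes used for georeferencing single-band TIFFs.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """A single-band georeferenced grid with an optional nodata sentinel.

    Parameters
    ----------
    values
        2-D array (float for continuous layers, int for categorical ones).
    x0, y0
        Coordinates of the top-left *corner* of the grid.
    dx, dy
        Cell sizes (both positive); rows advance southward (decreasing y).
    crs_tag
        ``"planar-km"`` or ``"lonlat-deg"``.
    nodata
        Sentinel value marking invalid cells; NaN is always treated as
        nodata for float grids.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    dx: float = 1.0
    dy: float = 1.0
    crs_tag: str = "planar-km"
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes dx, dy must be positive")
        if self.crs_tag not in ("planar-km", "lonlat-deg"):
            raise ValueError(f"unknown crs_tag {self.crs_tag!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where the cell holds a usable value."""
        mask = np.ones(self.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= np.isfinite(self.values)
        if self.nodata is not None:
            mask &= self.values != self.nodata
        return mask

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_cols) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.y0 - (np.arange(self.n_rows) + 0.5) * self.dy

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrids of cell-centre coordinates."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def point_to_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (x, y) points to (row, col) of the containing cell."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        col = np.floor((pts[:, 0] - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - pts[:, 1]) / self.dy).astype(int)
        if (row < 0).any() or (row >= self.n_rows).any() or (col < 0).any() or (
            col >= self.n_cols
        ).any():
            raise ValueError("point outside the raster extent")
        return row, col

    def values_at(self, points: np.ndarray) -> np.ndarray:
        row, col = self.point_to_index(points)
        return self.values[row, col]

    def same_registration(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
            and self.crs_tag == other.crs_tag
        )

    def like(self, values: np.ndarray, nodata: float | int | None = None) -> "RasterGrid":
        """A new grid sharing this grid's registration."""
        return replace(self, values=np.asarray(values), nodata=nodata)


def cell_area_km2(grid: RasterGrid) -> np.ndarray:
    """Per-cell area in km².

    Planar grids have the constant area ``dx * dy``.  Geographic grids use
    the spherical-band formula: a cell spanning longitudes ``Δλ`` between
    latitudes ``φ1 < φ2`` has area ``R² Δλ (sin φ2 − sin φ1)``.
    """
    if grid.crs_tag == "planar-km":
        return np.full(grid.shape, grid.dx * grid.dy)
    if grid.crs_tag == "lonlat-deg":
        lat_top = grid.y0 - np.arange(grid.n_rows) * grid.dy
        lat_bot = lat_top - grid.dy
        dlon = math.radians(grid.dx)
        band = (
            EARTH_RADIUS_KM**2
            * dlon
            * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
        )
        return np.repeat(band[:, None], grid.n_cols, axis=1)
    raise ValueError(f"unknown crs_tag {grid.crs_tag!r}")


def great_circle_km(p1, p2, crs_tag: str = "planar-km") -> float:
    """Distance between two points: Euclidean (planar) or haversine (lonlat)."""
    x1, y1 = float(p1[0]), float(p1[1])
    x2, y2 = float(p2[0]), float(p2[1])
    if crs_tag == "planar-km":
        return math.hypot(x2 - x1, y2 - y1)
    if crs_tag == "lonlat-deg":
        lam1, phi1 = math.radians(x1), math.radians(y1)
        lam2, phi2 = math.radians(x2), math.radians(y2)
        a = (
            math.sin((phi2 - phi1) / 2) ** 2
            + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2
        )
        return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))
    raise ValueError(f"unknown crs_tag {crs_tag!r}")


def pairwise_distance_km(points_a: np.ndarray, points_b: np.ndarray, crs_tag: str) -> np.ndarray:
    """Full (n_a, n_b) distance matrix, vectorized."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if crs_tag == "planar-km":
        diff = a[:, None, :] - b[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    if crs_tag == "lonlat-deg":
        lam_a, phi_a = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
        lam_b, phi_b = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
        h = (
            np.sin((phi_b - phi_a) / 2) ** 2
            + np.cos(phi_a) * np.cos(phi_b) * np.sin((lam_b - lam_a) / 2) ** 2
        )
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    raise ValueError(f"unknown crs_tag {crs_tag!r}")


@dataclass
class EnvStack:
    """Named, co-registered set of environmental layers for one scenario."""

    layers: dict[str, RasterGrid]
    scenario_id: str = "current"

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(names) != len(set(names)):
            raise ValueError("layer names must be unique")
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not grids[0].same_registration(g):
                raise ValueError("all layers in an EnvStack must be co-registered")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def joint_valid_mask(self) -> np.ndarray:
        mask = np.ones(self.template.shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.valid_mask
        return mask

    def table(self, names: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid, n_layers) matrix over jointly valid cells + flat index."""
        names = list(names) if names is not None else self.names
        mask = self.joint_valid_mask()
        idx = np.flatnonzero(mask.ravel())
        cols = [np.asarray(self.layers[n].values, dtype=float).ravel()[idx] for n in names]
        return np.column_stack(cols), idx

    def values_at(self, points: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else self.names
        return np.column_stack([self.layers[n].values_at(points) for n in names]).astype(float)

    def subset(self, names: Sequence[str]) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names}, scenario_id=self.scenario_id)


@dataclass
class OccurrenceSet:
    """One species' presence coordinates (presence-only, GBIF-style)."""

    species: str
    points: np.ndarray
    years: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and not np.isfinite(self.points).all():
            raise ValueError("occurrence coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_raster(path: str | Path, grid: RasterGrid) -> None:
    """Write a single-band GeoTIFF (pixel scale, tiepoint and nodata tags)."""
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.dx, grid.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, grid.y0, 0.0)),
    ]
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)))
    tifffile.imwrite(
        str(path),
        grid.values,
        description=json.dumps({"crs_tag": grid.crs_tag}),
        extratags=extratags,
    )


def read_raster(path: str | Path, band: int = 0) -> RasterGrid:
    """Read one band of a GeoTIFF written by :func:`write_raster` (or any
    single-band GeoTIFF carrying pixel-scale / tiepoint tags)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        if band < 0 or band >= len(tif.pages):
            raise IndexError(f"band {band} out of range for {path}")
        page = tif.pages[band]
        values = page.asarray()
        tags = page.tags
        dx = dy = 1.0
        x0 = y0 = 0.0
        if _TAG_MODEL_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            dx, dy = float(sx), float(sy)
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            x0, y0 = float(tp[3]), float(tp[4])
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            nodata = float(raw) if np.issubdtype(values.dtype, np.floating) else int(float(raw))
        crs_tag = "planar-km"
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                crs_tag = json.loads(desc.value).get("crs_tag", "planar-km")
            except (json.JSONDecodeError, AttributeError):
                pass
    return RasterGrid(values, x0=x0, y0=y0, dx=dx, dy=dy, crs_tag=crs_tag, nodata=nodata)


def write_occurrences(path: str | Path, occs: Iterable[OccurrenceSet]) -> None:
    frames = []
    for occ in occs:
        df = pd.DataFrame({"species": occ.species, "x": occ.points[:, 0], "y": occ.points[:, 1]})
        if occ.years is not None:
            df["year"] = occ.years
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_occurrences(path: str | Path) -> list[OccurrenceSet]:
    df = pd.read_csv(path)
    out = []
    for sp, grp in df.groupby("species", sort=False):
        years = grp["year"].to_numpy() if "year" in grp.columns else None
        out.append(OccurrenceSet(str(sp), grp[["x", "y"]].to_numpy(), years))
    return out


def aggregate_block_mean(grid: RasterGrid, factor: int) -> RasterGrid:
    """Aggregate a grid to a coarser resolution by block mean.

    Used to bring fine-resolution derived layers (e.g. soil principal
    components) onto the analysis grid.  Partial trailing blocks are
    dropped; nodata cells are excluded from each block's mean.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr = grid.n_rows // factor
    nc = grid.n_cols // factor
    vals = np.asarray(grid.values[: nr * factor, : nc * factor], dtype=float).copy()
    mask = grid.valid_mask[: nr * factor, : nc * factor]
    vals[~mask] = np.nan
    blocks = vals.reshape(nr, factor, nc, factor)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(blocks, axis=(1, 3))
    return RasterGrid(
        out,
        x0=grid.x0,
        y0=grid.y0,
        dx=grid.dx * factor,
        dy=grid.dy * factor,
        crs_tag=grid.crs_tag,
        nodata=None,
    )
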