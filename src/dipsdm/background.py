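"""Pseudo-absence sampling and background-extent calibration.

Background (pseudo-absence) points are drawn from an annulus around the
presences: cells farther than a fixed exclusion distance (default 10 km,
preventing cells holding both a presence and a pseudo-absence) but within a
buffer distance of the nearest presence.  The buffer itself is tuned per
species: default-settings models are cross-validated over an ascending
buffer grid, a Michaelis-Menten curve ``AUC(d) = Vm * d / (K + d)`` is fit
to the buffer-performance pairs, and the smallest buffer whose observed AUC
reaches the fitted asymptote ``Vm`` is selected (falling back to the
best-AUC buffer when no observation crosses the asymptote, which a noiseless
saturating curve never does).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .core_rasters import EnvStack, OccurrenceSet, RasterGrid, pairwise_distance_km
from .evaluate_tune import PartitionScheme, _fold_scores, make_partitions


@dataclass
class BackgroundSpec:
    buffer_km: float
    exclusion_km: float = 10.0
    n_points: int = 1000

    def __post_init__(self) -> None:
        if not (self.buffer_km > self.exclusion_km >= 0):
            raise ValueError("require buffer_km > exclusion_km >= 0")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass
class BackgroundTuningResult:
    buffer_grid_km: np.ndarray
    auc_per_buffer: np.ndarray
    vm: float
    k_km: float
    selected_buffer_km: float


def distance_to_nearest_presence(grid: RasterGrid, occ: OccurrenceSet) -> np.ndarray:
    """Per-cell distance (km) from cell centre to the nearest presence."""
    X, Y = grid.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    if grid.crs_tag == "planar-km":
        tree = cKDTree(occ.points)
        d, _ = tree.query(centers)
    else:
        d = pairwise_distance_km(centers, occ.points, grid.crs_tag).min(axis=1)
    return d.reshape(grid.shape)


def sample_background(
    occ: OccurrenceSet,
    grid: RasterGrid,
    spec: BackgroundSpec,
    seed: int = 0,
    distance_km: np.ndarray | None = None,
) -> np.ndarray:
    """Sample pseudo-absence cell centres from the annulus
    ``exclusion_km < d(nearest presence) <= buffer_km``.

    Sampling is uniform without replacement; if the annulus holds fewer
    valid cells than requested, sampling is with replacement.  Pass a
    precomputed ``distance_km`` grid to amortize across buffers.
    """
    if distance_km is None:
        distance_km = distance_to_nearest_presence(grid, occ)
    eligible = (
        (distance_km > spec.exclusion_km)
        & (distance_km <= spec.buffer_km)
        & grid.valid_mask
    )
    idx = np.flatnonzero(eligible.ravel())
    if len(idx) == 0:
        raise ValueError("empty annulus: no eligible background cells")
    rng = np.random.default_rng(seed)
    replace = spec.n_points > len(idx)
    chosen = rng.choice(idx, size=spec.n_points, replace=replace)
    rows, cols = np.unravel_index(chosen, grid.shape)
    x = grid.x0 + (cols + 0.5) * grid.dx
    y = grid.y0 - (rows + 0.5) * grid.dy
    return np.column_stack([x, y])


def _mm(d: np.ndarray, vm: float, k: float) -> np.ndarray:
    return vm * d / (k + d)


def fit_michaelis_menten(
    buffers: np.ndarray, performances: np.ndarray
) -> tuple[float, float]:
    """Least-squares fit of the saturation curve ``y = Vm d / (K + d)``."""
    d = np.asarray(buffers, dtype=float)
    y = np.asarray(performances, dtype=float)
    if len(d) < 3 or len(np.unique(d)) < 3:
        raise ValueError("need at least three distinct buffers")
    if not (np.isfinite(d).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    if np.ptp(y) == 0:
        return float(y[0]), 1e-9  # flat curve: asymptote reached immediately
    p0 = (min(1.0, max(y.max(), 1e-3)), float(np.median(d)))
    try:
        (vm, k), _ = curve_fit(
            _mm, d, y, p0=p0, bounds=([1e-9, 1e-9], [1.0, 1e7]), maxfev=20000
        )
    except RuntimeError:
        vm, k = p0
    return float(vm), float(k)


def select_buffer_from_curve(
    buffers: np.ndarray, aucs: np.ndarray
) -> tuple[float, float, float]:
    """Michaelis-Menten selection rule applied to an observed curve.

    Returns (Vm, K, selected buffer): the smallest buffer whose observed
    performance reaches the fitted asymptote Vm, or the best-performing
    buffer when none crosses it.
    """
    buffers = np.asarray(buffers, dtype=float)
    aucs = np.asarray(aucs, dtype=float)
    vm, k = fit_michaelis_menten(buffers, aucs)
    crossing = np.flatnonzero(aucs >= vm)
    selected = buffers[crossing[0]] if len(crossing) else buffers[int(np.argmax(aucs))]
    return vm, k, float(selected)


def select_background_extent(
    occ: OccurrenceSet,
    stack: EnvStack,
    buffer_grid_km: np.ndarray,
    n_points: int = 1000,
    exclusion_km: float = 10.0,
    seed: int = 0,
    n_hinge_knots: int = 10,
    max_iterations: int = 200,
    convergence_tol: float = 1e-4,
) -> BackgroundTuningResult:
    """Tune the background buffer with default-settings models.

    For each ascending buffer, 'block'-partitioned cross-validated AUC of an
    LQPH / rm=1 model on that buffer's pseudo-absences is recorded; a
    Michaelis-Menten curve is fitted to (buffer, AUC) and the smallest
    buffer whose AUC >= fitted Vm wins (max-AUC buffer if none crosses).
    """
    buffers = np.sort(np.asarray(buffer_grid_km, dtype=float))
    grid = stack.template
    dist = distance_to_nearest_presence(grid, occ)
    pres_cov = stack.values_at(occ.points)
    names = stack.names
    aucs = np.empty(len(buffers))
    for i, buf in enumerate(buffers):
        spec = BackgroundSpec(buffer_km=buf, exclusion_km=exclusion_km, n_points=n_points)
        bg = sample_background(occ, grid, spec, seed=seed + i, distance_km=dist)
        # block partitioning regardless of sample size during extent tuning
        part = make_partitions(occ, bg, threshold_n=1)
        bg_cov = stack.values_at(bg, names)
        _or, auc = _fold_scores(
            pres_cov, bg_cov, names, part, "LQPH", 1.0,
            n_hinge_knots, max_iterations, convergence_tol,
        )
        aucs[i] = auc
    vm, k, selected = select_buffer_from_curve(buffers, aucs)
    return BackgroundTuningResult(
        buffer_grid_km=buffers,
        auc_per_buffer=aucs,
        vm=vm,
        k_km=k,
        selected_buffer_km=selected,
    )
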