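"""Synthetic landscapes, species, occurrences, land cover and future climates.

The generator reproduces the statistical structure the downstream analysis
assumes: smooth spatially-autocorrelated environmental fields with a known
cross-correlation structure, species whose true per-cell occurrence
probability is a known inverse-cloglog function of a covariate subset,
spatially biased presence-only sampling, categorical land cover grown as
blobs with natural and anthropogenic classes, blob-shaped protected areas, a
digital elevation model anti-correlated with the temperature-like layer, and
future climates built from the current one by per-layer shift/scale plus
smooth GCM-specific noise.

Every generator is deterministic under its seed.  Default landscapes are
planar with 4 km cells, so a 64x64 grid spans 256 km and the analysis'
kilometre-scale rules (10 km thinning and exclusion, 20-200 km background
buffers) are geometrically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core_rasters import EnvStack, OccurrenceSet, RasterGrid

DEFAULT_CELL_KM = 4.0
TEMPERATURE_LAYER = "bio01"


@dataclass
class TrueSpecies:
    """Known truth behind a synthetic species.

    ``coef_linear``/``coef_quadratic`` act on layer values standardized over
    the landscape, so coefficients are effect sizes per landscape s.d.
    """

    species: str
    coef_linear: dict[str, float]
    coef_quadratic: dict[str, float]
    prevalence_target: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence_target must lie in (0, 1)")
        # All-zero coefficients are allowed: the species is then spatially
        # uniform with probability = prevalence_target (a useful null).


@dataclass
class ScenarioOffsets:
    """Per-layer additive shift and multiplicative scale defining a future
    scenario from the current one (future = current * scale + shift)."""

    scenario_id: str
    shifts: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales.values()):
            raise ValueError("scales must be positive")


def _smooth_field(n_rows: int, n_cols: int, spatial_range: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized low-frequency Gaussian field (smoothed white noise)."""
    white = rng.standard_normal((n_rows, n_cols))
    f = gaussian_filter(white, sigma=spatial_range, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_env_stack(
    n_rows: int = 64,
    n_cols: int = 64,
    n_bioclim: int = 3,
    n_soil: int = 8,
    spatial_range: float = 6.0,
    cross_correlation: float = 0.0,
    seed: int = 0,
    cell_km: float = DEFAULT_CELL_KM,
) -> tuple[EnvStack, RasterGrid]:
    """Generate a current-climate EnvStack plus a DEM.

    Layers ``bio01..bioNN`` are smooth standardized fields; when
    ``cross_correlation`` > 0 the designated pair (bio01, bio02) is built
    with that correlation.  Soil layers ``soil01..soilNN`` mix three latent
    fields plus idiosyncratic noise, giving them the low effective rank that
    motivates a PCA.  The DEM is negatively correlated with the
    temperature-like layer (``bio01``), emulating the lapse rate.

    Returns
    -------
    (stack, dem) where dem is in metres above sea level.
    """
    if n_rows < 16 or n_cols < 16:
        raise ValueError("landscape must be at least 16x16")
    if not (0.0 <= cross_correlation < 1.0):
        raise ValueError("cross_correlation must lie in [0, 1)")
    if n_bioclim < 1:
        raise ValueError("need at least one bioclim layer")
    rng = np.random.default_rng(seed)
    layers: dict[str, RasterGrid] = {}

    def grid(arr: np.ndarray) -> RasterGrid:
        return RasterGrid(arr, x0=0.0, y0=n_rows * cell_km, dx=cell_km, dy=cell_km,
                          crs_tag="planar-km")

    bio_fields = [_smooth_field(n_rows, n_cols, spatial_range, rng) for _ in range(n_bioclim)]
    if n_bioclim >= 2 and cross_correlation > 0.0:
        rho = cross_correlation
        bio_fields[1] = rho * bio_fields[0] + np.sqrt(1 - rho**2) * bio_fields[1]
        bio_fields[1] = (bio_fields[1] - bio_fields[1].mean()) / bio_fields[1].std()
    for i, f in enumerate(bio_fields):
        layers[f"bio{i + 1:02d}"] = grid(f)

    latent = [_smooth_field(n_rows, n_cols, spatial_range, rng) for _ in range(3)]
    for j in range(n_soil):
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        f = sum(wi * li for wi, li in zip(w, latent))
        f = f + 0.15 * _smooth_field(n_rows, n_cols, max(1.0, spatial_range / 3), rng)
        f = (f - f.mean()) / f.std()
        layers[f"soil{j + 1:02d}"] = grid(f)

    # DEM: temperature decreases with elevation, so corr(dem, bio01) < 0.
    dem_std = -0.8 * bio_fields[0] + 0.6 * _smooth_field(n_rows, n_cols, spatial_range, rng)
    dem_std = (dem_std - dem_std.mean()) / dem_std.std()
    dem_m = np.clip(700.0 + 450.0 * dem_std, 0.0, None)
    return EnvStack(layers, scenario_id="current"), grid(dem_m)


def _standardized_table(stack: EnvStack, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    table, idx = stack.table(names)
    mu = table.mean(axis=0)
    sd = table.std(axis=0)
    sd[sd == 0] = 1.0
    return (table - mu) / sd, idx


def generate_species(
    stack: EnvStack,
    coef_linear: dict[str, float],
    coef_quadratic: dict[str, float] | None = None,
    prevalence_target: float = 0.15,
    species: str = "synthetic_sp",
    seed: int = 0,
) -> tuple[TrueSpecies, RasterGrid]:
    """Build a species with known truth and its true-probability raster.

    Per-cell occurrence probability is the inverse cloglog of the linear
    predictor, ``p = 1 − exp(−exp(η))``, with the intercept calibrated by
    bisection so that the landscape-mean probability equals
    ``prevalence_target``.
    """
    coef_quadratic = coef_quadratic or {}
    sp = TrueSpecies(species, dict(coef_linear), dict(coef_quadratic), prevalence_target)
    names = sorted(set(coef_linear) | set(coef_quadratic))
    if names:
        z, idx = _standardized_table(stack, names)
        eta = np.zeros(len(z))
        for j, name in enumerate(names):
            eta += coef_linear.get(name, 0.0) * z[:, j]
            eta += coef_quadratic.get(name, 0.0) * z[:, j] ** 2
    else:
        idx = np.flatnonzero(stack.joint_valid_mask().ravel())
        eta = np.zeros(len(idx))

    def mean_prob(c: float) -> float:
        return float(np.mean(1.0 - np.exp(-np.exp(np.clip(eta + c, -30, 30)))))

    lo, hi = -30.0, 30.0
    if not (mean_prob(lo) <= prevalence_target <= mean_prob(hi)):
        raise ValueError("prevalence unreachable for this predictor")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_prob(mid) < prevalence_target:
            lo = mid
        else:
            hi = mid
    sp.intercept = 0.5 * (lo + hi)
    prob_flat = 1.0 - np.exp(-np.exp(np.clip(eta + sp.intercept, -30, 30)))
    tmpl = stack.template
    prob = np.full(tmpl.shape, np.nan)
    prob.ravel()[idx] = prob_flat
    return sp, tmpl.like(prob)


def sample_occurrences(
    true_prob: RasterGrid,
    n_presence: int,
    sampling_bias: RasterGrid | None = None,
    seed: int = 0,
    species: str = "synthetic_sp",
    replace: bool = False,
) -> OccurrenceSet:
    """Draw presences with probability ∝ truth × bias; jitter within cells."""
    rng = np.random.default_rng(seed)
    w = np.where(true_prob.valid_mask, np.nan_to_num(true_prob.values, nan=0.0), 0.0)
    w = np.asarray(w, dtype=float)
    if sampling_bias is not None:
        if not true_prob.same_registration(sampling_bias):
            raise ValueError("sampling bias raster must be co-registered")
        w = w * np.clip(np.nan_to_num(sampling_bias.values, nan=0.0), 0.0, None)
    flat = w.ravel()
    positive = np.flatnonzero(flat > 0)
    if not replace and n_presence > len(positive):
        raise ValueError(
            f"n_presence={n_presence} exceeds {len(positive)} cells with positive probability"
        )
    p = flat[positive] / flat[positive].sum()
    chosen = rng.choice(positive, size=n_presence, replace=replace, p=p)
    rows, cols = np.unravel_index(chosen, true_prob.shape)
    xc = true_prob.x0 + (cols + 0.5) * true_prob.dx
    yc = true_prob.y0 - (rows + 0.5) * true_prob.dy
    jit = rng.uniform(-0.5, 0.5, size=(n_presence, 2))
    pts = np.column_stack([xc + jit[:, 0] * true_prob.dx, yc + jit[:, 1] * true_prob.dy])
    return OccurrenceSet(species, pts)


def generate_landcover_and_pa(
    stack: EnvStack,
    n_classes: int = 22,
    anthropogenic_fraction: float = 0.5,
    pa_fraction: float = 0.15,
    seed: int = 0,
    n_unsuitable: int | None = 17,
    blob_range: float = 4.0,
) -> tuple[RasterGrid, RasterGrid, pd.DataFrame]:
    """Categorical land cover (blobby classes), PA mask, and reclass table.

    Classes are grown as spatial blobs by arg-maxing per-class smooth score
    fields.  A subset of classes is marked unsuitable so their combined
    coverage approximates ``anthropogenic_fraction``; when ``n_unsuitable``
    is given, exactly that many classes are marked.  The protected-area mask
    is a smooth field thresholded at its (1 − pa_fraction) quantile, giving
    blob-shaped areas covering almost exactly ``pa_fraction`` of the grid.

    Returns (landcover classes grid, PA mask grid (0/1), reclass table with
    columns class_id, class_name, suitable).
    """
    if not (0.0 <= anthropogenic_fraction <= 1.0):
        raise ValueError("anthropogenic_fraction must lie in [0, 1]")
    if not (0.0 < pa_fraction < 1.0):
        raise ValueError("pa_fraction must lie in (0, 1)")
    if n_unsuitable is not None and not (0 <= n_unsuitable <= n_classes):
        raise ValueError("n_unsuitable out of range")
    rng = np.random.default_rng(seed)
    tmpl = stack.template
    nr, nc = tmpl.shape
    scores = np.stack(
        [_smooth_field(nr, nc, blob_range, rng) + rng.normal(0, 0.25) for _ in range(n_classes)]
    )
    classes = np.argmax(scores, axis=0).astype(np.int32) + 1  # class ids 1..n

    areas = np.array([(classes == cid).sum() for cid in range(1, n_classes + 1)], dtype=float)
    frac = areas / areas.sum()
    target = anthropogenic_fraction
    order = rng.permutation(n_classes)
    unsuitable: list[int] = []
    cum = 0.0
    for ci in order:
        if cum < target:
            unsuitable.append(ci)
            cum += frac[ci]
    if n_unsuitable is not None:
        # pad with the smallest remaining classes / trim the smallest chosen
        rest = sorted(set(range(n_classes)) - set(unsuitable), key=lambda c: frac[c])
        while len(unsuitable) < n_unsuitable and rest:
            unsuitable.append(rest.pop(0))
        while len(unsuitable) > n_unsuitable:
            unsuitable.remove(min(unsuitable, key=lambda c: frac[c]))
    unsuit_set = {ci + 1 for ci in unsuitable}
    reclass = pd.DataFrame(
        {
            "class_id": np.arange(1, n_classes + 1),
            "class_name": [
                f"anthropogenic_{cid}" if cid in unsuit_set else f"natural_{cid}"
                for cid in range(1, n_classes + 1)
            ],
            "suitable": [0 if cid in unsuit_set else 1 for cid in range(1, n_classes + 1)],
        }
    )

    pa_field = _smooth_field(nr, nc, blob_range, rng)
    thresh = np.quantile(pa_field, 1.0 - pa_fraction)
    pa = (pa_field > thresh).astype(np.int16)
    return tmpl.like(classes), tmpl.like(pa), reclass


def generate_future(
    stack: EnvStack,
    offsets: ScenarioOffsets,
    n_gcms: int = 5,
    gcm_noise_sd: float = 0.1,
    seed: int = 0,
    noise_range: float = 6.0,
) -> list[EnvStack]:
    """n_gcms future realisations: shifted/rescaled current climate plus
    independent smooth GCM noise of s.d. ``gcm_noise_sd`` per layer."""
    if n_gcms < 1:
        raise ValueError("n_gcms must be >= 1")
    rng = np.random.default_rng(seed)
    tmpl = stack.template
    out = []
    for g in range(n_gcms):
        layers = {}
        for name, grid in stack.layers.items():
            scale = offsets.scales.get(name, 1.0)
            shift = offsets.shifts.get(name, 0.0)
            vals = np.asarray(grid.values, dtype=float) * scale + shift
            if gcm_noise_sd > 0:
                vals = vals + gcm_noise_sd * _smooth_field(tmpl.n_rows, tmpl.n_cols, noise_range, rng)
            layers[name] = grid.like(vals, nodata=grid.nodata)
        out.append(EnvStack(layers, scenario_id=f"{offsets.scenario_id}-gcm{g + 1}"))
    return out
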