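"""Occurrence thinning, predictor pruning, soil PCA, and GCM averaging.

These are the data-preparation steps applied before any model is fitted:

* spatial thinning of presence records at a minimum nearest-neighbour
  distance (default 10 km) to reduce sampling bias;
* greedy removal of environmental layers until no retained pair has
  |Pearson r| above a threshold (default 0.7);
* PCA compression of the soil layers, keeping the fewest components that
  explain more than a target share of total variance (default 90%);
* cellwise averaging of multiple GCM realisations of a future scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .core_rasters import EnvStack, OccurrenceSet, RasterGrid, pairwise_distance_km


@dataclass
class PreprocessConfig:
    thin_km: float = 10.0
    r_threshold: float = 0.7
    pca_var_target: float = 0.90
    keep_list: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.thin_km <= 0:
            raise ValueError("thin_km must be positive")
        if not (0 < self.r_threshold < 1):
            raise ValueError("r_threshold must lie in (0, 1)")
        if not (0 < self.pca_var_target < 1):
            raise ValueError("pca_var_target must lie in (0, 1)")


def thin_occurrences(
    occ: OccurrenceSet,
    thin_km: float = 10.0,
    n_restarts: int = 20,
    seed: int = 0,
    crs_tag: str = "planar-km",
) -> OccurrenceSet:
    """Randomized-restart greedy spatial thinning.

    Each pass repeatedly deletes one member (chosen at random) of the
    closest pair closer than ``thin_km``, until no violating pair remains;
    the largest surviving set over ``n_restarts`` passes is returned.  The
    result is always a subset of the input with all pairwise distances
    >= ``thin_km``, and thinning an already-thinned set is the identity.
    """
    n = occ.n
    if n <= 1:
        return occ
    dist = pairwise_distance_km(occ.points, occ.points, crs_tag)
    np.fill_diagonal(dist, np.inf)
    if dist.min() >= thin_km:
        return occ
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(max(1, n_restarts)):
        alive = np.ones(n, dtype=bool)
        d = dist.copy()
        while True:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if d[i, j] >= thin_km:
                break
            drop = i if rng.random() < 0.5 else j
            alive[drop] = False
            d[drop, :] = np.inf
            d[:, drop] = np.inf
        if best is None or alive.sum() > best.sum():
            best = alive
    keep = np.flatnonzero(best)
    years = occ.years[keep] if occ.years is not None else None
    return OccurrenceSet(occ.species, occ.points[keep], years)


def correlation_filter(
    stack: EnvStack,
    r_threshold: float = 0.7,
    keep_list: tuple[str, ...] = (),
) -> list[str]:
    """Greedy collinearity pruning over jointly valid cells.

    While any retained pair violates |r| > threshold, drop the non-keep-list
    variable with the largest mean |r| against its violating partners.
    Returns retained layer names in stack order.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least two layers")
    table, _ = stack.table(names)
    corr = np.corrcoef(table, rowvar=False)
    keep_set = set(keep_list)
    unknown = keep_set - set(names)
    if unknown:
        raise ValueError(f"keep_list names not in stack: {sorted(unknown)}")
    retained = list(names)
    while True:
        idx = {n: names.index(n) for n in retained}
        viol = [
            (a, b)
            for i, a in enumerate(retained)
            for b in retained[i + 1 :]
            if abs(corr[idx[a], idx[b]]) > r_threshold
        ]
        if not viol:
            return retained
        for a, b in viol:
            if a in keep_set and b in keep_set:
                raise ValueError(
                    f"keep_list pair ({a}, {b}) violates |r| <= {r_threshold}"
                )
        partners: dict[str, list[float]] = {}
        for a, b in viol:
            partners.setdefault(a, []).append(abs(corr[idx[a], idx[b]]))
            partners.setdefault(b, []).append(abs(corr[idx[a], idx[b]]))
        candidates = [n for n in retained if n in partners and n not in keep_set]
        drop = max(candidates, key=lambda n: (np.mean(partners[n]), -retained.index(n)))
        retained.remove(drop)


@dataclass
class PCAResult:
    """Loadings and standardization of the soil PCA, reusable on any
    co-registered stack (e.g. future scenarios) via :meth:`transform`."""

    layer_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # (n_components_full, n_layers)
    explained_fraction: np.ndarray
    n_components_kept: int

    def transform(self, stack: EnvStack) -> EnvStack:
        """Project a stack onto the kept components, emitting PC rasters."""
        table, idx = stack.table(self.layer_names)
        z = (table - self.means) / self.sds
        scores = z @ self.loadings[: self.n_components_kept].T
        tmpl = stack.template
        layers = {}
        for k in range(self.n_components_kept):
            vals = np.full(tmpl.shape, np.nan)
            vals.ravel()[idx] = scores[:, k]
            layers[f"PC{k + 1}"] = tmpl.like(vals)
        return EnvStack(layers, scenario_id=stack.scenario_id)

    def to_dict(self) -> dict:
        return {
            "layer_names": self.layer_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_fraction": self.explained_fraction.tolist(),
            "n_components_kept": self.n_components_kept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAResult":
        return cls(
            layer_names=list(d["layer_names"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            loadings=np.asarray(d["loadings"]),
            explained_fraction=np.asarray(d["explained_fraction"]),
            n_components_kept=int(d["n_components_kept"]),
        )


def soil_pca(soil_stack: EnvStack, pca_var_target: float = 0.90) -> tuple[PCAResult, EnvStack]:
    """PCA of standardized soil layers, keeping the smallest number of
    components whose cumulative explained variance exceeds the target."""
    names = soil_stack.names
    if len(names) < 2:
        raise ValueError("need at least two soil layers")
    table, _ = soil_stack.table(names)
    sds = table.std(axis=0)
    constant = [n for n, s in zip(names, sds) if s == 0]
    if constant:
        raise ValueError(f"constant layers have zero variance: {constant}")
    means = table.mean(axis=0)
    z = (table - means) / sds
    pca = PCA()
    pca.fit(z)
    frac = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(frac), pca_var_target) + 1)
    k = min(k, len(frac))
    result = PCAResult(
        layer_names=names,
        means=means,
        sds=sds,
        loadings=pca.components_,
        explained_fraction=frac,
        n_components_kept=k,
    )
    return result, result.transform(soil_stack)


def average_gcms(gcm_stacks: list[EnvStack], scenario_id: str | None = None) -> EnvStack:
    """Cellwise mean of co-registered GCM stacks; nodata wherever any input
    is nodata."""
    if not gcm_stacks:
        raise ValueError("empty GCM list")
    names = gcm_stacks[0].names
    for s in gcm_stacks[1:]:
        if s.names != names:
            raise ValueError("GCM stacks must share layer names")
        if not s.template.same_registration(gcm_stacks[0].template):
            raise ValueError("GCM stacks must be co-registered")
    layers = {}
    for name in names:
        grids = [s.layers[name] for s in gcm_stacks]
        vals = np.mean([np.asarray(g.values, dtype=float) for g in grids], axis=0)
        valid = np.logical_and.reduce([g.valid_mask for g in grids])
        vals = np.where(valid, vals, np.nan)
        layers[name] = grids[0].like(vals)
    sid = scenario_id or gcm_stacks[0].scenario_id.split("-gcm")[0]
    return EnvStack(layers, scenario_id=sid)
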