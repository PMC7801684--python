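"""Lasso-penalized maximum-entropy presence-background model.

The model is the Gibbs distribution over background cells,

    P(x) = exp(sum_j beta_j f_j(x)) / Z,

fitted by minimizing the penalized point-process objective

    -mean_presence log P(x)  +  sum_j lambda_j |beta_j|,

where the per-feature penalty is

    lambda_j = rm * s_default(class, n_presence) * sd(f_j | background) / sqrt(n_presence).

``s_default`` follows the sample-size-interpolated per-class defaults of the
standard implementations and ships as an inspectable JSON data file.
Features are the classical classes — linear, quadratic, pairwise product,
and forward/reverse hinges at equally spaced interior knots — rescaled to
[0, 1] using background bounds.  Optimization is cyclic coordinate descent
with per-coordinate Newton steps, soft-thresholding, and step halving, which
makes the objective monotonically nonincreasing across sweeps.

Predictions come out either ``raw`` (normalized over the training
background) or ``cloglog``: ``1 − exp(−exp(H) · raw)`` with ``H`` the
entropy of the fitted raw distribution, a monotone rescaling interpretable
as a probability of presence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .core_rasters import EnvStack, RasterGrid

FEATURE_CLASS_MENU = ("L", "LQ", "H", "LQH", "LQPH")


def _load_reg_defaults() -> dict:
    with resources.files("dipsdm.data").joinpath("regularization_defaults.json").open() as fh:
        return json.load(fh)


_REG_DEFAULTS = _load_reg_defaults()


def default_reg_scalar(feature_kind: str, n_presence: int) -> float:
    """Interpolated default regularization scalar for a feature kind
    ("linear", "quadratic", "product" share one table; "hinge" its own)."""
    key = "hinge" if feature_kind == "hinge" else "linear_quadratic_product"
    tab = _REG_DEFAULTS[key]
    return float(np.interp(n_presence, tab["sample_sizes"], tab["betas"]))


@dataclass
class ModelConfig:
    feature_classes: str = "LQPH"
    reg_multiplier: float = 1.0
    n_hinge_knots: int = 10
    max_iterations: int = 200
    convergence_tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.feature_classes not in FEATURE_CLASS_MENU:
            raise ValueError(
                f"feature_classes must be one of {FEATURE_CLASS_MENU}, got {self.feature_classes!r}"
            )
        if self.reg_multiplier <= 0:
            raise ValueError("reg_multiplier must be positive")


@dataclass
class FeatureExpansion:
    """Feature definitions plus the background statistics needed to apply
    them anywhere (clamping bounds and [0,1] rescaling)."""

    covariate_names: list[str]
    feature_classes: str
    cov_min: np.ndarray
    cov_max: np.ndarray
    # each feature: (kind, i, j_or_knot); kind in {linear, quadratic, product,
    # hinge_fwd, hinge_rev}; for products j is the partner covariate index,
    # for hinges it is the knot value.
    features: list[tuple[str, int, float | int | None]]
    feat_min: np.ndarray | None = None
    feat_max: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return len(self.features)

    def raw_design(self, cov: np.ndarray) -> np.ndarray:
        """Unscaled feature matrix from a clamped covariate matrix."""
        x = np.clip(np.asarray(cov, dtype=float), self.cov_min, self.cov_max)
        cols = np.empty((len(x), self.n_features))
        for k, (kind, i, aux) in enumerate(self.features):
            xi = x[:, i]
            if kind == "linear":
                cols[:, k] = xi
            elif kind == "quadratic":
                cols[:, k] = xi**2
            elif kind == "product":
                cols[:, k] = xi * x[:, int(aux)]
            elif kind == "hinge_fwd":
                denom = self.cov_max[i] - aux
                cols[:, k] = np.maximum(0.0, (xi - aux) / denom)
            elif kind == "hinge_rev":
                denom = aux - self.cov_min[i]
                cols[:, k] = np.maximum(0.0, (aux - xi) / denom)
            else:  # pragma: no cover
                raise ValueError(kind)
        return cols

    def transform(self, cov: np.ndarray) -> np.ndarray:
        """[0,1]-rescaled design matrix (bounds from the background)."""
        cols = self.raw_design(cov)
        span = self.feat_max - self.feat_min
        span = np.where(span == 0, 1.0, span)
        return (cols - self.feat_min) / span

    def feature_kinds(self) -> list[str]:
        out = []
        for kind, _, _ in self.features:
            out.append("hinge" if kind.startswith("hinge") else kind)
        return out

    def to_dict(self) -> dict:
        return {
            "covariate_names": self.covariate_names,
            "feature_classes": self.feature_classes,
            "cov_min": self.cov_min.tolist(),
            "cov_max": self.cov_max.tolist(),
            "features": [[k, i, a] for k, i, a in self.features],
            "feat_min": self.feat_min.tolist(),
            "feat_max": self.feat_max.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureExpansion":
        return cls(
            covariate_names=list(d["covariate_names"]),
            feature_classes=d["feature_classes"],
            cov_min=np.asarray(d["cov_min"]),
            cov_max=np.asarray(d["cov_max"]),
            features=[(k, int(i), a) for k, i, a in d["features"]],
            feat_min=np.asarray(d["feat_min"]),
            feat_max=np.asarray(d["feat_max"]),
        )


def build_features(
    background_cov: np.ndarray,
    covariate_names: list[str],
    feature_classes: str = "LQPH",
    n_hinge_knots: int = 10,
) -> FeatureExpansion:
    """Construct the feature expansion from background covariate values.

    Constant covariates are dropped with a warning.  Hinge knots are
    ``n_hinge_knots`` equally spaced interior points of each covariate's
    background range, with a forward and a reverse hinge at each knot.
    """
    if feature_classes not in FEATURE_CLASS_MENU:
        raise ValueError(f"feature_classes must be one of {FEATURE_CLASS_MENU}")
    bg = np.asarray(background_cov, dtype=float)
    if bg.ndim != 2 or bg.shape[1] != len(covariate_names):
        raise ValueError("background covariates must be (n, n_covariates)")
    spans = bg.max(axis=0) - bg.min(axis=0)
    keep = spans > 0
    if not keep.all():
        dropped = [n for n, k in zip(covariate_names, keep) if not k]
        warnings.warn(f"dropping constant covariates: {dropped}")
        bg = bg[:, keep]
        covariate_names = [n for n, k in zip(covariate_names, keep) if k]
    if bg.shape[1] == 0:
        raise ValueError("no non-constant covariates left")
    cmin, cmax = bg.min(axis=0), bg.max(axis=0)
    n_cov = bg.shape[1]
    feats: list[tuple[str, int, float | int | None]] = []
    if "L" in feature_classes:
        feats += [("linear", i, None) for i in range(n_cov)]
    if "Q" in feature_classes:
        feats += [("quadratic", i, None) for i in range(n_cov)]
    if "P" in feature_classes:
        feats += [("product", i, j) for i in range(n_cov) for j in range(i + 1, n_cov)]
    if "H" in feature_classes:
        for i in range(n_cov):
            knots = np.linspace(cmin[i], cmax[i], n_hinge_knots + 2)[1:-1]
            for k in knots:
                feats.append(("hinge_fwd", i, float(k)))
                feats.append(("hinge_rev", i, float(k)))
    exp = FeatureExpansion(
        covariate_names=list(covariate_names),
        feature_classes=feature_classes,
        cov_min=cmin,
        cov_max=cmax,
        features=feats,
    )
    raw_bg = exp.raw_design(bg)
    exp.feat_min = raw_bg.min(axis=0)
    exp.feat_max = raw_bg.max(axis=0)
    return exp


@dataclass
class MaxEntModel:
    expansion: FeatureExpansion
    beta: np.ndarray
    alpha: float                 # log-normalizer: raw = exp(eta - alpha)
    entropy_H: float             # entropy of the fitted raw distribution
    config: ModelConfig
    converged: bool = True
    objective_path: list[float] = field(default_factory=list)

    def _eta(self, design: np.ndarray) -> np.ndarray:
        return design @ self.beta

    def predict_design(self, design: np.ndarray, output: str = "cloglog") -> np.ndarray:
        raw = np.exp(np.clip(self._eta(design) - self.alpha, -700.0, 700.0))
        if output == "raw":
            return raw
        if output == "cloglog":
            return np.clip(1.0 - np.exp(-np.exp(self.entropy_H) * raw), 0.0, 1.0)
        raise ValueError("output must be 'raw' or 'cloglog'")

    def predict_cov(self, cov: np.ndarray, output: str = "cloglog") -> np.ndarray:
        return self.predict_design(self.expansion.transform(cov), output)

    def to_dict(self) -> dict:
        return {
            "expansion": self.expansion.to_dict(),
            "beta": self.beta.tolist(),
            "alpha": self.alpha,
            "entropy_H": self.entropy_H,
            "config": vars(self.config).copy(),
            "converged": self.converged,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "MaxEntModel":
        return cls(
            expansion=FeatureExpansion.from_dict(d["expansion"]),
            beta=np.asarray(d["beta"]),
            alpha=float(d["alpha"]),
            entropy_H=float(d["entropy_H"]),
            config=ModelConfig(**d["config"]),
            converged=bool(d["converged"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MaxEntModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def penalized_objective(
    beta: np.ndarray,
    presence_design: np.ndarray,
    background_design: np.ndarray,
    penalties: np.ndarray,
) -> float:
    """Exact penalized negative mean presence log-probability (the quantity
    the fitter minimizes); exposed for oracle tests."""
    eta_bg = background_design @ beta
    m = eta_bg.max()
    log_z = m + np.log(np.exp(eta_bg - m).sum())
    return float(
        -np.mean(presence_design @ beta) + log_z + np.sum(penalties * np.abs(beta))
    )


def feature_penalties(
    expansion: FeatureExpansion,
    background_design: np.ndarray,
    n_presence: int,
    reg_multiplier: float,
) -> np.ndarray:
    sd = background_design.std(axis=0)
    kinds = expansion.feature_kinds()
    s = np.array([default_reg_scalar(k, n_presence) for k in kinds])
    return reg_multiplier * s * sd / np.sqrt(max(n_presence, 1))


def fit_maxent(
    presence_design: np.ndarray,
    background_design: np.ndarray,
    config: ModelConfig,
    expansion: FeatureExpansion,
) -> MaxEntModel:
    """Cyclic coordinate descent with soft-thresholding.

    Features with zero background variance are frozen at zero.  Each
    coordinate takes a Newton-style step on the smooth part, soft-thresholds
    against its lasso penalty, and halves the step until the exact objective
    does not increase; the sweep stops when the largest coefficient change
    falls below ``convergence_tol``.
    """
    F_p = np.asarray(presence_design, dtype=float)
    F_b = np.asarray(background_design, dtype=float)
    n_pres, n_feat = F_p.shape
    if n_pres < 2:
        raise ValueError("need at least two presences")
    if len(F_b) <= n_pres:
        raise ValueError("background must be larger than the presence set")
    lam = feature_penalties(expansion, F_b, n_pres, config.reg_multiplier)
    active = F_b.std(axis=0) > 0
    mean_p = F_p.mean(axis=0)

    beta = np.zeros(n_feat)
    eta = np.zeros(len(F_b))

    def _lse(v: np.ndarray) -> float:
        m = v.max()
        return float(m + np.log(np.exp(v - m).sum()))

    # obj is maintained incrementally: linear presence term + log Z + penalty
    lin = 0.0                      # -mean_p @ beta
    pen = 0.0                      # sum lam |beta|
    log_z = _lse(eta)
    obj = lin + log_z + pen
    path = [obj]
    converged = False
    for _ in range(config.max_iterations):
        max_delta = 0.0
        for j in range(n_feat):
            if not active[j]:
                continue
            w = np.exp(eta - eta.max())
            p = w / w.sum()
            fj = F_b[:, j]
            e = float(p @ fj)
            var = float(p @ (fj - e) ** 2)
            if var <= 1e-12:
                continue
            grad = e - mean_p[j]
            b_new = beta[j] - grad / var
            b_new = np.sign(b_new) * max(0.0, abs(b_new) - lam[j] / var)
            delta = b_new - beta[j]
            if delta == 0.0:
                continue
            # step halving against the exact (incrementally evaluated) objective
            accepted = False
            for _half in range(30):
                eta_c = eta + delta * fj
                log_z_c = _lse(eta_c)
                lin_c = lin - mean_p[j] * delta
                pen_c = pen + lam[j] * (abs(beta[j] + delta) - abs(beta[j]))
                cand_obj = lin_c + log_z_c + pen_c
                if cand_obj <= obj + 1e-12:
                    accepted = True
                    break
                delta *= 0.5
            if not accepted:
                continue
            eta = eta_c
            beta[j] += delta
            lin, pen, log_z, obj = lin_c, pen_c, log_z_c, cand_obj
            max_delta = max(max_delta, abs(delta))
        path.append(obj)
        # stop on stationary coefficients or a stalled objective
        if max_delta < config.convergence_tol or (
            len(path) >= 2 and path[-2] - path[-1] < 1e-10 * max(1.0, abs(path[-1]))
        ):
            converged = True
            break
    if not converged:
        warnings.warn("coordinate descent hit max_iterations without converging")

    eta_bg = F_b @ beta
    m = eta_bg.max()
    alpha = float(m + np.log(np.exp(eta_bg - m).sum()))
    raw = np.exp(eta_bg - alpha)
    nz = raw > 0
    entropy = float(-(raw[nz] * np.log(raw[nz])).sum())
    return MaxEntModel(
        expansion=expansion,
        beta=beta,
        alpha=alpha,
        entropy_H=entropy,
        config=config,
        converged=converged,
        objective_path=path,
    )


def fit_from_covariates(
    presence_cov: np.ndarray,
    background_cov: np.ndarray,
    covariate_names: list[str],
    config: ModelConfig,
) -> MaxEntModel:
    """Convenience wrapper: build the expansion from the background, then fit."""
    expansion = build_features(
        background_cov, covariate_names, config.feature_classes, config.n_hinge_knots
    )
    F_b = expansion.transform(background_cov)
    F_p = expansion.transform(presence_cov)
    return fit_maxent(F_p, F_b, config, expansion)


def predict(model: MaxEntModel, stack: EnvStack, output: str = "cloglog") -> RasterGrid:
    """Project the model over a scenario stack, clamping covariates to the
    training range.  Raw output is normalized over the training background,
    so summing it over that background gives 1."""
    missing = [n for n in model.expansion.covariate_names if n not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing covariate layers: {missing}")
    cov, idx = stack.subset(model.expansion.covariate_names).table()
    pred = model.predict_cov(cov, output=output)
    tmpl = stack.template
    vals = np.full(tmpl.shape, np.nan)
    vals.ravel()[idx] = pred
    return tmpl.like(vals)
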