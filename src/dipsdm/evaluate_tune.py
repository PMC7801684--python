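"""Spatial cross-validation, discrimination metrics, tuning and gates.

Model selection follows an omission-rate-first rule: over a grid of feature
classes and regularization multipliers, candidates are cross-validated with
either 'block' partitioning (four geographic bins of near-equal presence
counts, for n > 25 presences) or jackknife (leave-one-presence-out, n <= 25);
the candidate with the lowest mean test omission rate at the lowest presence
threshold wins, with mean test AUC breaking ties.  The selected
configuration is refit on all presences and the full background, then gated
on AUC >= 0.75, TSS >= 0.45 and omission at the maxSSS threshold <= 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_rasters import EnvStack, OccurrenceSet
from .maxent import MaxEntModel, ModelConfig, build_features, fit_maxent

# The 19-multiplier default grid: a ratio-0.75 geometric progression of
# eight values below 1, plus 0.5 steps from the default 1.0 up to 6.0.
DEFAULT_RM_GRID = tuple(
    sorted([0.75**k for k in range(1, 9)] + [1.0 + 0.5 * i for i in range(11)])
)
DEFAULT_FC_MENU = ("L", "LQ", "H", "LQH", "LQPH")


@dataclass
class PartitionScheme:
    kind: str                      # "block4" or "jackknife"
    presence_folds: np.ndarray
    background_folds: np.ndarray | None  # None => full background every fold
    n_folds: int


def make_partitions(
    occ: OccurrenceSet,
    background_points: np.ndarray,
    threshold_n: int = 25,
) -> PartitionScheme:
    """Spatial 'block' partitioning (n > threshold) or jackknife (n <=).

    Block partitioning splits presences at their median x, then each half at
    its own median y, giving four bins whose presence counts differ by at
    most one; background points inherit the same geographic boundaries.
    """
    pts = occ.points
    n = len(pts)
    if n < 2:
        raise ValueError("need at least two presences to partition")
    if n <= threshold_n or n < 4:  # block4 needs one presence per bin
        return PartitionScheme("jackknife", np.arange(n), None, n)

    bg = np.atleast_2d(np.asarray(background_points, dtype=float))
    folds = np.empty(n, dtype=int)
    order_x = np.lexsort((np.arange(n), pts[:, 0]))
    n_left = (n + 1) // 2
    left, right = order_x[:n_left], order_x[n_left:]
    x_split = 0.5 * (pts[left, 0].max() + pts[right, 0].min())

    y_splits = {}
    for side, (members, base) in enumerate([(left, 0), (right, 2)]):
        order_y = members[np.lexsort((members, pts[members, 1]))]
        n_low = (len(members) + 1) // 2
        low, high = order_y[:n_low], order_y[n_low:]
        folds[low] = base
        folds[high] = base + 1
        y_splits[side] = 0.5 * (pts[low, 1].max() + pts[high, 1].min())

    bg_left = bg[:, 0] <= x_split
    bg_folds = np.where(
        bg_left,
        np.where(bg[:, 1] <= y_splits[0], 0, 1),
        np.where(bg[:, 1] <= y_splits[1], 2, 3),
    )
    return PartitionScheme("block4", folds, bg_folds, 4)


def auc_pb(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Presence-background AUC in its Mann-Whitney form: the fraction of
    (presence, background) pairs ranked correctly, ties counting one half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("scores must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(b)))


def omission_rate(
    train_presence_scores: np.ndarray,
    test_presence_scores: np.ndarray,
    threshold: float | None = None,
) -> float:
    """Fraction of test presences scoring strictly below the threshold
    (default: the lowest training-presence score, LPT)."""
    train = np.asarray(train_presence_scores, dtype=float)
    test = np.asarray(test_presence_scores, dtype=float)
    if len(train) == 0:
        raise ValueError("training scores must be nonempty")
    if len(test) == 0:
        raise ValueError("test scores must be nonempty")
    tau = float(train.min()) if threshold is None else float(threshold)
    return float(np.mean(test < tau))


def maxsss(
    presence_scores: np.ndarray, background_scores: np.ndarray
) -> tuple[float, float, float, float]:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the unique pooled scores; sensitivity counts presences
    >= tau, specificity counts background < tau; ties resolve to the
    smallest threshold.  Returns (tau, tss, sensitivity, specificity).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("scores must be nonempty")
    taus = np.unique(np.concatenate([p, b]))
    sens = (p[None, :] >= taus[:, None]).mean(axis=1)
    spec = (b[None, :] < taus[:, None]).mean(axis=1)
    k = int(np.argmax(sens + spec))  # first max => smallest tau
    return float(taus[k]), float(sens[k] + spec[k] - 1.0), float(sens[k]), float(spec[k])


@dataclass
class EvalReport:
    auc: float
    or_lpt: float
    or_maxsss: float
    tss: float
    maxsss_threshold: float


@dataclass
class GateDecision:
    accept: bool
    reasons: list[str] = field(default_factory=list)


def gate_model(
    report: EvalReport,
    min_auc: float = 0.75,
    min_tss: float = 0.45,
    max_or: float = 0.25,
) -> GateDecision:
    """Reject iff AUC < 0.75, TSS < 0.45 or OR(maxSSS) > 0.25 (strict)."""
    reasons = []
    if report.auc < min_auc:
        reasons.append(f"AUC {report.auc:.3f} < {min_auc}")
    if report.tss < min_tss:
        reasons.append(f"TSS {report.tss:.3f} < {min_tss}")
    if report.or_maxsss > max_or:
        reasons.append(f"OR {report.or_maxsss:.3f} > {max_or}")
    return GateDecision(accept=not reasons, reasons=reasons)


def select_candidate(grid: pd.DataFrame) -> pd.Series:
    """Omission-rate-first selection: the row with the lowest mean test OR,
    ties broken by highest mean test AUC, then by grid order."""
    return grid.sort_values(
        by=["mean_test_or", "mean_test_auc"], ascending=[True, False], kind="stable"
    ).iloc[0]


@dataclass
class TuningResult:
    grid: pd.DataFrame             # feature_classes, rm, mean_test_or, mean_test_auc
    selected_fc: str
    selected_rm: float
    model: MaxEntModel
    report: EvalReport
    gate: GateDecision


def _fold_scores(
    pres_cov: np.ndarray,
    bg_cov: np.ndarray,
    names: list[str],
    partition: PartitionScheme,
    fc: str,
    rm: float,
    n_hinge_knots: int,
    max_iterations: int,
    convergence_tol: float,
) -> tuple[float, float]:
    """Mean cross-validated (omission rate, AUC) for one candidate."""
    ors, aucs = [], []
    for k in range(partition.n_folds):
        tr_p = pres_cov[partition.presence_folds != k]
        te_p = pres_cov[partition.presence_folds == k]
        if len(te_p) == 0 or len(tr_p) < 2:
            continue
        if partition.background_folds is None:
            tr_b = te_b = bg_cov
        else:
            tr_b = bg_cov[partition.background_folds != k]
            te_b = bg_cov[partition.background_folds == k]
            if len(te_b) == 0 or len(tr_b) <= len(tr_p):
                tr_b = te_b = bg_cov
        config = ModelConfig(
            feature_classes=fc,
            reg_multiplier=rm,
            n_hinge_knots=n_hinge_knots,
            max_iterations=max_iterations,
            convergence_tol=convergence_tol,
        )
        expansion = build_features(tr_b, names, fc, n_hinge_knots)
        model = fit_maxent(
            expansion.transform(tr_p), expansion.transform(tr_b), config, expansion
        )
        s_tr = model.predict_cov(tr_p)
        s_te = model.predict_cov(te_p)
        s_bg = model.predict_cov(te_b)
        ors.append(omission_rate(s_tr, s_te))
        aucs.append(auc_pb(s_te, s_bg))
    if not ors:
        raise RuntimeError("no usable folds")
    return float(np.mean(ors)), float(np.mean(aucs))


def tune_model(
    occ: OccurrenceSet,
    background_points: np.ndarray,
    stack: EnvStack,
    covariate_names: list[str] | None = None,
    rm_grid: tuple[float, ...] = DEFAULT_RM_GRID,
    fc_menu: tuple[str, ...] = DEFAULT_FC_MENU,
    partition: PartitionScheme | None = None,
    n_hinge_knots: int = 10,
    max_iterations: int = 200,
    convergence_tol: float = 1e-5,
) -> TuningResult:
    """Evaluate the full candidate grid and refit the winner.

    Selection: lowest mean cross-validated omission rate at the lowest
    presence threshold; ties broken by highest mean test AUC, then by grid
    order.  The final report evaluates the refit model on all presences and
    the full background.
    """
    names = covariate_names or stack.names
    pres_cov = stack.values_at(occ.points, names)
    bg_cov = stack.values_at(background_points, names)
    if partition is None:
        partition = make_partitions(occ, background_points)

    rows = []
    for fc in fc_menu:
        for rm in rm_grid:
            mean_or, mean_auc = _fold_scores(
                pres_cov, bg_cov, names, partition, fc, rm,
                n_hinge_knots, max_iterations, convergence_tol,
            )
            rows.append({"feature_classes": fc, "rm": rm,
                         "mean_test_or": mean_or, "mean_test_auc": mean_auc})
    grid = pd.DataFrame(rows)
    best = select_candidate(grid)
    fc_sel, rm_sel = str(best["feature_classes"]), float(best["rm"])

    config = ModelConfig(
        feature_classes=fc_sel,
        reg_multiplier=rm_sel,
        n_hinge_knots=n_hinge_knots,
        max_iterations=max_iterations,
        convergence_tol=convergence_tol,
    )
    expansion = build_features(bg_cov, names, fc_sel, n_hinge_knots)
    model = fit_maxent(
        expansion.transform(pres_cov), expansion.transform(bg_cov), config, expansion
    )
    s_p = model.predict_cov(pres_cov)
    s_b = model.predict_cov(bg_cov)
    tau, tss, sens, _spec = maxsss(s_p, s_b)
    report = EvalReport(
        auc=auc_pb(s_p, s_b),
        or_lpt=float(best["mean_test_or"]),
        or_maxsss=1.0 - sens,
        tss=tss,
        maxsss_threshold=tau,
    )
    return TuningResult(
        grid=grid,
        selected_fc=fc_sel,
        selected_rm=rm_sel,
        model=model,
        report=report,
        gate=gate_model(report),
    )
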