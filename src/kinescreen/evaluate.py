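"""LOSO-validated classification of movement feature tables.

Pipeline, in order: PCA keeping 95% of the variance (fit globally by
default, per fold optionally), then leave-one-subject-out cross-validation
in which each fold's training block is normalised by its own median/MAD,
a (cost, gamma) pair for the Gaussian C-SVM is chosen on the training block
over a 7x7 log grid, and a nonlinear SVM-RFE with correlation bias
reduction ranks the PCA features. Median feature ranks across folds define
nested candidate subsets; the feature count is then chosen to maximise the
LOSO Cohen's kappa (ties: fewer features, then higher accuracy), with each
fold predicting under its own (cost, gamma). An alternative view that
optimises a single global (cost, gamma) pair jointly with the feature
count over the whole LOSO surface is recorded alongside; it is kept out of
the headline metrics because selecting over the full grid on the same LOSO
predictions inflates kappa substantially under a null signal.

The ASD group is the positive class: TPR is sensitivity toward ASD, TNR
specificity toward TD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._svm import fit_predict_precomputed
from .features import FeatureTable
from .preprocessing import ExplainedVariancePCA, RobustMedianScaler, log_grid
from .rfe import KernelSVMRFE


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionMetrics:
    """Two-class confusion counts and the derived performance measures."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    tpr: float
    tnr: float
    kappa: float


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ConfusionMetrics:
    """Accuracy, TPR, TNR and Cohen's kappa from confusion counts.

    Kappa uses the standard two-rater chance correction,
    ``(p_o - p_e) / (1 - p_e)`` with ``p_e`` from the marginal products.
    An empty class leaves the corresponding rate NaN; kappa is still
    computed whenever its denominator is non-zero.
    """
    for v in (tp, fn, tn, fp):
        if v < 0 or v != int(v):
            raise ValueError("confusion counts must be non-negative integers")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("confusion counts sum to zero")
    accuracy = (tp + tn) / n
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    tnr = tn / (tn + fp) if (tn + fp) else float("nan")
    p_o = accuracy
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else float("nan")
    return ConfusionMetrics(tp, fn, tn, fp, accuracy, tpr, tnr, kappa)


def counts_from_rates(tpr_pct: float, tnr_pct: float, n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Reconstruct integer confusion counts from printed class-wise rates.

    Given TPR and TNR as percentages plus the group sizes, the underlying
    counts are ``tp = round(tpr * n_pos)`` and ``tn = round(tnr * n_neg)``
    (rates printed to two decimals identify the counts uniquely for group
    sizes of this order). Returns ``(tp, fn, tn, fp)``.
    """
    tp = round(tpr_pct / 100.0 * n_pos)
    tn = round(tnr_pct / 100.0 * n_neg)
    return tp, n_pos - tp, tn, n_neg - tn


def metrics_from_rates(tpr_pct: float, tnr_pct: float, n_pos: int = 22, n_neg: int = 25) -> ConfusionMetrics:
    """Full metric set implied by printed TPR/TNR and the group sizes."""
    return confusion_metrics(*counts_from_rates(tpr_pct, tnr_pct, n_pos, n_neg))


# ---------------------------------------------------------------------------
# Configuration and result containers


@dataclass
class ClassifierConfig:
    """Hyperparameters of the LOSO classification stack."""

    variance_fraction: float = 0.95
    grid_lo: float = 0.1
    grid_hi: float = 1000.0
    grid_k: int = 7
    pca_scope: str = "global"  # "global" (replication default) or "per-fold"
    rfe: bool = True
    cbr: bool = True
    corr_threshold: float = 0.9
    max_features: int | None = None
    inner_cv_splits: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_fraction <= 1.0:
            raise ValueError("variance_fraction must lie in (0, 1]")
        if self.pca_scope not in ("global", "per-fold"):
            raise ValueError("pca_scope must be 'global' or 'per-fold'")
        if not 0.0 < self.corr_threshold:
            raise ValueError("corr_threshold must be positive")

    @property
    def grid(self) -> np.ndarray:
        return log_grid(self.grid_lo, self.grid_hi, self.grid_k)


@dataclass
class FoldResult:
    """Outcome of one leave-one-subject-out fold."""

    subject_id: str
    y_true: int
    y_pred: int
    chosen_cost: float
    chosen_gamma: float
    ranking: np.ndarray


@dataclass
class EvaluationReport:
    """LOSO evaluation of one joint-set x stimulus-set model.

    The primary ``metrics`` come from the nested view: each fold predicts
    with the (cost, gamma) chosen on its own training block and only the
    feature count is kappa-optimised across the LOSO surface. The
    alternative single-global-pair view — every (top-k, cost, gamma)
    combination scored by LOSO kappa, which carries far more selection
    optimism — is recorded in the ``grid_*`` fields.
    """

    joint_set: str
    segment_set: str
    metrics: ConfusionMetrics
    n_selected: int
    n_pca: int
    median_ranks: np.ndarray
    fold_results: list[FoldResult] = field(default_factory=list)
    grid_metrics: ConfusionMetrics | None = None
    grid_n_selected: int | None = None
    grid_cost: float | None = None
    grid_gamma: float | None = None

    @property
    def n_folds(self) -> int:
        return len(self.fold_results)

    def to_row(self) -> dict:
        m = self.metrics
        return {
            "stimuli": self.segment_set,
            "joints": self.joint_set,
            "accuracy_pct": round(100 * m.accuracy, 2),
            "tpr_pct": round(100 * m.tpr, 2) if not math.isnan(m.tpr) else float("nan"),
            "tnr_pct": round(100 * m.tnr, 2) if not math.isnan(m.tnr) else float("nan"),
            "kappa": round(m.kappa, 2),
            "features_selected": f"{self.n_selected}/{self.n_pca}",
            "grid_cost": self.grid_cost,
            "grid_gamma": self.grid_gamma,
        }


# ---------------------------------------------------------------------------
# LOSO machinery


def _sq_dists(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Per-feature squared differences, shape (len(A), len(B), p)."""
    B = A if B is None else B
    return (A[:, None, :] - B[None, :, :]) ** 2


def _select_grid_point(Z: np.ndarray, y: np.ndarray, grid: np.ndarray,
                       n_splits: int, seed: int) -> tuple[float, float]:
    """Pick (cost, gamma) by stratified k-fold accuracy on a training block.

    Ties favour the smaller cost, then the smaller gamma, so the choice is
    deterministic.
    """
    n_splits = min(n_splits, int(np.bincount(y).min()))
    if n_splits < 2:
        return float(grid[len(grid) // 2]), float(grid[len(grid) // 2])
    D = _sq_dists(Z).sum(axis=2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, y))
    best_key, best = None, None
    for g in grid:
        K = np.exp(-g * D)
        for c in grid:
            correct = total = 0
            for tr, va in splits:
                pred = fit_predict_precomputed(K[np.ix_(tr, tr)], y[tr], c, K[np.ix_(va, tr)])
                correct += int((pred == y[va]).sum())
                total += len(va)
            key = (correct / total, -c, -g)
            if best_key is None or key > best_key:
                best_key, best = key, (float(c), float(g))
    return best


def loso_evaluate(
    table: FeatureTable,
    config: ClassifierConfig | None = None,
    joint_set: str = "custom",
    segment_set: str = "custom",
) -> EvaluationReport:
    """Run the full LOSO classification stack on a feature table.

    Returns the kappa-optimised :class:`EvaluationReport`; the per-fold
    RFE rankings and the (cost, gamma) chosen inside each fold are kept in
    ``fold_results`` alongside the globally selected pair.
    """
    config = config or ClassifierConfig()
    X, y = table.X, table.y
    subjects = table.subjects
    n = len(y)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("LOSO evaluation requires at least 2 subjects per class")

    grid = config.grid
    if config.pca_scope == "global":
        Z_global = ExplainedVariancePCA(config.variance_fraction).fit_transform(X)
    else:
        Z_global = None

    # Pass 1: per-fold normalisation, grid choice and RFE ranking
    fold_train: list[np.ndarray] = []
    fold_test: list[np.ndarray] = []
    fold_pairs: list[tuple[float, float]] = []
    rankings: list[np.ndarray] = []
    for i in range(n):
        train = np.arange(n) != i
        if Z_global is not None:
            Zt_raw, Zv_raw = Z_global[train], Z_global[~train]
        else:
            pca = ExplainedVariancePCA(config.variance_fraction).fit(X[train])
            Zt_raw, Zv_raw = pca.transform(X[train]), pca.transform(X[~train])
        scaler = RobustMedianScaler().fit(Zt_raw)
        Zt, Zv = scaler.transform(Zt_raw), scaler.transform(Zv_raw)
        c_i, g_i = _select_grid_point(Zt, y[train], grid,
                                      config.inner_cv_splits, config.seed + i)
        if config.rfe and Zt.shape[1] > 1:
            ranking = KernelSVMRFE(C=c_i, gamma=g_i, cbr=config.cbr,
                                   corr_threshold=config.corr_threshold).fit(Zt, y[train]).ranking_
        else:
            ranking = np.arange(1, Zt.shape[1] + 1)
        fold_train.append(Zt)
        fold_test.append(Zv[0])
        fold_pairs.append((c_i, g_i))
        rankings.append(ranking)

    p_common = min(r.shape[0] for r in rankings)
    rank_matrix = np.stack([r[:p_common] for r in rankings])
    median_ranks = np.median(rank_matrix, axis=0)
    order = np.argsort(median_ranks, kind="stable")
    n_pca = p_common
    k_max = n_pca if config.max_features is None else min(config.max_features, n_pca)

    # Pass 2: score every (top-k, cost, gamma) combination by LOSO kappa.
    # Squared distances accumulate over the nested feature subsets, so each
    # fold computes its per-feature difference tensors once.
    d_train = [_sq_dists(Zt[:, order]) for Zt in fold_train]
    d_test = [_sq_dists(Zv[None, order], Zt[:, order])[0] for Zv, Zt in zip(fold_test, fold_train)]
    preds = np.empty((k_max, len(grid), len(grid), n), dtype=int)
    Dtr = [np.zeros((Zt.shape[0], Zt.shape[0])) for Zt in fold_train]
    Dte = [np.zeros(Zt.shape[0]) for Zt in fold_train]
    y_train_by_fold = [np.delete(y, i) for i in range(n)]
    for ki in range(k_max):
        for i in range(n):
            Dtr[i] = Dtr[i] + d_train[i][:, :, ki]
            Dte[i] = Dte[i] + d_test[i][:, ki]
            for gi, g in enumerate(grid):
                Ktr = np.exp(-g * Dtr[i])
                kte = np.exp(-g * Dte[i])[None, :]
                for ci, c in enumerate(grid):
                    preds[ki, gi, ci, i] = fit_predict_precomputed(Ktr, y_train_by_fold[i], c, kte)[0]

    def _metrics_for(pr: np.ndarray) -> ConfusionMetrics:
        tp = int(((pr == 1) & (y == 1)).sum())
        fn = int(((pr == 0) & (y == 1)).sum())
        tn = int(((pr == 0) & (y == 0)).sum())
        fp = int(((pr == 1) & (y == 0)).sum())
        return confusion_metrics(tp, fn, tn, fp)

    # primary view: fold-specific (cost, gamma), only the feature count k
    # is optimised (ties: fewer features, then higher accuracy)
    grid_index = {float(v): idx for idx, v in enumerate(grid)}
    best_key, best = None, None
    for ki in range(k_max):
        pr = np.array([
            preds[ki, grid_index[fold_pairs[i][1]], grid_index[fold_pairs[i][0]], i]
            for i in range(n)
        ])
        m = _metrics_for(pr)
        key = (m.kappa, -(ki + 1), m.accuracy)
        if best_key is None or key > best_key:
            best_key, best = key, (ki + 1, m, pr)
    k_sel, metrics, predictions = best

    # recorded secondary view: one global (cost, gamma) over the whole grid
    # (ties: fewer features, higher accuracy, smaller cost, smaller gamma)
    g_best_key, g_best = None, None
    for ki in range(k_max):
        for gi, g in enumerate(grid):
            for ci, c in enumerate(grid):
                m = _metrics_for(preds[ki, gi, ci])
                key = (m.kappa, -(ki + 1), m.accuracy, -c, -g)
                if g_best_key is None or key > g_best_key:
                    g_best_key, g_best = key, (ki + 1, float(c), float(g), m)
    folds = [
        FoldResult(subject_id=subjects[i], y_true=int(y[i]), y_pred=int(predictions[i]),
                   chosen_cost=fold_pairs[i][0], chosen_gamma=fold_pairs[i][1],
                   ranking=rankings[i])
        for i in range(n)
    ]
    return EvaluationReport(
        joint_set=joint_set,
        segment_set=segment_set,
        metrics=metrics,
        n_selected=k_sel,
        n_pca=n_pca,
        median_ranks=median_ranks,
        fold_results=folds,
        grid_n_selected=g_best[0],
        grid_cost=g_best[1],
        grid_gamma=g_best[2],
        grid_metrics=g_best[3],
    )
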