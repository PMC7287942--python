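"""Nonlinear SVM recursive feature elimination with correlation bias reduction.

Plain RFE for a kernel SVM scores feature ``i`` by the change in the dual
objective when the kernel is recomputed without that feature, holding the
dual coefficients fixed:

    DJ(i) = 1/2 a' H a  -  1/2 a' H(-i) a

where ``H_{st} = y_s y_t K(x_s, x_t)`` over the support vectors and
``H(-i)`` uses the kernel evaluated without feature ``i``. The feature with
the smallest objective change is eliminated each round; rank 1 is the
feature eliminated last.

Highly inter-correlated features mask each other under this criterion:
removing one leaves near-identical information in its partners, so the
whole correlated set receives deceptively small scores and can be discarded
even when jointly informative. Correlation bias reduction (CBR) counters
this by grouping features whose pairwise |Pearson r| reaches a threshold
and scoring every member by the objective change from removing the *entire
group*; ties within a group are broken by the member's individual score.

For the Gaussian kernel ``K(x, z) = exp(-gamma ||x - z||^2)`` removing a
feature subset S factorises as ``K(-S) = K * exp(gamma * sum_{i in S}
(x_i - z_i)^2)``, so each round needs a single SVM fit plus cheap kernel
updates.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_X_y, check_is_fitted

from ._svm import fit_precomputed


def _correlation_groups(X: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the |Pearson r| >= threshold graph."""
    p = X.shape[1]
    if p == 1 or threshold > 1.0:
        return [[i] for i in range(p)]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate with nothing
    adj = np.abs(corr) >= threshold
    seen = np.zeros(p, dtype=bool)
    groups = []
    for start in range(p):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adj[u] & ~seen):
                seen[v] = True
                stack.append(v)
        groups.append(sorted(comp))
    return groups


class KernelSVMRFE(BaseEstimator):
    """Gaussian-kernel SVM-RFE ranking with optional correlation bias reduction.

    Parameters
    ----------
    C, gamma : float
        Cost and Gaussian-kernel width of the SVM trained each round.
    corr_threshold : float
        |Pearson r| at or above which features are grouped for CBR. A value
        above 1 disables grouping, reducing the procedure to plain
        nonlinear SVM-RFE.
    cbr : bool
        Whether correlation bias reduction is applied.

    Attributes
    ----------
    ranking_ : ndarray of shape (n_features,)
        Permutation of ``1..n_features``; 1 = eliminated last (most
        important).
    elimination_order_ : list of int
        Feature indices in elimination order (first eliminated first).
    """

    def __init__(self, C: float = 10.0, gamma: float = 1.0,
                 corr_threshold: float = 0.9, cbr: bool = True):
        self.C = C
        self.gamma = gamma
        self.corr_threshold = corr_threshold
        self.cbr = cbr

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("SVM-RFE requires both classes in y")
        p = X.shape[1]
        if p < 2:
            raise ValueError("SVM-RFE requires at least 2 features")

        active = list(range(p))
        ranking = np.zeros(p, dtype=int)
        order: list[int] = []
        next_rank = p
        while len(active) > 1:
            crit = self._round_criteria(X[:, active], y)
            # eliminate the smallest (group criterion, individual criterion,
            # then lowest original index) — fully deterministic
            pos = min(range(len(active)), key=lambda i: (crit[0][i], crit[1][i], active[i]))
            feat = active.pop(pos)
            ranking[feat] = next_rank
            order.append(feat)
            next_rank -= 1
        ranking[active[0]] = 1
        order.append(active[0])

        self.ranking_ = ranking
        self.elimination_order_ = order
        self.n_features_in_ = p
        return self

    def _round_criteria(self, Xa: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Group-aware and individual DJ criteria for the active features."""
        n_active = Xa.shape[1]
        # per-feature squared-difference matrices; gamma is applied by hand
        # so one Gram matrix serves both the fit and the criteria
        d_all = (Xa[:, None, :] - Xa[None, :, :]) ** 2  # (n, n, p_active)
        K_all = np.exp(-self.gamma * d_all.sum(axis=2))
        sv, a, _ = fit_precomputed(K_all, y, self.C)
        # a holds y_s * alpha_s; the label signs fold into a' K a and the
        # overall sign of a is irrelevant to the quadratic forms below
        d = d_all[np.ix_(sv, sv)]
        K = K_all[np.ix_(sv, sv)]
        D = d.sum(axis=2)
        J = a @ K @ a

        def dj(subset: list[int]) -> float:
            # K without the subset's features; computed from the distance
            # difference (>= 0) so the exponent never overflows
            K_minus = np.exp(-self.gamma * (D - d[:, :, subset].sum(axis=2)))
            return 0.5 * J - 0.5 * (a @ K_minus @ a)

        individual = np.array([dj([i]) for i in range(n_active)])
        if self.cbr:
            grouped = individual.copy()
            for group in _correlation_groups(Xa, self.corr_threshold):
                if len(group) > 1:
                    g_val = dj(group)
                    for i in group:
                        grouped[i] = g_val
        else:
            grouped = individual
        return grouped, individual

    def top_features(self, k: int) -> np.ndarray:
        """Indices of the ``k`` best-ranked features, best first."""
        check_is_fitted(self, "ranking_")
        return np.argsort(self.ranking_, kind="stable")[:k]
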