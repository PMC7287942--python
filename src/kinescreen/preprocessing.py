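"""Preprocessing estimators for the classification stack.

Both transformers follow the scikit-learn estimator contract (``fit`` /
``transform``, fitted attributes with trailing underscores) so they compose
with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted


def log_grid(lo: float = 0.1, hi: float = 1000.0, k: int = 7) -> np.ndarray:
    """``k`` logarithmically spaced values from ``lo`` to ``hi`` inclusive.

    The default 7-point grid on [0.1, 1000] serves both the SVM cost and the
    Gaussian-kernel gamma (geometric midpoint 10).
    """
    if lo <= 0:
        raise ValueError("lo must be positive")
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if k < 2:
        raise ValueError("k must be at least 2")
    return np.geomspace(lo, hi, k)


class RobustMedianScaler(TransformerMixin, BaseEstimator):
    """Center by the median and scale by the raw median absolute deviation.

    The MAD is ``median(|x - median(x)|)`` without the 1.4826 normal-
    consistency factor. Columns whose MAD is zero are passed through
    centered only (scale 1) and flagged in ``zero_scale_mask_``.

    Attributes
    ----------
    center_ : ndarray of shape (n_features,)
        Per-column training median.
    scale_ : ndarray of shape (n_features,)
        Per-column training MAD, with zeros replaced by 1.
    zero_scale_mask_ : ndarray of bool
        True where the training MAD was exactly zero.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.center_ = np.median(X, axis=0)
        mad = np.median(np.abs(X - self.center_), axis=0)
        self.zero_scale_mask_ = mad == 0
        self.scale_ = np.where(self.zero_scale_mask_, 1.0, mad)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "center_")
        X = check_array(X)
        return (X - self.center_) / self.scale_


class ExplainedVariancePCA(TransformerMixin, BaseEstimator):
    """PCA keeping the fewest components reaching a variance fraction.

    Components are ordered by explained variance and truncated at the
    smallest count whose cumulative explained-variance ratio reaches
    ``variance_fraction`` (default 0.95). Component signs follow a
    deterministic convention: the loading of largest magnitude in each
    component is made positive, so repeated fits on the same data produce
    identical score matrices.
    """

    def __init__(self, variance_fraction: float = 0.95):
        self.variance_fraction = variance_fraction

    def fit(self, X, y=None):
        if not 0.0 < self.variance_fraction <= 1.0:
            raise ValueError("variance_fraction must lie in (0, 1]")
        X = check_array(X, ensure_min_samples=2)
        if np.all(X == X[0]):
            raise ValueError("cannot run PCA on an all-constant feature matrix")
        pca = PCA(n_components=None, svd_solver="full").fit(X)
        ratios = pca.explained_variance_ratio_
        cum = np.cumsum(ratios)
        # float-tolerant threshold so variance_fraction=1.0 keeps full rank
        n_comp = int(np.searchsorted(cum, self.variance_fraction - 1e-12) + 1)
        n_comp = min(n_comp, len(ratios))
        components = pca.components_[:n_comp].copy()
        flip = np.sign(components[np.arange(n_comp), np.argmax(np.abs(components), axis=1)])
        flip[flip == 0] = 1.0
        components *= flip[:, None]
        self.mean_ = pca.mean_
        self.components_ = components
        self.explained_variance_ = pca.explained_variance_[:n_comp]
        self.explained_variance_ratio_ = ratios[:n_comp]
        self.n_components_ = n_comp
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X)
        return (X - self.mean_) @ self.components_.T
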