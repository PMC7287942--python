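"""Thin fast path around libsvm for precomputed-kernel C-SVC fits.

The LOSO grid/feature search fits tens of thousands of tiny SVMs (n <= 47),
where :class:`sklearn.svm.SVC`'s per-call validation dominates the run
time. When scikit-learn's low-level libsvm binding is importable we call it
directly; otherwise we fall back to ``SVC``. Both paths return the same
``(support, coef, intercept)`` triple in the *raw libsvm sign convention*,
under which the decision value for a test row is
``k_test[support] @ coef + intercept`` and class 1 is predicted when the
decision is <= 0. The equivalence of the two paths is asserted by a unit
test on random problems.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised indirectly
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except ImportError:  # pragma: no cover
    _libsvm = None
    _HAVE_LIBSVM = False

from sklearn.svm import SVC


def fit_precomputed(K: np.ndarray, y01: np.ndarray, C: float):
    """Fit a C-SVC on a precomputed kernel; labels must be 0/1.

    Returns ``(support_indices, dual_coef, intercept)`` in the raw libsvm
    sign convention (see module docstring).
    """
    if _HAVE_LIBSVM:
        K = np.ascontiguousarray(K, dtype=np.float64)
        res = _libsvm.fit(K, np.asarray(y01, dtype=np.float64),
                          svm_type=0, kernel="precomputed", C=float(C))
        return res[0], res[3][0], float(res[4][0])
    svc = SVC(C=C, kernel="precomputed").fit(K, np.asarray(y01, dtype=int))
    # sklearn's decision_function is the negation of the raw libsvm decision
    return svc.support_, -svc.dual_coef_[0], -float(svc.intercept_[0])


def predict_precomputed(K_test: np.ndarray, support: np.ndarray,
                        coef: np.ndarray, intercept: float) -> np.ndarray:
    """Predict 0/1 labels for precomputed-kernel test rows."""
    dec = K_test[:, support] @ coef + intercept
    return (dec <= 0).astype(int)


def fit_predict_precomputed(K: np.ndarray, y01: np.ndarray, C: float,
                            K_test: np.ndarray) -> np.ndarray:
    support, coef, intercept = fit_precomputed(K, y01, C)
    return predict_precomputed(K_test, support, coef, intercept)
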