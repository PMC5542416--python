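"""Linear soft-margin SVM used by all decoding schemes.

Classification uses libsvm's C-SVC with a linear kernel and fixed C.
The hot loop fits hundreds of thousands of six-sample problems, so the
default path calls the libsvm binding bundled with scikit-learn directly,
bypassing estimator construction; it is numerically identical to
``sklearn.svm.SVC(kernel="linear", C=C)`` (asserted in the test-suite) and
falls back to the public estimator if the binding is unavailable.

Ties in the decision function (decision value exactly 0) are broken toward
the first class, deterministically.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - environment probe
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except Exception:  # pragma: no cover
    _HAVE_LIBSVM = False

from sklearn.svm import SVC


def decision_values(train0: np.ndarray, train1: np.ndarray, test: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Signed decision values for test vectors; positive favors class 0.

    ``train0``/``train1`` are the training vectors of the two classes
    (rows = samples). libsvm orders classes by first appearance, so with
    class 0 first its decision function is positive on the class-0 side.
    """
    X = np.ascontiguousarray(np.vstack([train0, train1]), dtype=np.float64)
    y = np.empty(len(X))
    y[: len(train0)] = 0.0
    y[len(train0):] = 1.0
    test = np.asarray(test, dtype=np.float64)
    if _HAVE_LIBSVM:
        out = _libsvm.fit(X, y, svm_type=0, kernel="linear", C=C)
        support_vectors, dual_coef, intercept = out[1], out[3], out[4]
        w = dual_coef.ravel() @ support_vectors
        return test @ w + intercept[0]
    model = SVC(kernel="linear", C=C).fit(X, y)  # pragma: no cover
    return -model.decision_function(test)  # pragma: no cover


def classify(train0: np.ndarray, train1: np.ndarray, test: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Predicted class labels (0 or 1) for test vectors; ties go to class 0."""
    return (decision_values(train0, train1, test, C) < 0).astype(int)
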