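"""Partial least squares regression (NIPALS) and two-class PLS-DA.

The predictor matrix X is projected onto A orthogonal latent variables,
    T = X R,
and a regression is established between the scores and the response,
    y_hat = T q,
so the composite coefficient vector is b = R q. For classification the
response is a 0/1 dummy coding of class membership; because predictions are
real-valued, class assignment applies one-dimensional linear discriminant
analysis (equal priors, pooled variance) to the predicted response, which
reduces to a midpoint threshold between the class means of y_hat.

The NIPALS implementation is PLS1 with X-deflation only; weight vectors are
unit-norm, so R = W (P' W)^{-1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CENTER = "CENTER"
AUTOSCALE = "AUTOSCALE"

_TINY_WEIGHT = 1e-12


@dataclass
class Preprocessor:
    """Column centering / autoscaling fitted on training rows only."""

    means: np.ndarray
    scales: np.ndarray
    mode: str

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.scales

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scales + self.means


def fit_preprocessor(X: np.ndarray, mode: str = AUTOSCALE) -> Preprocessor:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    means = X.mean(axis=0)
    if mode == CENTER:
        scales = np.ones(X.shape[1])
    elif mode == AUTOSCALE:
        scales = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(scales == 0)
        if zero.size:
            raise ValueError(f"zero-variance column(s) {zero.tolist()} in AUTOSCALE mode")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Preprocessor(means=means, scales=scales, mode=mode)


@dataclass
class PLSModel:
    """Fitted PLS1 model on preprocessed data."""

    A: int
    W: np.ndarray  # p x A unit-norm weight vectors
    P: np.ndarray  # p x A X-loadings
    q: np.ndarray  # A response coefficients
    R: np.ndarray  # p x A projection weights: T = X R for new data
    T: np.ndarray  # n x A training scores
    b: np.ndarray  # p composite coefficients R q
    preprocessor: Preprocessor | None = None
    y_mean: float = 0.0

    def coefficients(self, a: int | None = None) -> np.ndarray:
        """Composite coefficients using only the first ``a`` latent variables.

        NIPALS components are nested, so one fit at A_max yields the whole
        complexity path.
        """
        a = self.A if a is None else a
        if not 1 <= a <= self.A:
            raise ValueError("component count out of range")
        Wa, Pa = self.W[:, :a], self.P[:, :a]
        return Wa @ np.linalg.solve(Pa.T @ Wa, self.q[:a])


def fit_pls(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """NIPALS PLS1 on centered (or autoscaled) X and centered y.

    Deflates X only; stops early with a warning if a weight vector is
    numerically zero (degenerate collinear input).
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} outside 1..min(n-1={n - 1}, p={p})")

    Xd = X.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    a_eff = 0
    for a in range(A):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw < _TINY_WEIGHT:
            warnings.warn(
                f"NIPALS stopped early at {a} latent variables (zero weight vector)",
                RuntimeWarning,
            )
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < _TINY_WEIGHT:
            warnings.warn(
                f"NIPALS stopped early at {a} latent variables (zero score)", RuntimeWarning
            )
            break
        pa = Xd.T @ t / tt
        q[a] = y @ t / tt
        W[:, a], P[:, a], T[:, a] = w, pa, t
        Xd -= np.outer(t, pa)
        a_eff = a + 1

    if a_eff == 0:
        raise ValueError("no latent variable could be extracted")
    W, P, T, q = W[:, :a_eff], P[:, :a_eff], T[:, :a_eff], q[:a_eff]
    R = W @ np.linalg.inv(P.T @ W)
    return PLSModel(A=a_eff, W=W, P=P, q=q, R=R, T=T, b=R @ q)


def predict_pls(model: PLSModel, X_new: np.ndarray, a: int | None = None) -> np.ndarray:
    """Predicted responses for new rows: preprocess, apply b, un-center y."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    expected = model.W.shape[0]
    if X_new.shape[1] != expected:
        raise ValueError(f"expected {expected} columns, got {X_new.shape[1]}")
    if model.preprocessor is not None:
        X_new = model.preprocessor.transform(X_new)
    b = model.b if a is None else model.coefficients(a)
    return X_new @ b + model.y_mean


@dataclass
class PLSDAModel:
    """Two-class PLS-DA: PLS on a 0/1 dummy response + LDA threshold."""

    pls: PLSModel
    class0: str
    class1: str
    threshold: float  # LDA decision point on the predicted response
    lda_sign: float  # +1 if class1 has the larger training mean response
    orientation: float  # canonical-variate sign: class1 training mean < 0
    train_scores: np.ndarray = field(default=None)  # canonical variate, training rows

    @property
    def variable_weights(self) -> np.ndarray:
        """Per-variable contribution on the autoscaled inputs; positive means
        the marker pushes the prediction toward ``class1``."""
        return self.pls.b.copy()


def fit_plsda(
    X: np.ndarray,
    labels: np.ndarray,
    A: int,
    positive_class: str = "PFS",
    mode: str = AUTOSCALE,
) -> PLSDAModel:
    """Fit PLS-DA: dummy y in {0,1}, autoscaled X, LDA rule on y_hat.

    The decision threshold is the midpoint of the class means of the
    training predictions (1-D LDA with equal priors and pooled variance).
    """
    labels = np.asarray(labels, dtype=str)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_class in classes:
        class1 = positive_class
        class0 = next(c for c in classes if c != class1)
    else:
        class0, class1 = classes
    y = (labels == class1).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("each class needs at least 2 training samples")

    prep = fit_preprocessor(X, mode)
    Xp = prep.transform(X)
    y_mean = float(y.mean())
    model = fit_pls(Xp, y - y_mean, A)
    model.preprocessor = prep
    model.y_mean = y_mean

    yhat = predict_pls(model, X)
    m1 = yhat[y == 1].mean()
    m0 = yhat[y == 0].mean()
    threshold = 0.5 * (m0 + m1)
    lda_sign = 1.0 if m1 >= m0 else -1.0
    # Canonical variate oriented so the positive class sits at negative values.
    orientation = -1.0 if lda_sign * (m1 - threshold) >= 0 else 1.0

    da = PLSDAModel(
        pls=model,
        class0=class0,
        class1=class1,
        threshold=threshold,
        lda_sign=lda_sign,
        orientation=orientation,
    )
    da.train_scores = canonical_variate(da, X)
    return da


def predict_class(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Assign the positive class where the predicted response clears the
    LDA threshold (in the direction of the positive-class training mean)."""
    yhat = predict_pls(model.pls, X_new)
    pos = model.lda_sign * (yhat - model.threshold) >= 0
    return np.where(pos, model.class1, model.class0)


def canonical_variate(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Sample scores along the discriminant direction; the threshold maps to
    zero and the positive-class training mean is negative."""
    yhat = predict_pls(model.pls, X_new)
    return model.orientation * (yhat - model.threshold)


def variable_weights(model: PLSDAModel) -> np.ndarray:
    return model.variable_weights
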