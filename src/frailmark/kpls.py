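"""Kernel PLS regression with a Gaussian kernel (dual-form NIPALS).

Instead of extracting scores directly from X, KPLS extracts them from a
kernel matrix K[i,j] = k(x_i, x_j), i.e. from an implicit non-linear
feature-space projection. With the Gaussian kernel
    k(x, x') = exp(-||x - x'||^2 / (2 sigma^2))
the model can capture smooth non-linear relations between the marker panel
and a clinical outcome; as sigma grows the kernel linearizes and predictions
approach those of ordinary linear PLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls import AUTOSCALE, Preprocessor, fit_preprocessor

_TINY = 1e-12


def gaussian_kernel(X1: np.ndarray, X2: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian (RBF) kernel matrix, K[i,j] = exp(-||x1_i - x2_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("dimension mismatch")
    sq = (
        np.sum(X1**2, axis=1)[:, None]
        + np.sum(X2**2, axis=1)[None, :]
        - 2.0 * X1 @ X2.T
    )
    return np.exp(-np.clip(sq, 0.0, None) / (2.0 * sigma**2))


def linear_kernel(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Inner-product kernel; used to check the linear-PLS equivalence."""
    return np.atleast_2d(np.asarray(X1, float)) @ np.atleast_2d(np.asarray(X2, float)).T


def center_kernel(K_train: np.ndarray, K_new: np.ndarray | None = None):
    """Double-center a training kernel; optionally center a cross-kernel of
    new samples using the *training* means.

    Kc = (I - 11'/n) K (I - 11'/n); for an m x n cross-kernel,
    Kc_new[i,j] = K_new[i,j] - rowmean_i - colmean_j(train) + grandmean(train).
    """
    K = np.asarray(K_train, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError("training kernel must be square")
    col_means = K.mean(axis=0)
    grand = K.mean()
    Kc = K - col_means[None, :] - col_means[:, None] + grand
    if K_new is None:
        return Kc
    Kn = np.atleast_2d(np.asarray(K_new, dtype=float))
    Knc = Kn - Kn.mean(axis=1, keepdims=True) - col_means[None, :] + grand
    return Kc, Knc


@dataclass
class KPLSModel:
    sigma: float | None  # None = linear kernel
    X_train: np.ndarray  # preprocessed training rows
    preprocessor: Preprocessor | None
    kernel_col_means: np.ndarray
    kernel_grand_mean: float
    T: np.ndarray  # n x A normalized feature-space scores
    U: np.ndarray  # n x A deflated-response vectors
    y_center: float
    y_train_centered: np.ndarray
    A: int

    def dual_coefficients(self, a: int | None = None) -> np.ndarray:
        a = self.A if a is None else a
        if not 1 <= a <= self.A:
            raise ValueError("component count out of range")
        Ta, Ua = self.T[:, :a], self.U[:, :a]
        Kc = self._train_kernel_centered()
        return Ua @ np.linalg.solve(Ta.T @ Kc @ Ua, Ta.T @ self.y_train_centered)

    def _kernel(self, X1, X2) -> np.ndarray:
        if self.sigma is None:
            return linear_kernel(X1, X2)
        return gaussian_kernel(X1, X2, self.sigma)

    def _train_kernel_centered(self) -> np.ndarray:
        return center_kernel(self._kernel(self.X_train, self.X_train))


def fit_kpls(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float | None,
    A: int,
    mode: str = AUTOSCALE,
) -> KPLSModel:
    """Dual-form NIPALS on the centered kernel (PLS1).

    Each component takes t proportional to K_deflated y_deflated, then
    deflates both the kernel and the response by the normalized score.
    ``sigma=None`` selects the linear (inner-product) kernel.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if not 1 <= A <= n - 1:
        raise ValueError(f"A={A} outside 1..{n - 1}")
    prep = fit_preprocessor(X, mode) if mode is not None else None
    Xp = prep.transform(X) if prep is not None else X

    K = gaussian_kernel(Xp, Xp, sigma) if sigma is not None else linear_kernel(Xp, Xp)
    col_means = K.mean(axis=0)
    grand = float(K.mean())
    Kc = center_kernel(K)
    y_center = float(y.mean())
    yc = y - y_center

    Kd = Kc.copy()
    yd = yc.copy()
    T = np.zeros((n, A))
    U = np.zeros((n, A))
    a_eff = 0
    for a in range(A):
        t = Kd @ yd
        nt = np.linalg.norm(t)
        if nt < _TINY:
            break  # degenerate (e.g. constant response): keep extracted LVs
        t /= nt
        T[:, a], U[:, a] = t, yd
        proj = np.eye(n) - np.outer(t, t)
        Kd = proj @ Kd @ proj
        yd = yd - t * (t @ yd)
        a_eff += 1

    model = KPLSModel(
        sigma=sigma,
        X_train=Xp,
        preprocessor=prep,
        kernel_col_means=col_means,
        kernel_grand_mean=grand,
        T=T[:, :a_eff],
        U=U[:, :a_eff],
        y_center=y_center,
        y_train_centered=yc,
        A=a_eff,
    )
    return model


def predict_kpls(model: KPLSModel, X_new: np.ndarray, a: int | None = None) -> np.ndarray:
    """Predictions for new rows via the centered cross-kernel."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if model.preprocessor is not None:
        X_new = model.preprocessor.transform(X_new)
    if model.A == 0:  # constant-response degenerate fit
        return np.full(X_new.shape[0], model.y_center)
    Kn = model._kernel(X_new, model.X_train)
    Knc = (
        Kn
        - Kn.mean(axis=1, keepdims=True)
        - model.kernel_col_means[None, :]
        + model.kernel_grand_mean
    )
    B = model.dual_coefficients(a)
    return Knc @ B + model.y_center


def q2_score(y_true, y_pred) -> float:
    """Out-of-sample coefficient of determination:
    Q2 = 1 - sum((y - y_hat)^2) / sum((y - mean(y))^2). Can be negative."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ValueError("need equal-length samples with n >= 2")
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero-variance y_true")
    return float(1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot)


def median_pairwise_distance(X: np.ndarray) -> float:
    """Median Euclidean distance between distinct rows (sigma-grid anchor)."""
    X = np.asarray(X, dtype=float)
    sq = (
        np.sum(X**2, axis=1)[:, None] + np.sum(X**2, axis=1)[None, :] - 2 * X @ X.T
    )
    d = np.sqrt(np.clip(sq[np.triu_indices(len(X), k=1)], 0.0, None))
    med = float(np.median(d))
    return med if med > 0 else 1.0


def sigma_grid(X: np.ndarray, n_points: int = 7, span: float = 10.0) -> np.ndarray:
    """Log grid of kernel widths centered on the median pairwise distance."""
    center = median_pairwise_distance(X)
    return center * np.logspace(-np.log10(span) / 2, np.log10(span) / 2, n_points)
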