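"""Prewhitened GLM fitting and t-score computation.

The observation model is ``Y = X beta + eps`` with ``eps ~ N(0, sigma^2 V)``.
Given an estimate of the autocorrelation matrix ``V``, the data and design
are premultiplied by the whitening matrix ``W`` (``W'W = V^-1``) so that the
whitened error is spherical; ordinary least squares on the whitened problem
then gives the generalised-least-squares estimates.  The t-score for a
contrast ``c`` is

    t = c' beta_hat / (sigma_hat * eta),    eta = sqrt(c' (WX)^- (WX)^-' c)

with ``sigma_hat^2 = e'e / trace(R)`` from the whitened residuals
``e = R W Y``.  Two intercept-based summary statistics quantify functional
sensitivity:

* ``t0`` — the t-score testing the mean signal (contrast on the intercept),
  which shrinks appropriately when serial correlation inflates the
  uncertainty of the variance estimate;
* ``tSNR_w`` — the conventional temporal SNR weighted by sqrt(N), which
  ignores serial correlation entirely.

For white noise and an intercept-only design the two coincide exactly
(``eta0 = 1/sqrt(N)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignMatrix

__all__ = [
    "GLMFit",
    "ContrastResult",
    "whitening_matrix",
    "fit_glm",
    "contrast_t",
    "mean_t",
    "weighted_tsnr",
]

#: Relative eigenvalue floor applied when inverting covariance matrices.
EIG_FLOOR = 1e-8


def whitening_matrix(V: np.ndarray) -> np.ndarray:
    """Symmetric whitening matrix ``W = V^{-1/2}``.

    The defining property ``W'W = V^-1`` does not pin ``W`` down uniquely;
    the symmetric principal inverse square root (via eigendecomposition) is
    used, with eigenvalues floored at ``1e-8`` of the largest to guard
    against indefiniteness of estimated mixtures.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("V must be square")
    if not np.allclose(V, V.T, atol=1e-10 * max(1.0, np.abs(V).max())):
        raise ValueError("V must be symmetric")
    w, U = np.linalg.eigh((V + V.T) / 2.0)
    w = np.maximum(w, EIG_FLOOR * w.max())
    return (U / np.sqrt(w)) @ U.T


@dataclass
class GLMFit:
    """Result of a (whitened) GLM fit across voxels."""

    W: np.ndarray
    beta: np.ndarray          # k x v
    residuals: np.ndarray     # n x v, e = R W Y
    sigma2: np.ndarray        # length v
    trace_R: float            # effective residual dof, trace(R V_w), V_w = I
    X: DesignMatrix
    pinv_WX: np.ndarray = field(repr=False, default=None)

    @property
    def n_voxels(self) -> int:
        return self.beta.shape[1]

    @property
    def dof(self) -> float:
        return self.trace_R


@dataclass
class ContrastResult:
    """t-scores for one contrast across voxels."""

    contrast: np.ndarray
    t: np.ndarray
    eta: float
    effect: np.ndarray
    infinite_mask: np.ndarray
    dof: float

    @property
    def mean_t(self) -> float:
        finite = self.t[~self.infinite_mask]
        return float(np.mean(finite)) if finite.size else float("inf")


def fit_glm(
    Y: np.ndarray, X: DesignMatrix, W: np.ndarray | None = None
) -> GLMFit:
    """Fit the GLM to whitened data.

    ``Y`` is ``n x v`` (time by voxels).  ``W`` defaults to the identity
    (no serial-correlation model).  Estimates::

        beta = (WX)^- W Y
        e    = R W Y,  R = I - WX (X'W'WX)^-1 X'W'
        sigma^2 = e'e / trace(R)      (per voxel)
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, v = Y.shape
    if n != X.n_samples:
        raise ValueError("Y row count must match the design")
    if W is None:
        W = np.eye(n)
    W = np.asarray(W, dtype=float)
    if W.shape != (n, n):
        raise ValueError("W must be n x n")

    WX = W @ X.matrix
    WY = W @ Y
    pinv_WX = np.linalg.pinv(WX)
    beta = pinv_WX @ WY
    fitted = WX @ beta
    e = WY - fitted
    # trace(R) = n - rank(WX); R = I - WX (WX)^-
    rank = np.linalg.matrix_rank(WX)
    trace_R = float(n - rank)
    if trace_R <= 0:
        raise ValueError("zero residual degrees of freedom")
    sigma2 = np.einsum("ij,ij->j", e, e) / trace_R
    # voxels fit exactly (up to roundoff) are treated as zero-variance
    scale = np.einsum("ij,ij->j", WY, WY) / n
    sigma2 = np.where(sigma2 <= 1e-24 * scale, 0.0, sigma2)
    return GLMFit(
        W=W,
        beta=beta,
        residuals=e,
        sigma2=sigma2,
        trace_R=trace_R,
        X=X,
        pinv_WX=pinv_WX,
    )


def contrast_t(fit: GLMFit, c: np.ndarray) -> ContrastResult:
    """t-score for contrast ``c``: ``t = c'beta / (sigma_hat * eta)``.

    Voxels with exactly zero residual variance are flagged and reported as
    +/-inf (sign of the effect) rather than raising.
    """
    c = np.asarray(c, dtype=float).ravel()
    if c.size != fit.X.n_columns:
        raise ValueError("contrast length must equal design columns")
    if not np.any(c):
        raise ValueError("contrast must be non-zero")
    g = fit.pinv_WX.T @ c
    eta = float(np.sqrt(g @ g))
    effect = c @ fit.beta
    sigma = np.sqrt(fit.sigma2)
    zero = sigma == 0
    t = np.empty_like(effect)
    t[~zero] = effect[~zero] / (sigma[~zero] * eta)
    t[zero] = np.sign(effect[zero]) * np.inf
    return ContrastResult(
        contrast=c,
        t=t,
        eta=eta,
        effect=effect,
        infinite_mask=zero,
        dof=fit.trace_R,
    )


def _intercept_contrast(fit: GLMFit) -> np.ndarray:
    c = np.zeros(fit.X.n_columns)
    c[fit.X.intercept_index] = 1.0
    return c


def mean_t(fit: GLMFit) -> ContrastResult:
    """t-score testing the mean signal (``t0``): the intercept contrast.

    Its effective precision ``eta0`` reduces to ``1/sqrt(N)`` when the noise
    is white and the design is the intercept alone; with correctly modelled
    serial correlation it grows, deflating ``t0`` relative to the weighted
    tSNR.
    """
    return contrast_t(fit, _intercept_contrast(fit))


def weighted_tsnr(fit: GLMFit) -> ContrastResult:
    """Temporal SNR weighted by the number of samples.

    ``tSNR_w = c0'beta / sigma_hat * sqrt(N)`` — the GLM residual standard
    deviation is used, so task variance is removed by the regressors, but the
    sqrt(N) weighting assumes independent samples.
    """
    c0 = _intercept_contrast(fit)
    res = contrast_t(fit, c0)
    n = fit.X.n_samples
    sigma = np.sqrt(fit.sigma2)
    nz = ~res.infinite_mask
    t = np.empty_like(res.effect)
    t[nz] = res.effect[nz] / sigma[nz] * np.sqrt(n)
    t[~nz] = np.sign(res.effect[~nz]) * np.inf
    return ContrastResult(
        contrast=c0,
        t=t,
        eta=1.0 / np.sqrt(n),
        effect=res.effect,
        infinite_mask=res.infinite_mask,
        dof=fit.trace_R,
    )
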