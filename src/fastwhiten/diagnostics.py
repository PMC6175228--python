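"""Evaluation instruments: residual whiteness, spectra, and stability.

Three instruments quantify how well a serial-correlation model has whitened
the data:

* a Ljung-Box Q screen — per voxel, the portmanteau statistic is computed at
  every lag up to ``max_lag`` on the first ``n_points`` residual samples, and
  the resulting p-values are FDR-corrected jointly across voxels and lags; a
  voxel "rejects" (retains serial correlation) if any lag survives;
* segment-averaged residual power spectra, which should be flat after
  successful prewhitening;
* a stability analysis — the precision (inverse standard error) of the mean
  signal estimate should grow linearly with the square root of the number of
  samples when the noise model is well conditioned; the R^2 of that linear
  relationship drops when the dictionary is over-parameterised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import warnings

import numpy as np
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .basis import CovarianceComponentSet
from .design import DesignMatrix
from .glm import fit_glm, mean_t, whitening_matrix
from .reml import pooled_sample_covariance, reml_fit

__all__ = [
    "WhitenessReport",
    "StabilityResult",
    "ljung_box_q",
    "benjamini_hochberg",
    "whiteness_screen",
    "residual_power_spectrum",
    "precision_stability",
]

logger = logging.getLogger(__name__)


@dataclass
class WhitenessReport:
    """Outcome of the Ljung-Box residual screen."""

    per_voxel_p: np.ndarray       # voxel x lag
    rejected: np.ndarray          # voxel mask
    proportion_rejected: float
    n_points: int
    max_lag: int
    fdr_q: float
    n_excluded: int = 0

    def as_dict(self) -> dict:
        return {
            "proportion_rejected": float(self.proportion_rejected),
            "n_voxels": int(self.rejected.size),
            "n_rejected": int(self.rejected.sum()),
            "n_points": self.n_points,
            "max_lag": self.max_lag,
            "fdr_q": self.fdr_q,
            "n_excluded": self.n_excluded,
        }


@dataclass
class StabilityResult:
    """Precision-versus-sqrt(n) linear fit over a truncation grid."""

    sample_grid: np.ndarray
    precision: np.ndarray
    r_squared: float
    slope: float
    intercept: float
    converged: np.ndarray = field(default_factory=lambda: np.array([], bool))

    def as_dict(self) -> dict:
        return {
            "sample_grid": self.sample_grid.tolist(),
            "precision": self.precision.tolist(),
            "r_squared": float(self.r_squared),
            "slope": float(self.slope),
            "intercept": float(self.intercept),
            "converged": self.converged.astype(bool).tolist(),
        }


def _sample_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelations rho_1..rho_max_lag of a demeaned series."""
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("constant series: autocorrelations undefined")
    return np.array(
        [float(x[k:] @ x[:-k]) / denom for k in range(1, max_lag + 1)]
    )


def ljung_box_q(series: np.ndarray, lag: int) -> tuple[float, float]:
    """Ljung-Box portmanteau test of zero autocorrelation up to ``lag``.

    ``Q = m (m+2) sum_{k=1..h} rho_k^2 / (m-k)`` is referred to the upper
    tail of chi-square with ``h`` degrees of freedom.  No adjustment is made
    for parameters fitted upstream; the calibration of the screen is checked
    empirically instead.
    """
    x = np.asarray(series, dtype=float).ravel()
    m = x.size
    if not (0 < lag < m):
        raise ValueError("lag must satisfy 0 < lag < series length")
    rho = _sample_autocorr(x, lag)
    ks = np.arange(1, lag + 1)
    Q = m * (m + 2.0) * float(np.sum(rho**2 / (m - ks)))
    p = float(stats.chi2.sf(Q, lag))
    return Q, p


def benjamini_hochberg(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Step-up false-discovery-rate control at level ``q``."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def whiteness_screen(
    residuals: np.ndarray,
    n_points: int = 100,
    max_lag: int = 20,
    fdr_q: float = 0.05,
) -> WhitenessReport:
    """Ljung-Box screen over all voxels (residuals are time x voxels).

    Each voxel's residual series is truncated to its first ``n_points``
    samples; Q is evaluated at every lag ``1..max_lag``; the voxel-by-lag
    p-values are FDR-corrected jointly and a voxel is rejected if any of its
    lags survives.  Voxels with undefined autocorrelation (constant series)
    are excluded with a logged count.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    n, v = R.shape
    if not (max_lag < n_points <= n):
        raise ValueError("need time dimension >= n_points > max_lag")
    R = R[:n_points]
    m = n_points
    ks = np.arange(1, max_lag + 1)

    pmat = np.full((v, max_lag), np.nan)
    excluded = np.zeros(v, dtype=bool)
    Rc = R - R.mean(axis=0)
    denom = np.einsum("ij,ij->j", Rc, Rc)
    excluded = denom == 0
    ok = ~excluded
    if ok.any():
        rho = np.empty((max_lag, int(ok.sum())))
        Rok = Rc[:, ok]
        for k in ks:
            rho[k - 1] = np.einsum("ij,ij->j", Rok[k:], Rok[:-k]) / denom[ok]
        cum = np.cumsum(rho**2 / (m - ks)[:, None], axis=0)
        Q = m * (m + 2.0) * cum  # lag x voxel
        pmat[ok, :] = stats.chi2.sf(Q, ks[:, None]).T
    n_excl = int(excluded.sum())
    if n_excl:
        logger.warning("%d constant voxels excluded from the screen", n_excl)

    rejected = np.zeros(v, dtype=bool)
    if ok.any():
        flat = pmat[ok].ravel()
        rej_flat = benjamini_hochberg(flat, fdr_q)
        rejected[ok] = rej_flat.reshape(int(ok.sum()), max_lag).any(axis=1)
    proportion = float(rejected[ok].mean()) if ok.any() else 0.0
    return WhitenessReport(
        per_voxel_p=pmat,
        rejected=rejected,
        proportion_rejected=proportion,
        n_points=n_points,
        max_lag=max_lag,
        fdr_q=fdr_q,
        n_excluded=n_excl,
    )


def residual_power_spectrum(
    residuals: np.ndarray, tr: float, nperseg: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-averaged residual power spectrum up to the Nyquist frequency.

    Segment-averaged periodogram (50% overlap, mean-detrended segments); a
    flat spectrum indicates successful prewhitening.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    n = R.shape[0]
    if n < 8:
        raise ValueError("need at least 8 time points")
    if nperseg is None:
        nperseg = max(8, min(256, n // 2))
    freqs, pxx = signal.welch(
        R,
        fs=1.0 / tr,
        axis=0,
        nperseg=min(nperseg, n),
        noverlap=min(nperseg, n) // 2,
        detrend="constant",
    )
    return freqs, pxx.mean(axis=1)


def precision_stability(
    Y: np.ndarray,
    X: DesignMatrix,
    basis_factory,
    n_total: int | None = None,
    n_min: int = 100,
    n_grid: int = 5,
    pool_mask: np.ndarray | None = None,
) -> StabilityResult:
    """Precision of the mean-signal estimate versus sqrt(number of samples).

    For each of ``n_grid`` equally spaced sample counts from ``n_min`` to
    ``n_total``, the series and design are truncated to their first ``n``
    samples, the autocorrelation mixture is re-estimated by ReML, the GLM is
    refit with the resulting whitening matrix, and the precision
    ``1 / SE(intercept)`` averaged over voxels is recorded.  The grid of
    precisions is then regressed on sqrt(n); a high R^2 indicates a stable,
    well-conditioned noise model.

    ``basis_factory`` maps a sample count to a component dictionary (so each
    truncation gets components of the right dimension).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if n_total is None:
        n_total = Y.shape[0]
    if n_total > Y.shape[0]:
        raise ValueError("n_total exceeds available samples")
    if n_total < n_min + n_grid * 5:
        raise ValueError("n_total too small for a strictly increasing grid")
    grid = np.unique(
        np.round(np.linspace(n_min, n_total, n_grid)).astype(int)
    )
    precisions = []
    converged = []
    for n in grid:
        Yt = Y[:n]
        Xt = X.truncated(int(n))
        S = pooled_sample_covariance(
            Yt, pool_mask if pool_mask is not None else None
        )
        basis = basis_factory(int(n))
        res = reml_fit(S, basis, Xt)
        if not res.converged:
            logger.warning("ReML did not converge at n=%d", n)
        W = whitening_matrix(res.V)
        fit = fit_glm(Yt, Xt, W)
        t0 = mean_t(fit)
        se = np.sqrt(fit.sigma2) * t0.eta
        valid = se > 0
        precisions.append(float(np.mean(1.0 / se[valid])))
        converged.append(res.converged)
    precisions = np.asarray(precisions)
    slope, intercept, r, _, _ = stats.linregress(
        np.sqrt(grid), precisions
    )
    return StabilityResult(
        sample_grid=grid,
        precision=precisions,
        r_squared=float(r**2),
        slope=float(slope),
        intercept=float(intercept),
        converged=np.asarray(converged, dtype=bool),
    )
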