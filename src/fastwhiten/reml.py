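"""Restricted maximum likelihood estimation of serial-correlation mixtures.

The autocorrelation matrix of the noise is modelled as a mixture
``V = sum_i lambda_i C_i`` over a covariance-component dictionary.  The
hyperparameters ``lambda`` are estimated from a sample covariance pooled over
task-responsive voxels by Fisher scoring on the (restricted) variational free
energy — a lower bound on log model evidence that scores accuracy while
penalising complexity, so dictionaries of different size can be compared
directly (differences greater than 3 nats are conventionally strong
evidence).

Restriction: the pooled covariance and the components are projected onto an
orthonormal basis of the orthogonal complement of the design's column space,
so that uncertainty about the fixed effects does not bias the covariance
estimate.  Each hyperparameter carries a flat Gaussian prior (mean 0,
variance ``exp(8)``); the free energy reported includes the resulting
complexity terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import warnings

import numpy as np
import scipy.linalg
from scipy import stats

from .basis import CovarianceComponentSet, mix_components
from .design import DesignMatrix

__all__ = [
    "SampleCovariance",
    "ReMLResult",
    "ModelComparison",
    "omnibus_voxel_selection",
    "pooled_sample_covariance",
    "reml_fit",
    "compare_models",
]

logger = logging.getLogger(__name__)

#: Prior variance of each hyperparameter (uninformative, log-scale 8).
PRIOR_VARIANCE = np.exp(8.0)

#: Strong-evidence threshold on free-energy differences (nats).
STRONG_EVIDENCE_NATS = 3.0

#: Fisher-information condition number above which a warning is issued.
CONDITION_WARN = 1e10


@dataclass
class SampleCovariance:
    """Second-moment matrix of (scaled) voxel time courses.

    ``matrix`` is the average of ``y y'`` over the pooled voxels after each
    voxel's series is scaled to unit mean square; ``n_voxels_pooled`` acts as
    the effective number of observations in the ReML objective.
    """

    matrix: np.ndarray
    n_voxels_pooled: int
    scaling: str = "unit mean square per voxel"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("sample covariance must be square")
        if not np.allclose(m, m.T, atol=1e-8 * max(1.0, np.abs(m).max())):
            raise ValueError("sample covariance must be symmetric")
        if self.n_voxels_pooled < 1:
            raise ValueError("n_voxels_pooled must be >= 1")
        self.matrix = (m + m.T) / 2.0

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ReMLResult:
    """Fitted hyperparameters and the free energy attained."""

    lam: np.ndarray
    V: np.ndarray                 # trace-normalized autocorrelation matrix
    free_energy: float
    posterior_cov: np.ndarray
    n_iterations: int
    converged: bool
    basis_label: str = ""
    condition_number: float = float("nan")


@dataclass
class ModelComparison:
    """Free-energy comparison of component dictionaries.

    ``delta_f`` is relative to the first (reference) basis; differences
    larger than 3 nats count as strong evidence.
    """

    entries: list[ReMLResult]
    labels: list[str]
    reference_label: str
    delta_f: np.ndarray
    winner: str
    strong_evidence: np.ndarray

    def as_dict(self) -> dict:
        return {
            "reference": self.reference_label,
            "winner": self.winner,
            "models": [
                {
                    "label": lab,
                    "free_energy": float(r.free_energy),
                    "delta_f": float(d),
                    "strong_evidence": bool(s),
                    "converged": bool(r.converged),
                    "n_iterations": int(r.n_iterations),
                }
                for lab, r, d, s in zip(
                    self.labels, self.entries, self.delta_f,
                    self.strong_evidence
                )
            ],
        }


def omnibus_voxel_selection(
    Y: np.ndarray,
    X: DesignMatrix,
    task_columns: np.ndarray | None = None,
    alpha: float = 0.001,
) -> np.ndarray:
    """Voxels surviving an omnibus F-test on the task regressors (OLS).

    Returns a boolean mask over voxels with joint-task F-test p < ``alpha``.
    If no voxel survives, all voxels are returned with a warning so that
    pooling never operates on an empty set.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, v = Y.shape
    if task_columns is None:
        task_columns = X.columns_of("task")
    task_columns = np.asarray(task_columns, dtype=int)
    if task_columns.size == 0:
        raise ValueError("task_columns must be non-empty")

    Xf = X.matrix
    keep = np.setdiff1d(np.arange(X.n_columns), task_columns)
    Xr = Xf[:, keep] if keep.size else np.zeros((n, 0))

    def rss(M: np.ndarray) -> tuple[np.ndarray, int]:
        if M.shape[1] == 0:
            return np.einsum("ij,ij->j", Y, Y), 0
        B = np.linalg.pinv(M) @ Y
        E = Y - M @ B
        return np.einsum("ij,ij->j", E, E), int(np.linalg.matrix_rank(M))

    rss_full, rank_full = rss(Xf)
    rss_red, rank_red = rss(Xr)
    df_num = rank_full - rank_red
    df_den = n - rank_full
    if df_den <= 0:
        raise ValueError("zero residual degrees of freedom in omnibus test")
    if df_num <= 0:
        raise ValueError("task columns add no rank to the design")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    F = np.where(rss_full == 0, np.inf, F)
    pvals = stats.f.sf(F, df_num, df_den)
    mask = pvals < alpha
    if not mask.any():
        warnings.warn(
            "no voxel survived the omnibus F-test; pooling over all voxels",
            stacklevel=2,
        )
        mask = np.ones(v, dtype=bool)
    return mask


def pooled_sample_covariance(
    Y: np.ndarray, mask: np.ndarray | None = None
) -> SampleCovariance:
    """Average outer product of voxel series scaled to unit mean square."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, v = Y.shape
    if mask is None:
        mask = np.ones(v, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != v:
        raise ValueError("mask length must equal number of voxels")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    Ym = Y[:, mask]
    ms = np.einsum("ij,ij->j", Ym, Ym) / n
    if np.any(ms == 0):
        raise ValueError("pooled mask contains all-zero voxel series")
    Ys = Ym / np.sqrt(ms)
    S = (Ys @ Ys.T) / Ys.shape[1]
    return SampleCovariance(matrix=S, n_voxels_pooled=int(mask.sum()))


def _residual_space_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of col(X)."""
    n = X.shape[0]
    U, s, _ = np.linalg.svd(X, full_matrices=True)
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    return U[:, rank:]


def _restricted_objective(
    h: np.ndarray, Qr: np.ndarray, Sr: np.ndarray, n_obs: int
) -> float:
    """Restricted log-likelihood ``-N/2 [logdet C + tr(C^-1 S)]`` in the
    reduced space (constant terms included); -inf if C is not PD."""
    m = Sr.shape[0]
    C = np.einsum("i,ijk->jk", h, Qr)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    tr = float(np.trace(scipy.linalg.cho_solve((L, True), Sr)))
    return -0.5 * n_obs * (logdet + tr + m * np.log(2 * np.pi))


def reml_fit(
    S: SampleCovariance,
    basis: CovarianceComponentSet,
    X: DesignMatrix | np.ndarray | None = None,
    *,
    max_iter: int = 64,
    tol: float = 1e-2,
    prior_variance: float = PRIOR_VARIANCE,
) -> ReMLResult:
    """Fisher-scoring ascent on the restricted variational free energy.

    Parameters
    ----------
    S
        Pooled sample covariance; ``n_voxels_pooled`` scales the likelihood.
    basis
        Covariance-component dictionary defining ``V(lambda)``.
    X
        Design whose column space is removed before likelihood evaluation
        (the restriction).  ``None`` fits in the full space.
    max_iter, tol
        Ascent stops when the predicted free-energy improvement drops below
        ``tol`` nats (converged) or after ``max_iter`` iterations.

    Hyperparameters are unconstrained reals under a Gaussian prior of mean 0
    and variance ``exp(8)``; any indefiniteness of the fitted mixture is
    handled downstream by eigenvalue flooring at whitening time.  Steps that
    would decrease the penalised objective are halved (Levenberg-style);
    persistent failure returns ``converged=False`` with diagnostics rather
    than raising.
    """
    n = S.n_samples
    if basis.n_samples != n:
        raise ValueError("basis dimension must match sample covariance")
    Xmat = X.matrix if isinstance(X, DesignMatrix) else X
    if Xmat is not None and Xmat.shape[0] != n:
        raise ValueError("design rows must match sample covariance")

    K = (
        _residual_space_basis(np.asarray(Xmat, dtype=float))
        if Xmat is not None and np.asarray(Xmat).size
        else np.eye(n)
    )
    m = K.shape[1]
    if m < 2:
        raise ValueError("residual space too small for covariance estimation")
    Sr = K.T @ S.matrix @ K
    Qr = np.stack([K.T @ Q @ K for Q in basis.matrices])
    k = len(basis)
    N = S.n_voxels_pooled
    hP = 1.0 / prior_variance  # scalar prior precision per component

    # scale-aware start: split the average reduced variance over the
    # unit-diagonal components
    diag_comps = np.array(
        [np.allclose(np.diag(Q), 1.0) for Q in basis.matrices]
    )
    h = np.zeros(k)
    scale = float(np.trace(Sr)) / m
    if diag_comps.any():
        h[diag_comps] = scale / diag_comps.sum()
    else:
        h[:] = scale / k

    def penalised(hvec: np.ndarray) -> float:
        L = _restricted_objective(hvec, Qr, Sr, N)
        return L - 0.5 * hP * float(hvec @ hvec)

    obj = penalised(h)
    if not np.isfinite(obj):
        h = np.zeros(k)
        h[0 if not diag_comps.any() else int(np.argmax(diag_comps))] = scale
        obj = penalised(h)

    converged = False
    n_iter = 0
    fisher = np.eye(k) / prior_variance
    for n_iter in range(1, max_iter + 1):
        C = np.einsum("i,ijk->jk", h, Qr)
        try:
            Lc = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            # mixture left the PD cone (can happen after an accepted step on
            # the boundary); nudge back towards the starting ridge
            h = 0.5 * h
            h[diag_comps] += 0.5 * scale / max(diag_comps.sum(), 1)
            obj = penalised(h)
            continue
        iC = scipy.linalg.cho_solve((Lc, True), np.eye(m))
        A = Qr @ iC                      # k x m x m, A_i = Q_i C^-1
        M = iC @ Sr @ iC                 # C^-1 S C^-1 (symmetric)
        trA = np.einsum("ijj->i", A)
        trQM = np.einsum("imn,nm->i", Qr, M)
        grad = -0.5 * N * (trA - trQM) - hP * h
        # expected curvature (Fisher information) + prior precision
        Asym = np.einsum("imn,jnm->ij", A, A)
        fisher = 0.5 * N * Asym + hP * np.eye(k)
        cond = float(np.linalg.cond(fisher))
        if cond > CONDITION_WARN:
            warnings.warn(
                f"ill-conditioned Fisher information (cond={cond:.2e}); "
                "the dictionary is likely over-parameterised",
                stacklevel=2,
            )
        dh = np.linalg.solve(fisher, grad)
        predicted = float(grad @ dh)
        if predicted < tol:
            converged = True
            break
        # step-halving to enforce ascent of the penalised objective
        step = 1.0
        for _ in range(16):
            new_obj = penalised(h + step * dh)
            if np.isfinite(new_obj) and new_obj >= obj - 1e-12:
                h = h + step * dh
                obj = new_obj
                break
            step *= 0.5
        else:
            logger.warning("step-halving failed to improve the objective")
            break

    lam = h
    V = mix_components(basis, lam)
    tr = float(np.trace(V))
    if tr <= 0:
        warnings.warn("fitted mixture has non-positive trace", stacklevel=2)
        Vn = np.eye(n)
    else:
        Vn = V * (n / tr)
    post_cov = np.linalg.inv(fisher)
    F = _free_energy(obj, h, hP, fisher, k, prior_variance)
    cond = float(np.linalg.cond(fisher))
    return ReMLResult(
        lam=lam,
        V=Vn,
        free_energy=F,
        posterior_cov=post_cov,
        n_iterations=n_iter,
        converged=converged,
        basis_label=basis.label,
        condition_number=cond,
    )


def _free_energy(
    penalised_obj: float,
    h: np.ndarray,
    hP: float,
    fisher: np.ndarray,
    k: int,
    prior_variance: float,
) -> float:
    """Laplace free energy: penalised likelihood at the mode plus the
    Gaussian-posterior complexity terms (only differences across models on
    the same data are meaningful)."""
    sign, logdet_post_prec = np.linalg.slogdet(fisher)
    if sign <= 0 or not np.isfinite(penalised_obj):
        return -np.inf
    # E_q[L] correction + entropy vs prior: 0.5*(tr(hP Sigma) - k)
    #   - 0.5*(logdet Ph - logdet hP)
    tr_term = hP * float(np.trace(np.linalg.inv(fisher)))
    logdet_prior_prec = -k * np.log(prior_variance)
    return (
        penalised_obj
        + 0.5 * (tr_term - k)
        - 0.5 * (logdet_post_prec - logdet_prior_prec)
    )


def compare_models(
    S: SampleCovariance,
    X: DesignMatrix | np.ndarray | None,
    bases: list[CovarianceComponentSet],
    **options,
) -> ModelComparison:
    """Fit every dictionary with identical options and rank by free energy.

    The first basis is the reference; ``delta_f`` and the strong-evidence
    flags (|delta F| > 3 nats) are reported against it.  Non-converged fits
    are kept in the table with their flag."""
    if len(bases) < 2:
        raise ValueError("need at least two bases to compare")
    results = [reml_fit(S, b, X, **options) for b in bases]
    labels = [b.label for b in bases]
    f = np.array([r.free_energy for r in results])
    delta = f - f[0]
    winner = labels[int(np.argmax(f))]
    strong = np.abs(delta) > STRONG_EVIDENCE_NATS
    return ModelComparison(
        entries=results,
        labels=labels,
        reference_label=labels[0],
        delta_f=delta,
        winner=winner,
        strong_evidence=strong,
    )
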