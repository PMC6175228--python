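"""Covariance-component dictionaries for serial-correlation modelling.

The temporal autocorrelation matrix of an fMRI time series is expressed as a
linear mixture ``V = sum_i lambda_i C_i`` over a fixed dictionary of Toeplitz
components ``C_i``.  Two dictionaries are provided:

* the classical two-component basis — white noise plus an AR(1) shape with a
  fixed decay — adequate for conventional (slow) sampling;
* the FAST family — exponential decays at ``p`` dyadic timescales together
  with their first- and second-order derivative shapes (3p components in
  total), able to capture the longer-lag structure of rapidly sampled data.

Components are stored densely; the series analysed here have at most a few
thousand samples, so the Toeplitz structure is verified rather than exploited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
import json

import numpy as np

__all__ = [
    "ComponentKind",
    "CovarianceComponent",
    "CovarianceComponentSet",
    "build_fast_components",
    "build_ar1_plus_white",
    "mix_components",
]

#: Largest FAST timescale count supported; dictionaries beyond 3*9 = 27
#: components are numerically unstable and never useful in practice.
MAX_P = 9


class ComponentKind(str, Enum):
    WHITE = "white"
    AR1 = "ar1"
    FAST = "fast"


@dataclass(frozen=True)
class CovarianceComponent:
    """One symmetric Toeplitz autocovariance shape.

    Parameters
    ----------
    matrix
        Dense ``n x n`` symmetric Toeplitz matrix (dimensionless shape).
    kind
        Which family the component belongs to.
    derivative_order
        For FAST components, the derivative order ``n`` in ``[0, 2]``; the
        entry at lag ``L > 0`` is ``L**n * exp(-alpha*L)`` and the diagonal is
        1 for order 0 and exactly 0 otherwise.
    decay_rate
        FAST decay ``alpha`` (per sample), ``None`` for white/AR1 components.
    timescale_index
        FAST timescale index ``q`` (1-based), ``None`` for white/AR1.
    """

    matrix: np.ndarray
    kind: ComponentKind
    derivative_order: int = 0
    decay_rate: float | None = None
    timescale_index: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("component matrix must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("component matrix has non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CovarianceComponentSet:
    """Ordered dictionary of covariance components sharing one dimension."""

    components: list[CovarianceComponent]
    n_samples: int
    p: int = 0  # FAST timescale count; 0 for the AR(1)+white basis
    label: str = ""
    ar_decay: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("component set must not be empty")
        for c in self.components:
            if c.n_samples != self.n_samples:
                raise ValueError("all components must share n_samples")

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    @property
    def matrices(self) -> list[np.ndarray]:
        return [c.matrix for c in self.components]

    def stacked(self) -> np.ndarray:
        """Components as a ``k x n x n`` array."""
        return np.stack(self.matrices)

    def export(self, directory: str | Path, fmt: str = "%.17g") -> Path:
        """Write each component as a TSV matrix plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "label": self.label,
            "n_samples": self.n_samples,
            "p": self.p,
            "components": [],
        }
        for i, c in enumerate(self.components):
            fname = f"component_{i:02d}.tsv"
            np.savetxt(directory / fname, c.matrix, delimiter="\t", fmt=fmt)
            manifest["components"].append(
                {
                    "file": fname,
                    "kind": c.kind.value,
                    "derivative_order": c.derivative_order,
                    "decay_rate": c.decay_rate,
                    "timescale_index": c.timescale_index,
                }
            )
        path = directory / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path


def _lag_matrix(n: int) -> np.ndarray:
    idx = np.arange(n)
    return np.abs(idx[:, None] - idx[None, :]).astype(float)


def build_fast_components(n_samples: int, p: int) -> CovarianceComponentSet:
    """Construct the FAST dictionary of ``3p`` Toeplitz components.

    The decay rates follow the dyadic rule ``alpha = 8 / 2**q`` for
    ``q = 1..p``.  For derivative order ``n`` the entry at lag ``L`` is::

        C[i, j] = 1                        if i == j and n == 0
        C[i, j] = L**n * exp(-alpha * L)   otherwise, L = |i - j|

    so order-0 components carry a unit diagonal while the order-1/2 shapes
    have an exactly zero diagonal.  Components are ordered by timescale ``q``
    ascending, derivative order ascending within each ``q``; dictionaries are
    therefore nested — the first ``3(p-1)`` components of size-``p`` equal the
    size-``p-1`` dictionary.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not (1 <= p <= MAX_P):
        raise ValueError(f"p must be in [1, {MAX_P}], got {p}")
    lag = _lag_matrix(n_samples)
    off = lag > 0
    comps: list[CovarianceComponent] = []
    for q in range(1, p + 1):
        alpha = 8.0 / 2.0**q
        decay = np.exp(-alpha * lag)
        for order in range(3):
            m = np.where(off, lag**order * decay, 1.0 if order == 0 else 0.0)
            comps.append(
                CovarianceComponent(
                    matrix=m,
                    kind=ComponentKind.FAST,
                    derivative_order=order,
                    decay_rate=alpha,
                    timescale_index=q,
                )
            )
    return CovarianceComponentSet(
        components=comps, n_samples=n_samples, p=p, label=f"fast:p={p}"
    )


def build_ar1_plus_white(
    n_samples: int, decay: float = 0.2
) -> CovarianceComponentSet:
    """Construct the two-component white-noise + AR(1) basis.

    The AR(1) component has entries ``decay ** |i-j|``; the white component is
    the identity.  ``decay`` defaults to the conventional fixed value 0.2.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not (0.0 <= decay < 1.0):
        raise ValueError("decay must be in [0, 1) for stationarity")
    lag = _lag_matrix(n_samples)
    white = CovarianceComponent(
        matrix=np.eye(n_samples), kind=ComponentKind.WHITE
    )
    ar1 = CovarianceComponent(matrix=decay**lag, kind=ComponentKind.AR1)
    return CovarianceComponentSet(
        components=[white, ar1],
        n_samples=n_samples,
        p=0,
        label=f"ar1:decay={decay:g}",
        ar_decay=decay,
    )


def mix_components(
    basis: CovarianceComponentSet, weights: np.ndarray
) -> np.ndarray:
    """Evaluate the mixture ``V = sum_i lambda_i C_i``."""
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != len(basis):
        raise ValueError(
            f"expected {len(basis)} weights, got {w.size}"
        )
    return np.einsum("i,ijk->jk", w, basis.stacked())
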