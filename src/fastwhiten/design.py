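"""Design-matrix construction for block-design BOLD experiments.

Builds the regressors a first-level fMRI GLM needs: HRF-convolved task
boxcars, a discrete-cosine low-frequency drift basis implementing a 128 s
high-pass filter, Fourier-expanded cardiac/respiratory phase regressors with
the two amplitude (respiratory-volume and heart-rate) regressors, and the
intercept.  The assembled matrix carries column labels, a partition map
(task / drift / nuisance / intercept) and the sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json
import warnings

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "EventSchedule",
    "PhysioTrace",
    "DesignMatrix",
    "canonical_hrf",
    "block_regressor",
    "dct_drift_basis",
    "physio_fourier_regressors",
    "amplitude_regressors",
    "assemble_design",
]

#: Microtime oversampling of the volume grid used for HRF convolution.
MICROTIME = 16

#: Canonical double-gamma HRF parameters (seconds): response/undershoot peak
#: delays, their dispersions, peak:undershoot amplitude ratio, kernel length.
HRF_PARAMS = dict(
    peak_delay=6.0,
    undershoot_delay=16.0,
    peak_disp=1.0,
    undershoot_disp=1.0,
    ratio=6.0,
    length=32.0,
)


@dataclass
class EventSchedule:
    """Task events as onset/duration/condition triples (seconds)."""

    onsets: np.ndarray
    durations: np.ndarray
    conditions: list[str] | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float).ravel()
        self.durations = np.asarray(self.durations, dtype=float).ravel()
        if self.onsets.size != self.durations.size:
            raise ValueError("onsets and durations must have equal length")
        if self.onsets.size and (
            np.any(self.onsets < 0) or np.any(np.diff(self.onsets) < 0)
        ):
            raise ValueError("onsets must be non-negative and sorted")
        if self.onsets.size and np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        if self.conditions is None:
            self.conditions = ["task"] * self.onsets.size

    @classmethod
    def blocks(
        cls, n_blocks: int, on: float, off: float, start: float = 0.0
    ) -> "EventSchedule":
        """Regular on/off block schedule: ``n_blocks`` of ``on`` s separated
        by ``off`` s rest."""
        onsets = start + np.arange(n_blocks) * (on + off)
        return cls(onsets=onsets, durations=np.full(n_blocks, float(on)))

    @classmethod
    def from_bids(cls, path: str | Path) -> "EventSchedule":
        """Read a BIDS-style events table (onset, duration, trial_type)."""
        tab = pd.read_csv(path, sep="\t")
        cond = (
            tab["trial_type"].astype(str).tolist()
            if "trial_type" in tab.columns
            else None
        )
        return cls(
            onsets=tab["onset"].to_numpy(),
            durations=tab["duration"].to_numpy(),
            conditions=cond,
        )


@dataclass
class PhysioTrace:
    """Per-volume physiological state: cardiac/respiratory phase (radians,
    sampled mid-volume) plus optional amplitude streams."""

    time: np.ndarray
    cardiac_phase: np.ndarray
    respiratory_phase: np.ndarray
    respiration_amplitude: np.ndarray | None = None
    cardiac_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).ravel()
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("cardiac_phase", "respiratory_phase"):
            ph = np.mod(np.asarray(getattr(self, name), dtype=float).ravel(),
                        2 * np.pi)
            if ph.size != self.time.size:
                raise ValueError(f"{name} must match time length")
            setattr(self, name, ph)


PARTITIONS = ("task", "drift", "nuisance", "intercept")


@dataclass
class DesignMatrix:
    """Labeled, partitioned design matrix with its sampling interval."""

    matrix: np.ndarray
    column_labels: list[str]
    partition: dict[str, str]
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        n, k = self.matrix.shape
        if len(self.column_labels) != k:
            raise ValueError("one label per column required")
        if set(self.partition) != set(self.column_labels):
            raise ValueError("partition must map every column label")
        bad = set(self.partition.values()) - set(PARTITIONS)
        if bad:
            raise ValueError(f"unknown partition classes: {bad}")
        if np.any(np.all(self.matrix == 0, axis=0)):
            raise ValueError("design contains an all-zero column")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def columns_of(self, kind: str) -> np.ndarray:
        """Indices of columns in one partition class."""
        return np.array(
            [
                i
                for i, lab in enumerate(self.column_labels)
                if self.partition[lab] == kind
            ],
            dtype=int,
        )

    @property
    def intercept_index(self) -> int:
        idx = self.columns_of("intercept")
        if idx.size != 1:
            raise ValueError(
                f"expected exactly one intercept column, found {idx.size}"
            )
        return int(idx[0])

    def truncated(self, n: int) -> "DesignMatrix":
        """First ``n`` rows (time truncation), same columns."""
        if not (0 < n <= self.n_samples):
            raise ValueError("invalid truncation length")
        return DesignMatrix(
            matrix=self.matrix[:n],
            column_labels=list(self.column_labels),
            partition=dict(self.partition),
            tr=self.tr,
        )

    def decimated(self, d: int) -> "DesignMatrix":
        """Every ``d``-th row, TR scaled accordingly."""
        if d < 1:
            raise ValueError("decimation factor must be >= 1")
        return DesignMatrix(
            matrix=self.matrix[::d],
            column_labels=list(self.column_labels),
            partition=dict(self.partition),
            tr=self.tr * d,
        )

    def save(self, path: str | Path) -> None:
        """TSV matrix with header row + JSON sidecar (partition, TR)."""
        path = Path(path)
        pd.DataFrame(self.matrix, columns=self.column_labels).to_csv(
            path, sep="\t", index=False
        )
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"partition": self.partition, "tr": self.tr}, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "DesignMatrix":
        path = Path(path)
        tab = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            matrix=tab.to_numpy(dtype=float),
            column_labels=list(tab.columns),
            partition=meta["partition"],
            tr=float(meta["tr"]),
        )


def canonical_hrf(dt: float, **params) -> np.ndarray:
    """Canonical double-gamma haemodynamic response kernel.

    Difference of two gamma densities (response peaking near 5 s, undershoot
    near 15 s, amplitude ratio 6:1) sampled every ``dt`` seconds over 32 s and
    scaled to unit peak.
    """
    if not (0 < dt <= 4):
        raise ValueError("dt must be in (0, 4] seconds")
    p = {**HRF_PARAMS, **params}
    t = np.arange(0, p["length"] + dt / 2, dt)
    peak = gamma_dist.pdf(t, p["peak_delay"] / p["peak_disp"],
                          scale=p["peak_disp"])
    under = gamma_dist.pdf(t, p["undershoot_delay"] / p["undershoot_disp"],
                           scale=p["undershoot_disp"])
    h = peak - under / p["ratio"]
    return h / h.max()


def block_regressor(
    schedule: EventSchedule, n: int, tr: float
) -> np.ndarray:
    """HRF-convolved task regressor sampled at the ``n`` volume times.

    The boxcar is built on a fine grid (``tr / 16``), convolved with the
    canonical HRF, then read out at mid-volume acquisition times.
    """
    dt = tr / MICROTIME
    n_fine = n * MICROTIME
    box = np.zeros(n_fine)
    duration_total = n * tr
    for onset, dur in zip(schedule.onsets, schedule.durations):
        if onset >= duration_total:
            warnings.warn("event beyond series end truncated", stacklevel=2)
            continue
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + dur) / dt)), n_fine)
        box[i0:i1] = 1.0
    if schedule.onsets.size == 0 or not box.any():
        return np.zeros(n)
    h = canonical_hrf(dt)
    # unit-sum kernel: a sustained block plateaus at 1 whatever the microtime
    conv = np.convolve(box, h / h.sum())[:n_fine]
    # mid-volume sampling on the fine grid
    mid = (np.arange(n) * MICROTIME + MICROTIME // 2).astype(int)
    return conv[mid]


def dct_drift_basis(
    n: int, tr: float, cutoff: float = 128.0
) -> np.ndarray:
    """Discrete-cosine drift columns modelling fluctuations slower than
    ``cutoff`` seconds (the high-pass filter).

    Retains ``k = floor(2*n*tr/cutoff + 1) - 1`` non-constant cosines
    ``sqrt(2/n) * cos(pi*(2i+1)*j / (2n))``; the constant term is left to the
    intercept.  Columns are zero-mean with unit norm and mutually orthogonal.
    """
    if cutoff >= n * tr:
        warnings.warn(
            "cutoff period exceeds series duration; no drift columns",
            stacklevel=2,
        )
        return np.empty((n, 0))
    k = int(np.floor(2.0 * n * tr / cutoff + 1.0)) - 1
    i = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * (2 * i + 1) * j / (2.0 * n))
        for j in range(1, k + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def physio_fourier_regressors(
    trace: PhysioTrace, order: int = 3
) -> np.ndarray:
    """Fourier expansion of cardiac and respiratory phase.

    Columns ``sin(m*phi_c), cos(m*phi_c), sin(m*phi_r), cos(m*phi_r)`` for
    harmonics ``m = 1..order`` — 12 columns at the standard third order.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order != 3:
        warnings.warn(
            f"order={order} deviates from the standard third harmonic",
            stacklevel=2,
        )
    cols = []
    for phase in (trace.cardiac_phase, trace.respiratory_phase):
        for m in range(1, order + 1):
            cols.append(np.sin(m * phase))
            cols.append(np.cos(m * phase))
    return np.column_stack(cols)


def _respiration_response(t: np.ndarray) -> np.ndarray:
    """Respiratory response kernel: fast positive lobe (~3 s) followed by a
    broad negative lobe (~16 s)."""
    return 0.6 * t**2.1 * np.exp(-t / 1.6) - 0.0023 * t**3.54 * np.exp(
        -t / 4.25
    )


def _cardiac_response(t: np.ndarray) -> np.ndarray:
    """Cardiac response kernel: gamma-like peak near 4 s with a Gaussian dip
    near 12 s."""
    return 0.6 * t**2.7 * np.exp(-t / 1.6) - 16.0 / np.sqrt(
        2 * np.pi * 9.0
    ) * np.exp(-((t - 12.0) ** 2) / 18.0)


def amplitude_regressors(
    trace: PhysioTrace, volume_times: np.ndarray
) -> np.ndarray:
    """Respiration-volume and heart-rate regressors.

    Each stream is mean-centred and convolved with its response kernel
    (respiratory and cardiac response functions over 32 s), sampled at the
    supplied mid-volume times.  Missing streams are omitted with a warning.
    """
    volume_times = np.asarray(volume_times, dtype=float)
    if volume_times.size < 2:
        raise ValueError("need at least two volume times")
    dt = float(np.median(np.diff(volume_times)))
    kt = np.arange(0, 32.0 + dt / 2, dt)
    cols = []
    for stream, kernel in (
        (trace.respiration_amplitude, _respiration_response),
        (trace.cardiac_rate, _cardiac_response),
    ):
        if stream is None:
            warnings.warn("missing physiological stream omitted",
                          stacklevel=2)
            continue
        s = np.asarray(stream, dtype=float).ravel()
        if s.size != trace.time.size:
            raise ValueError("amplitude stream must match trace length")
        s = np.interp(volume_times, trace.time, s)
        s = s - s.mean()
        cols.append(np.convolve(s, kernel(kt))[: volume_times.size])
    if not cols:
        return np.empty((volume_times.size, 0))
    return np.column_stack(cols)


def assemble_design(
    task: list[np.ndarray] | np.ndarray | None,
    n: int,
    tr: float,
    drift: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    task_labels: list[str] | None = None,
) -> DesignMatrix:
    """Concatenate task / drift / nuisance columns and append the intercept.

    Task columns must be jointly full rank (error otherwise); rank deficiency
    among nuisance columns only warns — downstream fitting uses a
    pseudoinverse.
    """
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    partition: dict[str, str] = {}

    if task is not None:
        tcols = (
            [np.asarray(c, dtype=float) for c in task]
            if isinstance(task, (list, tuple))
            else [np.asarray(task[:, j], dtype=float)
                  for j in range(np.atleast_2d(task).shape[1])]
            if np.asarray(task).ndim == 2
            else [np.asarray(task, dtype=float)]
        )
        T = np.column_stack(tcols)
        if np.linalg.matrix_rank(T) < T.shape[1]:
            raise ValueError("task columns are rank deficient")
        for j, col in enumerate(tcols):
            lab = (
                task_labels[j]
                if task_labels is not None
                else ("task" if len(tcols) == 1 else f"task_{j}")
            )
            blocks.append(col)
            labels.append(lab)
            partition[lab] = "task"

    for mat, kind in ((drift, "drift"), (nuisance, "nuisance")):
        if mat is None or mat.size == 0:
            continue
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        if mat.shape[0] != n:
            raise ValueError(f"{kind} matrix row count must equal n")
        for j in range(mat.shape[1]):
            lab = f"{kind}_{j}"
            blocks.append(mat[:, j])
            labels.append(lab)
            partition[lab] = kind

    blocks.append(np.ones(n))
    labels.append("intercept")
    partition["intercept"] = "intercept"

    X = np.column_stack(blocks)
    if X.shape[0] != n:
        raise ValueError("column length does not match n")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("design matrix is rank deficient", stacklevel=2)
    return DesignMatrix(
        matrix=X, column_labels=labels, partition=partition, tr=tr
    )
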