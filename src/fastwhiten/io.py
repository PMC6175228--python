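"""Readers, writers and run configuration.

On-disk interchange is plain delimited text (voxel-by-time TSV) with JSON
sidecars; 4D NIfTI-1 images with a companion 3D mask are supported as an
alternative input, and statistic maps can be written back into the same
geometry.  In memory the package works with time-by-voxels arrays, so the
readers transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

try:
    import yaml
except ImportError:  # pragma: no cover
    yaml = None

__all__ = [
    "TimeSeriesData",
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "write_stats_table",
    "write_nifti_map",
    "load_config",
]


class FormatError(ValueError):
    """Unreadable or inconsistent input file."""


@dataclass
class TimeSeriesData:
    """Voxel time courses plus the metadata needed to write results back."""

    Y: np.ndarray                 # time x voxels
    tr: float
    voxel_index: np.ndarray | None = None   # flat indices into the mask grid
    mask_image: object = None               # nibabel image of the mask
    source: str = ""

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.Y.shape[1]


def _sidecar_tr(path: Path, default: float | None) -> float | None:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        for key in ("tr", "TR", "RepetitionTime"):
            if key in meta:
                return float(meta[key])
    return default


def read_timeseries(
    path: str | Path,
    mask: str | Path | None = None,
    tr: float | None = None,
) -> TimeSeriesData:
    """Read a voxel-by-time TSV table or a 4D NIfTI-1 image with a mask.

    For TSV input the repetition time comes from a same-stem ``.json``
    sidecar (keys ``tr``/``TR``/``RepetitionTime``) or the ``tr`` argument;
    for NIfTI it defaults to the header ``pixdim[4]``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix in (".nii", ".gz") or "".join(path.suffixes[-2:]) == ".nii.gz":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise FormatError(f"{path}: expected a 4D image, got {data.ndim}D")
        if mask is None:
            raise FormatError(f"{path}: a companion 3D mask is required")
        mimg = nib.load(str(mask))
        mdat = np.asanyarray(mimg.dataobj)
        if mdat.shape != data.shape[:3]:
            raise FormatError(
                f"{mask}: mask shape {mdat.shape} does not match image grid "
                f"{data.shape[:3]}"
            )
        sel = mdat > 0
        if not sel.any():
            raise FormatError(f"{mask}: mask selects no voxels")
        Y = data[sel].T.astype(float)            # time x voxels
        header_tr = float(img.header["pixdim"][4])
        return TimeSeriesData(
            Y=Y,
            tr=tr if tr is not None else header_tr,
            voxel_index=np.flatnonzero(sel.ravel()),
            mask_image=mimg,
            source=str(path),
        )
    # delimited table, voxels x time
    try:
        tab = pd.read_csv(path, sep=None, engine="python", header=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: {exc}") from exc
    first = tab.iloc[0]
    if first.map(lambda x: isinstance(x, str)).any():
        tab = tab.iloc[1:].reset_index(drop=True)
    arr = tab.to_numpy(dtype=float)
    eff_tr = _sidecar_tr(path, tr)
    return TimeSeriesData(
        Y=arr.T, tr=eff_tr if eff_tr is not None else 1.0, source=str(path)
    )


def write_timeseries(path: str | Path, Y: np.ndarray, tr: float) -> None:
    """Write a time-by-voxels array as a voxel-by-time TSV + JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(Y, dtype=float).T, delimiter="\t",
               fmt="%.10g")
    path.with_suffix(".json").write_text(json.dumps({"tr": tr}, indent=2))


def write_stats_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_nifti_map(
    path: str | Path, values: np.ndarray, data: TimeSeriesData
) -> None:
    """Write a per-voxel statistic back into the mask geometry."""
    if data.mask_image is None or data.voxel_index is None:
        raise FormatError("no mask geometry available for map output")
    import nibabel as nib

    shape = data.mask_image.shape
    out = np.zeros(int(np.prod(shape)), dtype=float)
    out[data.voxel_index] = values
    img = nib.Nifti1Image(
        out.reshape(shape), data.mask_image.affine, None
    )
    nib.save(img, str(path))


_MODEL_SPECS = ("none", "ar1", "fast")


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    data: str | None = None
    mask: str | None = None
    design: str | None = None
    model: str = "ar1"
    contrasts: dict[str, list[float]] = field(default_factory=dict)
    n_points: int = 100
    max_lag: int = 20
    fdr_q: float = 0.05
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        validate_model_spec(self.model)
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")
        if self.max_lag >= self.n_points:
            raise ValueError("n_points must exceed max_lag")


def validate_model_spec(model: str) -> None:
    stem = model.split(":")[0]
    if stem not in _MODEL_SPECS:
        raise ValueError(f"unknown model spec {model!r}")
    if stem == "fast":
        try:
            p = int(model.split("p=")[1])
        except (IndexError, ValueError) as exc:
            raise ValueError("fast model requires :p=K") from exc
        if not (1 <= p <= 9):
            raise ValueError("fast p must be in [1, 9]")


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        if yaml is None:  # pragma: no cover
            raise FormatError("YAML support requires pyyaml")
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return RunConfig(**raw)
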