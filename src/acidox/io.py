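"""NIfTI + JSON-sidecar I/O.

4-D stacks (z-spectrum, echo series, DSC) travel as NIfTI volumes with a
JSON sidecar carrying the acquisition metadata the arrays cannot: offset
lists, echo timing (seconds, or milliseconds with an explicit unit tag),
baseline ranges.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .cest import ZSpectrumStack
from .dsc import DscTimeSeries
from .sage import SageEchoSeries

__all__ = [
    "save_volume",
    "load_volume",
    "save_zspectrum",
    "load_zspectrum",
    "save_sage",
    "load_sage",
    "save_dsc",
    "load_dsc",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    for i, v in enumerate(voxel_size_mm[:3]):
        aff[i, i] = v
    return aff


def save_volume(data: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, np.float64), _affine(voxel_size_mm)), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def _timing_in_seconds(sidecar: dict, key: str):
    vals = np.asarray(sidecar[key], float)
    if sidecar.get("time_unit", "s") == "ms":
        vals = vals / 1000.0
    return vals


def save_zspectrum(z: ZSpectrumStack, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """4-D stack with the S0 frame appended last; offsets in the sidecar."""
    path = Path(path)
    stack = np.concatenate([z.signals, z.s0[..., None]], axis=-1)
    save_volume(stack, path, voxel_size_mm)
    sidecar = {
        "offsets_ppm": z.offsets_ppm.tolist(),
        "s0_frame_index": stack.shape[-1] - 1,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    save_volume(z.mask.astype(np.uint8), path.parent / (path.stem.split(".")[0] + "_mask.nii"), voxel_size_mm)


def load_zspectrum(path) -> ZSpectrumStack:
    path = Path(path)
    stack, _ = load_volume(path)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    offsets = np.asarray(sidecar["offsets_ppm"], float)
    i_s0 = int(sidecar["s0_frame_index"])
    s0 = stack[..., i_s0]
    signals = np.delete(stack, i_s0, axis=-1)
    mask_path = path.parent / (path.stem.split(".")[0] + "_mask.nii")
    if mask_path.exists():
        mask = load_volume(mask_path)[0].astype(bool)
    else:
        mask = s0 > 0
    order = np.argsort(offsets)
    return ZSpectrumStack(offsets[order], signals[..., order], s0, mask)


def save_sage(series: SageEchoSeries, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    path = Path(path)
    save_volume(series.signals, path, voxel_size_mm)
    sidecar = {
        "echo_times": series.echo_times_s.tolist(),
        "te_se": series.te_se_s,
        "time_unit": "s",
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    save_volume(series.mask.astype(np.uint8), path.parent / (path.stem.split(".")[0] + "_mask.nii"), voxel_size_mm)


def load_sage(path) -> SageEchoSeries:
    path = Path(path)
    signals, _ = load_volume(path)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    te = _timing_in_seconds(sidecar, "echo_times")
    te_se = float(np.asarray(_timing_in_seconds(sidecar, "te_se")).reshape(()))
    mask_path = path.parent / (path.stem.split(".")[0] + "_mask.nii")
    if mask_path.exists():
        mask = load_volume(mask_path)[0].astype(bool)
    else:
        mask = signals.min(axis=-1) > 0
    return SageEchoSeries(te, te_se, signals, mask)


def save_dsc(ts: DscTimeSeries, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    path = Path(path)
    save_volume(ts.signals, path, voxel_size_mm)
    sidecar = {
        "time": ts.time_s.tolist(),
        "te": ts.te_s,
        "time_unit": "s",
        "baseline": list(ts.baseline),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    save_volume(ts.mask.astype(np.uint8), path.parent / (path.stem.split(".")[0] + "_mask.nii"), voxel_size_mm)


def load_dsc(path) -> DscTimeSeries:
    path = Path(path)
    signals, _ = load_volume(path)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    time_s = _timing_in_seconds(sidecar, "time")
    te = float(np.asarray(_timing_in_seconds(sidecar, "te")).reshape(()))
    mask_path = path.parent / (path.stem.split(".")[0] + "_mask.nii")
    if mask_path.exists():
        mask = load_volume(mask_path)[0].astype(bool)
    else:
        mask = signals.min(axis=-1) > 0
    return DscTimeSeries(time_s, te, signals, tuple(sidecar["baseline"]), mask)
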