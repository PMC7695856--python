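"""Readers/writers and ROI curve extraction.

NIfTI is the container for MRI volumes (4-D series, masks, parametric
maps), TIFF for microscopy, CSV for tables and JSON for configuration and
provenance.  Frame times are carried in a JSON sidecar/manifest because
the NIfTI header has no native slot for a dynamic schedule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .protocol import AcquisitionProtocol
from .forward_model import SignalCurve

__all__ = [
    "DceSeries",
    "RoiSet",
    "read_series",
    "write_series",
    "read_labels",
    "write_volume",
    "roi_mean_curve",
    "curve_to_csv",
    "write_parametric_maps",
    "write_provenance",
]


@dataclass
class DceSeries:
    """4-D dynamic series with spatial metadata and acquisition protocol."""

    data: np.ndarray
    affine: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError(f"series data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[3] != self.protocol.n_frames:
            raise ValueError(
                f"frame dimension {self.data.shape[3]} does not match protocol "
                f"frame count {self.protocol.n_frames}"
            )

    @property
    def voxel_dims_um(self):
        return tuple(1000.0 * np.abs(np.diag(self.affine)[:3]))


@dataclass
class RoiSet:
    """Integer label volume with an optional label -> name map."""

    labels: np.ndarray
    names: dict

    def __post_init__(self):
        if self.labels.ndim != 3:
            raise ValueError("ROI labels must be a 3-D volume")
        if np.any(self.labels < 0):
            raise ValueError("ROI labels must be nonnegative")


def _affine_from_protocol(protocol: AcquisitionProtocol) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = (d / 1000.0 for d in protocol.voxel_dims)  # um -> mm
    return aff


def write_series(series: DceSeries, path) -> None:
    """Write a 4-D series as NIfTI plus a JSON sidecar with frame times."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float64), series.affine)
    nib.save(img, path)
    sidecar = {
        "frame_times_s": list(series.protocol.frame_times),
        "tr_s": series.protocol.tr,
        "te_s": series.protocol.te,
        "flip_angle_rad": series.protocol.flip_angle,
        "voxel_dims_um": list(series.protocol.voxel_dims),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_series(path, protocol: AcquisitionProtocol | None = None) -> DceSeries:
    """Read a 4-D NIfTI series; frame times come from the sidecar if present.

    If neither a sidecar nor an explicit protocol is supplied, the default
    protocol is attached (matching frame count required).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path} holds a {data.ndim}-D image where a 4-D series is required")
    if protocol is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            protocol = AcquisitionProtocol(
                tr=meta.get("tr_s", 0.010),
                te=meta.get("te_s", 0.003),
                flip_angle=meta.get("flip_angle_rad", float(np.deg2rad(15.0))),
                frame_times=tuple(meta["frame_times_s"]),
                voxel_dims=tuple(meta.get("voxel_dims_um", (150.0, 150.0, 625.0))),
            )
        else:
            protocol = AcquisitionProtocol()
    return DceSeries(data=data, affine=img.affine, protocol=protocol)


def read_labels(path) -> np.ndarray:
    """Read a 3-D integer label/mask volume from NIfTI."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} holds a {data.ndim}-D image where a 3-D volume is required")
    return np.rint(data).astype(np.int32)


def write_volume(data, affine, path) -> None:
    data = np.asarray(data)
    dtype = np.int32 if np.issubdtype(data.dtype, np.integer) else np.float64
    nib.save(nib.Nifti1Image(data.astype(dtype), affine), Path(path))


def roi_mean_curve(series: DceSeries, rois: RoiSet, label: int) -> SignalCurve:
    """Mean signal over all voxels of one ROI label, per frame."""
    if rois.labels.shape != series.data.shape[:3]:
        raise ValueError("ROI volume shape does not match series spatial shape")
    sel = rois.labels == label
    if not np.any(sel):
        raise ValueError(f"ROI label {label} selects no voxels")
    values = series.data[sel].mean(axis=0)
    return SignalCurve(values=values, frame_times=series.protocol.times)


def curve_to_csv(curve: SignalCurve, path) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(curve.values.size),
            "time_s": curve.frame_times,
            "mean_SI": curve.values,
        }
    ).to_csv(Path(path), index=False)


def write_parametric_maps(maps, affine, out_dir, prefix: str = "fit") -> list:
    """Write fitted maps as NIfTI; aggregate rates also exported as T2* (ms).

    Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in maps.as_dict().items():
        p = out_dir / f"{prefix}_{name}.nii.gz"
        write_volume(arr, affine, p)
        written.append(p)
        if name.startswith("r2agg"):
            with np.errstate(divide="ignore"):
                t2 = np.where(arr > 0, 1000.0 / np.where(arr > 0, arr, 1.0), 0.0)
            pt = out_dir / f"{prefix}_{name.replace('r2agg', 't2star_ms')}.nii.gz"
            write_volume(t2, affine, pt)
            written.append(pt)
    pm = out_dir / f"{prefix}_mask.nii.gz"
    write_volume(maps.mask.astype(np.int32), affine, pm)
    written.append(pm)
    return written


def write_provenance(path, inputs: dict, config: dict, seed=None) -> None:
    """JSON provenance record: inputs, config hash, package version, seed."""
    from . import __version__

    config_json = json.dumps(config, sort_keys=True, default=str)
    record = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "package_version": __version__,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
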