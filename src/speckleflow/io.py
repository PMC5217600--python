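"""Standard-format I/O: multi-page TIFF stacks with JSON sidecars, NIfTI
volumes, CSV score tables and area series."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .lesion import VolumeImage
from .perfusion import AreaSeries
from .registration import ShiftEstimate
from .stack import SpeckleStack
from .stats import NSSRecord

__all__ = [
    "write_stack",
    "read_stack",
    "write_volume_nifti",
    "read_volume_nifti",
    "write_volume_tiff",
    "read_volume_tiff",
    "write_nss_csv",
    "read_nss_csv",
    "write_area_series_csv",
    "read_area_series_csv",
    "write_map_tiff",
    "write_shift_log",
]

INTENSITY_SCALE = 1000.0  # counts per unit mean intensity in 16-bit TIFFs


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: SpeckleStack, path: str | Path) -> None:
    """Speckle stack as 16-bit multi-page TIFF + JSON metadata sidecar."""
    path = Path(path)
    counts = np.clip(np.round(stack.frames * INTENSITY_SCALE), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, counts, photometric="minisblack")
    meta = {
        "exposure_s": stack.exposure_s,
        "frame_rate_hz": stack.frame_rate_hz,
        "pixel_pitch_mm": stack.pixel_pitch_mm,
        "intensity_scale": INTENSITY_SCALE,
        "timestamps_s": stack.timestamps_s.tolist(),
        "seed": stack.seed,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_stack(path: str | Path) -> SpeckleStack:
    path = Path(path)
    counts = tifffile.imread(path)
    if counts.ndim == 2:
        counts = counts[None]
    meta = json.loads(_sidecar(path).read_text())
    return SpeckleStack(
        frames=counts.astype(np.float64) / meta["intensity_scale"],
        exposure_s=meta["exposure_s"],
        frame_rate_hz=meta["frame_rate_hz"],
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        timestamps_s=np.asarray(meta["timestamps_s"]),
        seed=meta.get("seed"),
    )


def write_volume_nifti(vol: VolumeImage, path: str | Path) -> None:
    """Slice stack as NIfTI with voxel dimensions in the header."""
    path = Path(path)
    # store as (x, y, z) with the slice axis last
    data = np.transpose(vol.slices, (2, 1, 0)).astype(np.float32)
    affine = np.diag([vol.in_plane_pitch_mm, vol.in_plane_pitch_mm, vol.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((vol.in_plane_pitch_mm, vol.in_plane_pitch_mm, vol.slice_thickness_mm))
    nib.save(img, str(path))
    _sidecar(path).write_text(json.dumps({"modality": vol.modality, "true_volume_mm3": vol.true_volume_mm3}))


def read_volume_nifti(path: str | Path) -> VolumeImage:
    path = Path(path)
    img = nib.load(str(path))
    zx, zy, zz = img.header.get_zooms()[:3]
    if abs(zx - zy) > 1e-9:
        raise ValueError("anisotropic in-plane voxels are not supported")
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    data = np.transpose(np.asarray(img.dataobj, dtype=np.float64), (2, 1, 0))
    return VolumeImage(
        slices=data,
        slice_thickness_mm=float(zz),
        in_plane_pitch_mm=float(zx),
        modality=meta.get("modality", "MRI-like"),
        true_volume_mm3=meta.get("true_volume_mm3"),
    )


def write_volume_tiff(vol: VolumeImage, path: str | Path) -> None:
    """Slice stack as multi-page float TIFF + JSON geometry sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.slices.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps(
            {
                "slice_thickness_mm": vol.slice_thickness_mm,
                "in_plane_pitch_mm": vol.in_plane_pitch_mm,
                "modality": vol.modality,
                "true_volume_mm3": vol.true_volume_mm3,
            }
        )
    )


def read_volume_tiff(path: str | Path) -> VolumeImage:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(_sidecar(path).read_text())
    return VolumeImage(
        slices=data.astype(np.float64),
        slice_thickness_mm=meta["slice_thickness_mm"],
        in_plane_pitch_mm=meta["in_plane_pitch_mm"],
        modality=meta.get("modality", "MRI-like"),
        true_volume_mm3=meta.get("true_volume_mm3"),
    )


NSS_COLUMNS = ["rat_id", "examiner_id", "trial_index", "motor", "sensory", "beam", "reflex"]


def write_nss_csv(records: list[NSSRecord], path: str | Path) -> None:
    rows = [asdict(r) for r in records]
    pd.DataFrame(rows)[NSS_COLUMNS].to_csv(path, index=False)


def read_nss_csv(path: str | Path) -> list[NSSRecord]:
    df = pd.read_csv(path)
    return [
        NSSRecord(
            rat_id=str(row.rat_id),
            examiner_id=str(row.examiner_id),
            trial_index=int(row.trial_index),
            motor=int(row.motor),
            sensory=int(row.sensory),
            beam=int(row.beam),
            reflex=int(row.reflex),
        )
        for row in df.itertuples()
    ]


def write_area_series_csv(cbf50: AreaSeries, cbfplus: AreaSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_min": cbf50.times_min,
            "cbf50_mm2": cbf50.areas_mm2,
            "cbfplus_mm2": cbfplus.areas_mm2,
        }
    ).to_csv(path, index=False)


def read_area_series_csv(path: str | Path, pixel_pitch_mm: float = float("nan")) -> tuple[AreaSeries, AreaSeries]:
    df = pd.read_csv(path)
    t = df["time_min"].to_numpy()
    return (
        AreaSeries(t, df["cbf50_mm2"].to_numpy(), "CBF_50", pixel_pitch_mm),
        AreaSeries(t, df["cbfplus_mm2"].to_numpy(), "CBF_plus", pixel_pitch_mm),
    )


def write_map_tiff(arr: np.ndarray, path: str | Path) -> None:
    """Float map (contrast, flow, normalized flow) as 32-bit TIFF."""
    tifffile.imwrite(Path(path), arr.astype(np.float32), photometric="minisblack")


def write_shift_log(shifts: list[ShiftEstimate], path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(len(shifts)),
            "dy_px": [s.dy for s in shifts],
            "dx_px": [s.dx for s in shifts],
            "confidence": [s.confidence for s in shifts],
        }
    ).to_csv(path, index=False)
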