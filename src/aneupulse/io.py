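"""Reading and writing of 4D-CTA image series and analysis results.

A time-resolved CT angiography acquisition is represented as an ordered
sequence of :class:`VolumeStack` objects, one reconstructed 3D volume per
timepoint.  Series can be stored either as one directory of classic
single-frame CT DICOM slices per timepoint, or as a single 4D NIfTI-1 file.

Conventions
-----------
* Voxel arrays are indexed ``[x, y, z]``; DICOM rows map to the y axis and
  columns to the x axis.
* Voxel indices are 0-based and physical positions refer to voxel centers.
* All volumes are expressed in mm³, all HU values on the calibrated
  Hounsfield scale (stored value × rescale slope + intercept).
* A stack's timestamp is the center of its reconstruction footprint, on the
  scanner clock, in seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_RESCALE_INTERCEPT = -1024.0


@dataclass
class VolumeStack:
    """One reconstructed 3D CT volume with geometry and timing metadata.

    Parameters
    ----------
    voxels:
        3D array of HU values, indexed ``[x, y, z]``.
    spacing:
        Voxel size ``(X_v, Y_v, Z_v)`` in mm.
    origin:
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    timestamp:
        Mid-reconstruction time on the scanner clock, seconds.
    index:
        Position of this stack in its series.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    timestamp: float = 0.0
    index: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SeriesManifest:
    """An ordered, validated 4D series plus acquisition metadata."""

    stacks: list[VolumeStack]
    time_increment: float  # ms
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.array([s.timestamp for s in self.stacks])
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-3:  # 1 ms tolerance on constant increment
                raise ValueError(
                    f"non-constant time increment: spread {np.ptp(dt) * 1e3:.3f} ms"
                )

    @property
    def times(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.stacks])

    @property
    def span(self) -> float:
        t = self.times
        return float(t[-1] - t[0]) if len(t) else 0.0


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _format_tm(seconds: float) -> str:
    h, rem = divmod(seconds, 3600.0)
    m, s = divmod(rem, 60.0)
    return f"{int(h):02d}{int(m):02d}{s:09.6f}"


def _parse_tm(tm: str) -> float:
    return int(tm[0:2]) * 3600 + int(tm[2:4]) * 60 + float(tm[4:])


def _slice_dataset(stack: VolumeStack, k: int, series_uid: str, study_uid: str) -> Dataset:
    sx, sy, sz = stack.spacing
    ox, oy, oz = stack.origin
    ds = Dataset()
    ds.SOPClassUID = CT_IMAGE_STORAGE
    ds.SOPInstanceUID = generate_uid()
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    ds.SeriesNumber = stack.index
    ds.InstanceNumber = k + 1
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [ox, oy, oz + k * sz]
    ds.SliceThickness = sz
    ds.PixelSpacing = [sy, sx]  # [row spacing (y), column spacing (x)]
    ds.AcquisitionTime = _format_tm(stack.timestamp)
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = _RESCALE_INTERCEPT
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    plane = stack.voxels[:, :, k].T  # rows = y, cols = x
    stored = np.round(plane - _RESCALE_INTERCEPT).astype(np.int16)
    ds.Rows, ds.Columns = stored.shape
    ds.PixelData = stored.tobytes()

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CT_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    return ds


def write_series(
    stacks: list[VolumeStack],
    path: str | Path,
    format: str = "dicom_dirs",
    sidecar: dict | None = None,
) -> Path:
    """Write a series either as one DICOM directory per timepoint or as 4D NIfTI.

    ``sidecar``, when given, is written as ``series.json`` next to the image
    data (used to record the generating configuration and ground-truth event
    times of synthetic series).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "dicom_dirs":
        study_uid = generate_uid()
        for stack in stacks:
            d = path / f"t{stack.index:04d}"
            d.mkdir(exist_ok=True)
            series_uid = generate_uid()
            for k in range(stack.shape[2]):
                ds = _slice_dataset(stack, k, series_uid, study_uid)
                ds.save_as(d / f"slice{k:04d}.dcm", enforce_file_format=True)
    elif format == "nifti4d":
        data = np.stack([s.voxels for s in stacks], axis=3).astype(np.float32)
        sx, sy, sz = stacks[0].spacing
        affine = np.diag([sx, sy, sz, 1.0])
        affine[:3, 3] = stacks[0].origin
        img = nib.Nifti1Image(data, affine)
        dt = stacks[1].timestamp - stacks[0].timestamp if len(stacks) > 1 else 1.0
        img.header.set_zooms((sx, sy, sz, dt))
        img.header["toffset"] = stacks[0].timestamp
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, path / "series.nii")
    else:
        raise ValueError(f"unknown format {format!r}")
    if sidecar is not None:
        (path / "series.json").write_text(json.dumps(sidecar, indent=2))
    return path


def _load_stack_dicom(d: Path, index: int) -> VolumeStack:
    files = sorted(d.glob("*.dcm"))
    if not files:
        raise ValueError(f"stack {index}: no DICOM slices found in {d}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    row_sp = [(float(s.PixelSpacing[0]), float(s.PixelSpacing[1])) for s in slices]
    if len(set(row_sp)) != 1:
        raise ValueError(f"stack {index}: inconsistent in-plane spacing across slices")
    zpos = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    dz = np.diff(zpos)
    if len(dz):
        sz = float(np.median(dz))
        if np.any(np.abs(dz - sz) > 0.01 * sz):
            k = int(np.argmax(np.abs(dz - sz)))
            raise ValueError(
                f"stack {index}: missing or irregular slice between z={zpos[k]:.3f} "
                f"and z={zpos[k + 1]:.3f} mm"
            )
    else:
        sz = float(slices[0].SliceThickness)
    sy, sx = row_sp[0]
    planes = []
    for s in slices:
        hu = s.pixel_array.astype(float) * float(s.RescaleSlope) + float(s.RescaleIntercept)
        planes.append(hu.T)  # back to [x, y]
    voxels = np.stack(planes, axis=2)
    s0 = slices[0]
    origin = (
        float(s0.ImagePositionPatient[0]),
        float(s0.ImagePositionPatient[1]),
        float(s0.ImagePositionPatient[2]),
    )
    return VolumeStack(
        voxels=voxels,
        spacing=(sx, sy, sz),
        origin=origin,
        timestamp=_parse_tm(str(s0.AcquisitionTime)),
        index=index,
    )


def load_series(path: str | Path, format: str = "dicom_dirs") -> SeriesManifest:
    """Load a 4D series and validate its geometry and timing.

    HU calibration is applied from the rescale metadata.  Stacks are ordered
    by timestamp; a missing slice inside a stack or non-monotone timestamps
    raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dicom_dirs":
        dirs = sorted(p for p in path.iterdir() if p.is_dir() and p.name.startswith("t"))
        if not dirs:
            raise ValueError(f"no timepoint directories under {path}")
        stacks = [_load_stack_dicom(d, i) for i, d in enumerate(dirs)]
    elif format == "nifti4d":
        img = nib.load(path / "series.nii" if path.is_dir() else path)
        data = np.asanyarray(img.dataobj).astype(float)
        if data.ndim != 4:
            raise ValueError("expected a 4D NIfTI image")
        zooms = img.header.get_zooms()
        sx, sy, sz = (float(z) for z in zooms[:3])
        dt = float(zooms[3])
        t0 = float(img.header["toffset"])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        stacks = [
            VolumeStack(
                voxels=data[..., i],
                spacing=(sx, sy, sz),
                origin=origin,
                timestamp=t0 + i * dt,
                index=i,
            )
            for i in range(data.shape[3])
        ]
    else:
        raise ValueError(f"unknown format {format!r}")
    stacks.sort(key=lambda s: s.timestamp)
    for i, s in enumerate(stacks):
        s.index = i
    times = np.array([s.timestamp for s in stacks])
    increment = float(np.median(np.diff(times)) * 1e3) if len(times) > 1 else math.nan
    acquisition = {}
    sj = (path / "series.json") if path.is_dir() else None
    if sj is not None and sj.exists():
        acquisition = json.loads(sj.read_text()).get("acquisition", {})
    return SeriesManifest(stacks=stacks, time_increment=increment, acquisition=acquisition)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def save_results(results, path: str | Path) -> dict[str, Path]:
    """Write analysis outputs: the volume time series, per-pulse events and a
    JSON summary (pulsation statistics, detection verdict and dose block).

    ``results`` is a :class:`aneupulse.pipeline.RunResult` or any object with
    the same ``series`` / ``events`` / ``summary`` / ``dose`` attributes.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    ser = results.series
    norm = ser.normalized_volumes
    df = pd.DataFrame(
        {
            "index": np.arange(len(ser.times)),
            "time_s": ser.times,
            "volume_mm3": ser.volumes,
            "normalized_volume_mm3": norm if norm is not None else np.nan,
        }
    )
    out["series"] = path / "volume_series.csv"
    df.to_csv(out["series"], index=False)

    rows = []
    for ev in results.events:
        rows.append(
            {
                "zenith_time_s": ev.zenith[0],
                "zenith_volume_mm3": ev.zenith[1],
                "nadir_times_s": ";".join(f"{t:.6g}" for t, _ in ev.nadirs),
                "nadir_volumes_mm3": ";".join(f"{v:.6g}" for _, v in ev.nadirs),
                "amplitude_mm3": ev.amplitude,
                "mode": ev.mode,
            }
        )
    cols = [
        "zenith_time_s",
        "zenith_volume_mm3",
        "nadir_times_s",
        "nadir_volumes_mm3",
        "amplitude_mm3",
        "mode",
    ]
    out["events"] = path / "pulse_events.csv"
    pd.DataFrame(rows, columns=cols).to_csv(out["events"], index=False)

    summary = dict(results.summary.as_dict())
    if getattr(results, "dose", None) is not None:
        summary["dose"] = results.dose.as_dict()
    out["summary"] = path / "summary.json"
    out["summary"].write_text(json.dumps(summary, indent=2))
    return out
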