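"""Readers, writers and shared coordinate conventions.

All physical coordinates are millimetres in (SI, AP, LR) axis order —
superior–inferior first because it is the dominant axis of respiratory
target motion. Voxel indices are 0-based and refer to voxel *centers*:
the position of voxel (i, j, k) is ``origin + index * spacing``.

Supported external representations:

* phase-volume sets as either a directory of single-file NIfTI volumes
  (``phase_00.nii.gz`` … ``phase_09.nii.gz``) with a JSON sidecar, or a
  directory of per-phase DICOM CT series subdirectories;
* surrogate / target traces as 2-column CSV (``time_s,amplitude_mm``);
* 4-axis motion-controller waveforms as a plain-text table resampled to
  a constant rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImageGrid",
    "PhaseVolumeSet",
    "Trace",
    "read_phase_series",
    "write_phase_series",
    "read_trace_csv",
    "write_trace_csv",
    "write_controller_waveform",
    "read_controller_waveform",
]

#: sampling rate (Hz) of the controller-waveform dialect
CONTROLLER_RATE_HZ = 25.0
#: number of decimals written per sample (formatting quantum 1e-4 mm / s)
CONTROLLER_DECIMALS = 4

AXES = ("SI", "AP", "LR")


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3D sampling grid in the (SI, AP, LR) mm frame.

    Parameters
    ----------
    spacing : 3-tuple of float
        mm per voxel along (SI, AP, LR); all > 0.
    origin : 3-tuple of float
        mm position of the center of voxel (0, 0, 0).
    size : 3-tuple of int
        voxel counts along (SI, AP, LR); all >= 1.
    """

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    size: tuple[int, int, int]

    def __post_init__(self):
        if len(self.spacing) != 3 or len(self.origin) != 3 or len(self.size) != 3:
            raise ValueError("spacing, origin and size must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be > 0, got {self.spacing}")
        if any(n < 1 for n in self.size):
            raise ValueError(f"sizes must be >= 1, got {self.size}")
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "size", tuple(int(n) for n in self.size))

    def index_to_mm(self, index) -> np.ndarray:
        """Physical mm position of (possibly fractional) voxel indices."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def mm_to_index(self, pos) -> np.ndarray:
        """Fractional voxel index of an mm position."""
        return (np.asarray(pos, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def nearest_index(self, pos) -> tuple[int, int, int]:
        idx = np.rint(self.mm_to_index(pos)).astype(int)
        return tuple(int(v) for v in idx)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center mm coordinates along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.size[axis])

    @property
    def center_mm(self) -> np.ndarray:
        return self.index_to_mm([(n - 1) / 2 for n in self.size])

    def extent_mm(self) -> list[tuple[float, float]]:
        """Outer edges (min, max) of the grid along each axis, in mm."""
        return [
            (
                self.origin[a] - self.spacing[a] / 2,
                self.origin[a] + self.spacing[a] * (self.size[a] - 0.5),
            )
            for a in range(3)
        ]


MODALITIES = ("CT4D", "CBCT4D", "SYNTH")


@dataclass
class PhaseVolumeSet:
    """An ordered set of respiratory-phase volumes sharing one grid.

    Phase label ``k`` denotes the bin at ``k * 100 / n_phases`` % of the
    respiratory cycle (0% … 90% for the usual 10 phases).
    """

    volumes: list[np.ndarray]
    grid: ImageGrid
    phase_labels: list[int] = field(default_factory=list)
    modality: str = "SYNTH"

    def __post_init__(self):
        if not self.phase_labels:
            self.phase_labels = list(range(len(self.volumes)))
        if len(self.volumes) != len(self.phase_labels):
            raise ValueError("one phase label per volume required")
        if any(b <= a for a, b in zip(self.phase_labels, self.phase_labels[1:])):
            raise ValueError("phase labels must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        shape = tuple(self.grid.size)
        for lab, v in zip(self.phase_labels, self.volumes):
            if v.shape != shape:
                raise ValueError(
                    f"phase {lab} volume shape {v.shape} != grid size {shape}"
                )

    @property
    def n_phases(self) -> int:
        return len(self.volumes)


@dataclass(frozen=True)
class Trace:
    """A sampled 1D displacement signal: times in s, values in mm."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be 1D of equal length")
        if len(t) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def sample_rate(self) -> float:
        dt = np.diff(self.times)
        return 1.0 / float(np.median(dt))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dt = np.diff(self.times)
        return bool(np.allclose(dt, dt[0], rtol=rtol))

    def __call__(self, t) -> np.ndarray:
        """Linear interpolation; errors outside the sampled range."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError(
                f"time outside trace range [{self.times[0]}, {self.times[-1]}]"
            )
        return np.interp(t, self.times, self.values)


# ---------------------------------------------------------------------------
# phase-volume series I/O
# ---------------------------------------------------------------------------


def _sidecar_path(directory: Path) -> Path:
    return directory / "series_meta.json"


def write_phase_series(
    pvs: PhaseVolumeSet, path, format: str = "nifti"
) -> Path:
    """Write a phase set as NIfTI volumes + JSON sidecar or DICOM series.

    ``format='nifti'`` writes ``phase_XX.nii.gz`` files plus a
    ``series_meta.json`` sidecar carrying spacing/origin/modality;
    ``format='dicom'`` writes one CT series subdirectory per phase.
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    if format == "nifti":
        return _write_nifti_series(pvs, directory)
    if format == "dicom":
        return _write_dicom_series(pvs, directory)
    raise ValueError(f"unknown format {format!r}")


def _write_nifti_series(pvs: PhaseVolumeSet, directory: Path) -> Path:
    import nibabel as nib

    # axis order on disk matches memory: (SI, AP, LR); affine records spacing
    affine = np.diag(list(pvs.grid.spacing) + [1.0])
    affine[:3, 3] = pvs.grid.origin
    for lab, vol in zip(pvs.phase_labels, pvs.volumes):
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine)
        nib.save(img, directory / f"phase_{lab:02d}.nii.gz")
    meta = {
        "spacing_mm": list(pvs.grid.spacing),
        "origin_mm": list(pvs.grid.origin),
        "size_voxels": list(pvs.grid.size),
        "phase_labels": list(pvs.phase_labels),
        "modality": pvs.modality,
        "axis_order": "SI,AP,LR",
    }
    _sidecar_path(directory).write_text(json.dumps(meta, indent=2))
    return directory


def _write_dicom_series(pvs: PhaseVolumeSet, directory: Path) -> Path:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    study_uid = generate_uid()
    si_sp, ap_sp, lr_sp = pvs.grid.spacing
    for lab, vol in zip(pvs.phase_labels, pvs.volumes):
        sub = directory / f"phase_{lab:02d}"
        sub.mkdir(parents=True, exist_ok=True)
        series_uid = generate_uid()
        vol = np.asarray(vol, dtype=float)
        vmin, vmax = float(vol.min()), float(vol.max())
        slope = max((vmax - vmin) / 60000.0, 1e-6)
        intercept = vmin + 30000.0 * slope
        for i in range(vol.shape[0]):
            ds = Dataset()
            ds.file_meta = FileMetaDataset()
            ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
            ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
            ds.SOPClassUID = pydicom.uid.CTImageStorage
            ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
            ds.Modality = "CT"
            ds.StudyInstanceUID = study_uid
            ds.SeriesInstanceUID = series_uid
            ds.SeriesDescription = f"{pvs.modality} phase {lab * 10}%"
            ds.InstanceNumber = i + 1
            ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            # DICOM patient axes: x = LR, y = AP, z = SI (see module docstring)
            ds.ImagePositionPatient = [
                pvs.grid.origin[2],
                pvs.grid.origin[1],
                pvs.grid.origin[0] + i * si_sp,
            ]
            ds.PixelSpacing = [ap_sp, lr_sp]  # [row, col]
            ds.SliceThickness = si_sp
            ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 1
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.RescaleSlope = slope
            ds.RescaleIntercept = intercept
            raw = np.rint((vol[i] - intercept) / slope).astype(np.int16)
            ds.PixelData = raw.tobytes()
            ds.save_as(sub / f"slice_{i:04d}.dcm", enforce_file_format=True)
    return directory


def read_phase_series(path, modality: str | None = None) -> PhaseVolumeSet:
    """Read a phase-volume directory written by :func:`write_phase_series`.

    Accepts either NIfTI-with-sidecar or DICOM-series layout; phases are
    sorted ascending. Raises ``FileNotFoundError`` naming any missing
    phase and ``ValueError`` on inconsistent spacing across phases.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    if _sidecar_path(directory).exists():
        return _read_nifti_series(directory, modality)
    subdirs = sorted(p for p in directory.iterdir() if p.is_dir())
    if subdirs:
        return _read_dicom_series(directory, subdirs, modality)
    raise FileNotFoundError(f"no phase volumes found under {directory}")


def _read_nifti_series(directory: Path, modality: str | None) -> PhaseVolumeSet:
    import nibabel as nib

    meta = json.loads(_sidecar_path(directory).read_text())
    labels = meta["phase_labels"]
    volumes = []
    missing = [
        lab for lab in labels if not (directory / f"phase_{lab:02d}.nii.gz").exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing phase volume(s) {missing} under {directory}")
    for lab in labels:
        img = nib.load(directory / f"phase_{lab:02d}.nii.gz")
        volumes.append(np.asarray(img.dataobj, dtype=np.float32))
    grid = ImageGrid(
        tuple(meta["spacing_mm"]), tuple(meta["origin_mm"]), tuple(meta["size_voxels"])
    )
    return PhaseVolumeSet(
        volumes, grid, list(labels), modality or meta.get("modality", "SYNTH")
    )


def _read_dicom_series(
    directory: Path, subdirs: Sequence[Path], modality: str | None
) -> PhaseVolumeSet:
    import pydicom

    labels, volumes, grids = [], [], []
    for sub in subdirs:
        files = sorted(sub.glob("*.dcm"))
        if not files:
            raise FileNotFoundError(f"phase directory {sub} contains no DICOM files")
        slices = [pydicom.dcmread(f) for f in files]
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        first = slices[0]
        ap_sp, lr_sp = (float(v) for v in first.PixelSpacing)
        z = [float(ds.ImagePositionPatient[2]) for ds in slices]
        si_sp = float(np.median(np.diff(z))) if len(z) > 1 else float(
            first.SliceThickness
        )
        vol = np.stack(
            [
                ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope)
                + float(ds.RescaleIntercept)
                for ds in slices
            ],
            axis=0,
        )
        origin = (
            z[0],
            float(first.ImagePositionPatient[1]),
            float(first.ImagePositionPatient[0]),
        )
        grids.append(ImageGrid((si_sp, ap_sp, lr_sp), origin, vol.shape))
        volumes.append(vol)
        name = sub.name
        labels.append(int(name.split("_")[-1]) if "_" in name else len(labels))
    ref = grids[0]
    for lab, g in zip(labels, grids):
        if not np.allclose(g.spacing, ref.spacing, rtol=1e-5):
            raise ValueError(
                f"inconsistent spacing across phases: phase {lab} has "
                f"{g.spacing}, expected {ref.spacing}"
            )
    expected = list(range(min(labels), min(labels) + len(labels)))
    if sorted(labels) != expected and len(labels) != 10:
        missing = sorted(set(range(10)) - set(labels))
        raise FileNotFoundError(f"missing phase(s) {missing} under {directory}")
    order = np.argsort(labels)
    return PhaseVolumeSet(
        [volumes[i] for i in order],
        ref,
        [labels[i] for i in order],
        modality or "CT4D",
    )


# ---------------------------------------------------------------------------
# trace / controller-waveform I/O
# ---------------------------------------------------------------------------


def read_trace_csv(path) -> Trace:
    """Read a ``time_s,amplitude_mm`` CSV into a :class:`Trace`."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c.strip() for c in df.columns]
    if cols[:2] != ["time_s", "amplitude_mm"]:
        raise ValueError(
            f"expected header 'time_s,amplitude_mm', got {list(df.columns)!r}"
        )
    return Trace(df[df.columns[0]].to_numpy(float), df[df.columns[1]].to_numpy(float))


def write_trace_csv(trace: Trace, path) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "amplitude_mm": trace.values}).to_csv(
        path, index=False
    )
    return path


def write_controller_waveform(
    si: Trace, ap: Trace, lr: Trace, surrogate: Trace, path
) -> Path:
    """Write a 4-signal motion-controller file (plain text, 25 Hz).

    All four traces must span the same duration; each is linearly
    resampled onto a common 25 Hz time base starting at t = 0.
    """
    traces = {"si": si, "ap": ap, "lr": lr, "surrogate": surrogate}
    durations = {k: t.duration for k, t in traces.items()}
    if max(durations.values()) - min(durations.values()) > 1e-9:
        raise ValueError(f"trace durations differ: {durations}")
    duration = min(durations.values())
    n = int(math.floor(duration * CONTROLLER_RATE_HZ)) + 1
    t = np.arange(n) / CONTROLLER_RATE_HZ
    cols = [t] + [
        np.interp(t, tr.times - tr.times[0], tr.values) for tr in traces.values()
    ]
    path = Path(path)
    fmt = f"%.{CONTROLLER_DECIMALS}f"
    header = "time_s si_mm ap_mm lr_mm surrogate_mm"
    np.savetxt(path, np.column_stack(cols), fmt=fmt, header=header, comments="# ")
    return path


def read_controller_waveform(path) -> dict[str, Trace]:
    """Read a controller file back into named traces (keys si/ap/lr/surrogate)."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 5:
        raise ValueError("controller waveform must have 5 columns")
    t = data[:, 0]
    names = ["si", "ap", "lr", "surrogate"]
    return {name: Trace(t, data[:, i + 1]) for i, name in enumerate(names)}
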