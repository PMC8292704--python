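"""Motion amplitude from time-averaged 4D data sets.

Averaging the 10 phase volumes blurs the moving sphere into a motion
envelope whose extent along an axis is the target diameter D plus the
peak-to-trough excursion E. The envelope is interpolated to fine (0.1
mm) resolution around the target, binarized at a chosen threshold, and
the amplitude is read off as bounding-box extent minus D. This is the
fallback used where sine fitting is defeated by artifacts, and the
primary method for irregular patient waveforms whose individual phases
are too noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .io_formats import ImageGrid, PhaseVolumeSet
from .segmentation import label_components, select_target

__all__ = [
    "EnvelopeMeasurement",
    "average_volume",
    "measure_envelope",
    "window_level_threshold",
]


@dataclass(frozen=True)
class EnvelopeMeasurement:
    extents: np.ndarray  # mm (SI, AP, LR) of the thresholded envelope
    amplitudes: np.ndarray  # mm per axis, extent - target diameter (>= 0)
    threshold_used: float
    resolution: float  # mm of the interpolated grid

    def axis_amplitude(self, name: str) -> float:
        return float(self.amplitudes[{"SI": 0, "AP": 1, "LR": 2}[name.upper()]])


def average_volume(v: PhaseVolumeSet) -> np.ndarray:
    """Voxelwise arithmetic mean across phases (the 'average CT')."""
    if v.n_phases < 2:
        raise ValueError("need at least 2 phases to average")
    return np.mean(np.stack(v.volumes), axis=0)


def window_level_threshold(window: float, level: float) -> float:
    """Binarization threshold emulating a display window: the window
    center (level) — the intensity at 50% display gray."""
    if window <= 0:
        raise ValueError("window width must be > 0")
    return float(level)


def measure_envelope(
    avg: np.ndarray,
    grid: ImageGrid,
    threshold: float,
    seed,
    target_diameter: float,
    resolution: float = 0.1,
) -> EnvelopeMeasurement:
    """Measure per-axis motion amplitude from an averaged volume.

    The region around the seed-selected component is trilinearly
    interpolated to ``resolution`` mm, binarized at ``threshold``, the
    component containing (or nearest) the seed is selected, and extents
    are its bounding-box lengths; amplitudes subtract the target
    diameter (clamped at 0).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if not (avg.min() < threshold < avg.max()):
        raise ValueError(
            f"threshold {threshold} outside intensity range "
            f"[{avg.min():.1f}, {avg.max():.1f}]"
        )
    seed = np.asarray(seed, dtype=float)
    # coarse pass on the native grid to locate the envelope
    coarse = label_components(avg > threshold, grid)
    if not coarse:
        raise ValueError(
            f"no voxels above threshold {threshold}; lower the threshold"
        )
    comp = select_target(coarse, seed)
    pad = 2.0 + max(grid.spacing)  # mm beyond the coarse bbox
    lo = comp.bounding_box[:, 0] - pad
    hi = comp.bounding_box[:, 1] + pad
    axes = [
        np.arange(lo[a], hi[a] + resolution / 2, resolution) for a in range(3)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    idx = [
        (mesh[a] - grid.origin[a]) / grid.spacing[a] for a in range(3)
    ]
    fine = map_coordinates(avg, np.stack(idx), order=1, mode="nearest")
    fine_grid = ImageGrid(
        (resolution,) * 3, tuple(float(ax[0]) for ax in axes), fine.shape
    )
    comps = label_components(fine > threshold, fine_grid)
    if not comps:
        raise ValueError(
            f"interpolated region empty at threshold {threshold}; "
            "lower the threshold"
        )
    chosen = select_target(comps, seed)
    extents = (
        chosen.bounding_box[:, 1] - chosen.bounding_box[:, 0] + resolution
    )
    amplitudes = np.clip(extents - target_diameter, 0.0, None)
    return EnvelopeMeasurement(
        extents=extents,
        amplitudes=amplitudes,
        threshold_used=float(threshold),
        resolution=float(resolution),
    )
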