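"""Automatic target segmentation and per-phase centroid extraction.

The phase volumes are pooled into one 4D stack and binarized with a
single global Otsu threshold (so the target/background decision cannot
flicker between phases), optionally cleaned with a morphological
opening, labeled into 26-connected components, and the target is picked
per phase as the component whose centroid is nearest a seed point. The
seed for phase k > 0 is the selected centroid of phase k - 1, i.e. the
target is tracked across the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .io_formats import ImageGrid, PhaseVolumeSet

__all__ = [
    "LabeledComponent",
    "Trajectory",
    "SegmentationConfig",
    "binarize_otsu",
    "morph_open",
    "label_components",
    "select_target",
    "phase_centroids",
]


@dataclass(frozen=True)
class LabeledComponent:
    label: int
    voxel_count: int
    centroid: np.ndarray  # mm (SI, AP, LR)
    bounding_box: np.ndarray  # (3, 2) mm [min, max] voxel-center extents


@dataclass
class Trajectory:
    """Per-phase target centroids in mm (SI, AP, LR)."""

    phases: list[int]
    centroids: np.ndarray  # (n_phases, 3)
    masks: list[np.ndarray] | None = None

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (len(self.phases), 3):
            raise ValueError("one (SI, AP, LR) centroid per phase required")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    def axis(self, name: str) -> np.ndarray:
        return self.centroids[:, {"SI": 0, "AP": 1, "LR": 2}[name.upper()]]


@dataclass(frozen=True)
class SegmentationConfig:
    """``open_radius`` voxels of erosion-then-dilation (0 disables, the
    default: opening was only needed on noisy sets); ``per_phase_otsu``
    recomputes the threshold per phase instead of on the pooled stack."""

    open_radius: int = 0
    per_phase_otsu: bool = False
    keep_masks: bool = False


def binarize_otsu(
    v: PhaseVolumeSet, nbins: int = 256, per_phase: bool = False
) -> tuple[list[np.ndarray], float | list[float]]:
    """Binarize the phase set at the Otsu threshold of the pooled 4D
    histogram (256 bins between pooled min and max), maximizing the
    between-class variance; voxels strictly above threshold are
    foreground. ``per_phase=True`` thresholds each phase separately.
    """
    if per_phase:
        thresholds = []
        masks = []
        for vol in v.volumes:
            if np.ptp(vol) == 0:
                raise ValueError("cannot Otsu-threshold a constant volume")
            th = float(threshold_otsu(vol, nbins=nbins))
            thresholds.append(th)
            masks.append(vol > th)
        return masks, thresholds
    stack = np.stack(v.volumes)
    if np.ptp(stack) == 0:
        raise ValueError("cannot Otsu-threshold a constant volume set")
    th = float(threshold_otsu(stack, nbins=nbins))
    return [vol > th for vol in v.volumes], th


def morph_open(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary opening (erosion then dilation) with a ball element."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return mask
    selem = morphology.ball(radius)
    return ndimage.binary_dilation(ndimage.binary_erosion(mask, selem), selem)


def label_components(mask: np.ndarray, grid: ImageGrid) -> list[LabeledComponent]:
    """26-connected components with unweighted voxel-center centroids in mm."""
    labels = measure.label(mask, connectivity=3)
    out = []
    for rp in measure.regionprops(labels):
        centroid = grid.index_to_mm(rp.centroid)
        lo = grid.index_to_mm(rp.bbox[:3])
        hi = grid.index_to_mm(np.asarray(rp.bbox[3:]) - 1)
        out.append(
            LabeledComponent(
                label=int(rp.label),
                voxel_count=int(rp.area),
                centroid=np.asarray(centroid),
                bounding_box=np.stack([lo, hi], axis=1),
            )
        )
    return out


def select_target(
    components: list[LabeledComponent], seed
) -> LabeledComponent:
    """Component whose centroid is nearest the seed point (mm).

    Exact distance ties are broken by larger voxel count, then smaller
    label, so selection is deterministic.
    """
    if not components:
        raise ValueError("no components to select from")
    seed = np.asarray(seed, dtype=float)
    key = lambda c: (
        float(np.linalg.norm(c.centroid - seed)),
        -c.voxel_count,
        c.label,
    )
    return min(components, key=key)


def phase_centroids(
    v: PhaseVolumeSet,
    seed=None,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> Trajectory:
    """Run binarize -> (open) -> label -> select per phase and track the
    target: phase 0 uses ``seed`` (grid center when omitted, falling
    back to the largest component if nothing lies within the grid), and
    each later phase is seeded with the previous phase's centroid.
    """
    masks, _ = binarize_otsu(v, per_phase=cfg.per_phase_otsu)
    centroids = np.empty((v.n_phases, 3))
    kept = [] if cfg.keep_masks else None
    current_seed = None if seed is None else np.asarray(seed, dtype=float)
    for i, (lab, mask) in enumerate(zip(v.phase_labels, masks)):
        mask = morph_open(mask, cfg.open_radius)
        comps = label_components(mask, v.grid)
        if not comps:
            raise ValueError(f"phase {lab}: no component found after thresholding")
        if current_seed is None:
            chosen = max(comps, key=lambda c: (c.voxel_count, -c.label))
        else:
            chosen = select_target(comps, current_seed)
        centroids[i] = chosen.centroid
        current_seed = chosen.centroid
        if kept is not None:
            comp_mask = measure.label(mask, connectivity=3) == chosen.label
            kept.append(comp_mask)
    return Trajectory(list(v.phase_labels), centroids, kept)
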