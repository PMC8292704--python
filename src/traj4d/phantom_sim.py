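"""Digital dynamic-thorax-phantom simulator.

Renders a soft-tissue-equivalent sphere (optionally with a high-contrast
marker acting as the binning surrogate) inside a low-intensity lung
background, moves it by sine or patient-derived waveforms, and produces
10-phase volume sets under simplified 4D CT and 4D CBCT acquisition
models:

* **4D CBCT** — the scan oversamples the breathing cycle: frame times
  are spread uniformly over the scan duration, each frame is assigned a
  respiratory phase bin from its cycle fraction, and each phase volume
  is the mean of its frames' instantaneous renderings (within-bin
  temporal averaging stands in for reconstruction blur).
* **4D CT** — cine acquisition: the grid is covered by contiguous axial
  slabs imaged sequentially, each for one cycle time plus a safety
  margin; every cine image carries the cycle fraction at its timestamp,
  and each phase volume stitches together, per slab, the image whose
  fraction is nearest that phase's center. Irregular breathing therefore
  produces authentic slab-boundary (stitching) artifacts.

Programmed "amplitude" follows the motion-controller convention used
throughout this package: it is the peak-to-trough excursion E, i.e. the
target moves ±E/2 about its rest position, so the time-averaged envelope
of a sphere of diameter D spans D + E.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_formats import AXES, ImageGrid, PhaseVolumeSet, Trace

__all__ = [
    "MotionSpec",
    "PhantomSpec",
    "MarkerSpec",
    "AcquisitionSpec",
    "GroundTruth",
    "trajectory_at",
    "cycle_fraction",
    "render_volume",
    "simulate_cbct",
    "simulate_ct",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotionSpec:
    """Programmed target motion.

    ``kind='sine'``: per-axis displacement (E/2)·sin(2πt/T + φ) with
    peak-to-trough excursion E, cycle time T and phase offset φ.
    ``kind='waveform'``: per-axis displacement interpolated from traces
    (SI, AP, LR order); ``surrogate`` drives respiratory binning (for
    sine motion the sine itself is the surrogate).
    """

    kind: str = "sine"
    excursion: tuple[float, float, float] = (10.0, 0.0, 0.0)
    cycle_time: float = 5.0
    phase_offset: float = 0.0
    waveform: tuple[Trace, Trace, Trace] | None = None
    surrogate: Trace | None = None

    def __post_init__(self):
        if self.kind not in ("sine", "waveform"):
            raise ValueError(f"kind must be 'sine' or 'waveform', got {self.kind!r}")
        if any(e < 0 for e in self.excursion):
            raise ValueError("excursions must be >= 0")
        if self.cycle_time <= 0:
            raise ValueError("cycle_time must be > 0")
        if self.kind == "waveform" and self.waveform is None:
            raise ValueError("waveform motion requires per-axis traces")
        if self.kind == "sine" and self.waveform is not None:
            raise ValueError("sine motion must not carry waveform traces")


@dataclass(frozen=True)
class MarkerSpec:
    """High-contrast sphere rigidly offset from the target (the 'bolus')."""

    offset: tuple[float, float, float] = (-60.0, 0.0, 0.0)
    diameter: float = 10.0
    intensity: float = 800.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensities of the digital phantom insert.

    Intensities are CT-number-like (HU-scale) floats; the defaults give
    plausible lung/soft-tissue/bone contrast but are configuration, not
    claims about any physical phantom.
    """

    target_diameter: float = 20.0
    target_intensity: float = 40.0
    lung_intensity: float = -800.0
    marker: MarkerSpec | None = None
    center: tuple[float, float, float] | None = None  # rest position; grid center if None

    def __post_init__(self):
        if self.target_diameter <= 0:
            raise ValueError("target_diameter must be > 0")
        if self.target_intensity <= self.lung_intensity:
            raise ValueError("target_intensity must exceed lung_intensity")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition model parameters for either modality.

    4D CT fields: ``rotation_time`` (gantry rotation, s), ``cine_interval``
    (spacing of reconstructed cine images, s), ``cine_margin`` (extra
    dwell beyond one cycle per couch position, s), ``slab_thickness``
    (axial detector coverage per couch position, mm).
    4D CBCT fields: ``scan_duration`` (s) and ``n_frames``.
    """

    modality: str = "CBCT4D"
    grid: ImageGrid = field(
        default_factory=lambda: ImageGrid((1.0, 1.0, 1.0), (-31.5, -23.5, -23.5), (64, 48, 48))
    )
    cine_margin: float = 1.5
    rotation_time: float = 1.0
    cine_interval: float = 0.25
    slab_thickness: float = 40.0
    scan_duration: float = 240.0
    n_frames: int = 975
    n_phases: int = 10
    noise_sd: float = 20.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.modality not in ("CT4D", "CBCT4D"):
            raise ValueError("modality must be CT4D or CBCT4D")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """True per-phase displacement (mm, SI/AP/LR) of the simulated target."""

    phases: list[int]
    displacements: np.ndarray  # (n_phases, 3)
    center: np.ndarray  # rest position, mm

    @property
    def centroids(self) -> np.ndarray:
        return self.center[None, :] + self.displacements


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------


def trajectory_at(t, m: MotionSpec) -> np.ndarray:
    """Target displacement (mm, SI/AP/LR) at time(s) ``t`` seconds.

    Sine motion: axis displacement (E/2)·sin(2πt/T + φ). Waveform
    motion: linear interpolation of the per-axis traces (times outside
    the sampled range raise).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if m.kind == "sine":
        phase = 2 * np.pi * t / m.cycle_time + m.phase_offset
        disp = np.stack([e / 2 * np.sin(phase) for e in m.excursion], axis=-1)
    else:
        disp = np.stack([tr(t) for tr in m.waveform], axis=-1)
    return disp[0] if scalar else disp


def _surrogate_cycle_parser(surrogate: Trace, min_separation: float) -> Callable:
    """Map times to cycle fractions by linear interpolation between
    successive surrogate peaks (one peak == start of a cycle)."""
    from .waveforms import find_peaks_troughs

    peaks = find_peaks_troughs(surrogate, min_separation=min_separation)
    pk_t = surrogate.times[peaks.peak_indices]
    if len(pk_t) < 2:
        raise ValueError("surrogate must contain at least two peaks")

    def frac(t):
        t = np.asarray(t, dtype=float)
        # extend the first/last cycle length beyond the sampled peaks
        idx = np.searchsorted(pk_t, t, side="right") - 1
        idx = np.clip(idx, 0, len(pk_t) - 2)
        length = pk_t[idx + 1] - pk_t[idx]
        return ((t - pk_t[idx]) / length) % 1.0

    return frac


def cycle_fraction(t, m: MotionSpec) -> np.ndarray:
    """Respiratory cycle fraction in [0, 1) used for phase binning.

    For sine motion this is frac(t/T + φ/2π); for waveform motion the
    fraction is parsed from the surrogate's peak-to-peak cycles.
    """
    t = np.asarray(t, dtype=float)
    if m.kind == "sine":
        return (t / m.cycle_time + m.phase_offset / (2 * np.pi)) % 1.0
    surrogate = m.surrogate if m.surrogate is not None else m.waveform[0]
    return _surrogate_cycle_parser(surrogate, min_separation=1.0)(t)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_SUBDIV = 4  # subvoxel sampling per axis for boundary voxels


def _sphere_fill(grid: ImageGrid, center: np.ndarray, radius: float) -> tuple:
    """Fractional sphere occupancy per voxel, restricted to a bounding box.

    Returns (slices, fill) where ``fill`` covers only the bounding box.
    Interior/exterior voxels are decided by center distance; voxels the
    sphere surface crosses get a 4x4x4 subvoxel occupancy fraction.
    """
    sp = np.asarray(grid.spacing)
    lo_idx, hi_idx = [], []
    for a in range(3):
        lo = int(math.floor((center[a] - radius - grid.origin[a]) / sp[a])) - 1
        hi = int(math.ceil((center[a] + radius - grid.origin[a]) / sp[a])) + 1
        lo_idx.append(max(lo, 0))
        hi_idx.append(min(hi, grid.size[a] - 1))
    slices = tuple(slice(lo, hi + 1) for lo, hi in zip(lo_idx, hi_idx))
    coords = [
        grid.origin[a] + sp[a] * np.arange(lo_idx[a], hi_idx[a] + 1) - center[a]
        for a in range(3)
    ]
    d2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    half_diag = float(np.linalg.norm(sp)) / 2
    fill = (d2 <= (radius - half_diag) ** 2).astype(float) if radius > half_diag else np.zeros(d2.shape)
    boundary = (d2 > max(radius - half_diag, 0.0) ** 2) & (d2 < (radius + half_diag) ** 2)
    if np.any(boundary):
        bi, bj, bk = np.nonzero(boundary)
        # subvoxel offsets at cell centers of a _SUBDIV^3 partition
        off = (np.arange(_SUBDIV) + 0.5) / _SUBDIV - 0.5
        oz, oy, ox = np.meshgrid(off * sp[0], off * sp[1], off * sp[2], indexing="ij")
        sub = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)  # (S^3, 3)
        pts = np.stack(
            [coords[0][bi], coords[1][bj], coords[2][bk]], axis=1
        )  # (B, 3)
        d2sub = ((pts[:, None, :] + sub[None, :, :]) ** 2).sum(axis=2)
        fill[bi, bj, bk] = (d2sub <= radius**2).mean(axis=1)
    return slices, fill


def render_volume(
    p: PhantomSpec,
    displacement,
    grid: ImageGrid,
    out: np.ndarray | None = None,
    weight: float = 1.0,
) -> np.ndarray:
    """Render the phantom with the target displaced by ``displacement`` mm.

    Voxels inside the target sphere get ``target_intensity`` with
    fractional (partial-volume) filling at the surface; everything else
    is ``lung_intensity``. A marker sphere, if configured, is rendered
    the same way. When ``out`` is given, ``weight`` times the rendering
    is accumulated into it (used for within-bin averaging).
    """
    center0 = np.asarray(p.center if p.center is not None else grid.center_mm, float)
    disp = np.asarray(displacement, dtype=float)
    spheres = [(center0 + disp, p.target_diameter / 2, p.target_intensity)]
    if p.marker is not None:
        spheres.append(
            (center0 + disp + np.asarray(p.marker.offset), p.marker.diameter / 2, p.marker.intensity)
        )
    ext = grid.extent_mm()
    for c, r, _ in spheres:
        for a in range(3):
            if c[a] - r < ext[a][0] or c[a] + r > ext[a][1]:
                raise ValueError(
                    f"sphere (r={r} mm) at {np.round(c, 2)} clipped by grid along "
                    f"{AXES[a]} (extent {np.round(ext[a], 2)})"
                )
    if out is None:
        vol = np.full(grid.size, p.lung_intensity, dtype=float)
        for c, r, inten in spheres:
            sl, fill = _sphere_fill(grid, c, r)
            vol[sl] += fill * (inten - p.lung_intensity)
        return vol
    out += weight * p.lung_intensity
    for c, r, inten in spheres:
        sl, fill = _sphere_fill(grid, c, r)
        out[sl] += weight * fill * (inten - p.lung_intensity)
    return out


# ---------------------------------------------------------------------------
# acquisition models
# ---------------------------------------------------------------------------


def simulate_cbct(
    p: PhantomSpec, m: MotionSpec, a: AcquisitionSpec
) -> tuple[PhaseVolumeSet, GroundTruth]:
    """Simulate a phase-binned 4D CBCT of the moving phantom.

    Frame times are uniform over ``scan_duration``; frame ``t`` falls in
    phase bin ``floor(n_phases * cycle_fraction(t))``; each phase volume
    is the mean of its frames' renderings plus Gaussian noise. Ground
    truth is the mean true displacement per bin.
    """
    if a.modality != "CBCT4D":
        raise ValueError("simulate_cbct requires modality CBCT4D")
    dt = a.scan_duration / a.n_frames
    times = (np.arange(a.n_frames) + 0.5) * dt
    frac = cycle_fraction(times, m)
    bins = np.minimum((a.n_phases * frac).astype(int), a.n_phases - 1)
    counts = np.bincount(bins, minlength=a.n_phases)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise ValueError(
            f"phase bin(s) {empty.tolist()} received no frames; "
            "increase scan_duration or n_frames"
        )
    disp = trajectory_at(times, m)
    volumes = [np.zeros(a.grid.size, dtype=float) for _ in range(a.n_phases)]
    for t_i, b, d in zip(times, bins, disp):
        render_volume(p, d, a.grid, out=volumes[b], weight=1.0)
    rng = np.random.default_rng(a.rng_seed)
    for b in range(a.n_phases):
        volumes[b] /= counts[b]
        if a.noise_sd > 0:
            volumes[b] += rng.normal(0.0, a.noise_sd, size=volumes[b].shape)
    truth = np.stack(
        [disp[bins == b].mean(axis=0) for b in range(a.n_phases)], axis=0
    )
    center0 = np.asarray(p.center if p.center is not None else a.grid.center_mm, float)
    pvs = PhaseVolumeSet(volumes, a.grid, list(range(a.n_phases)), "CBCT4D")
    return pvs, GroundTruth(list(range(a.n_phases)), truth, center0)


def _circular_distance(x, c):
    d = np.abs(x - c) % 1.0
    return np.minimum(d, 1.0 - d)


def simulate_ct(
    p: PhantomSpec, m: MotionSpec, a: AcquisitionSpec
) -> tuple[PhaseVolumeSet, GroundTruth]:
    """Simulate a retrospectively binned cine 4D CT of the moving phantom.

    Axial slabs of ``slab_thickness`` mm are imaged one after another,
    each over ``cycle_time + cine_margin`` seconds with one cine image
    every ``cine_interval`` seconds. Each phase stitches together, per
    slab, the cine image whose cycle fraction is nearest the phase
    center k/n_phases; a warning is logged when the nearest available
    fraction is further than half a bin away. Ground truth is the true
    displacement at each phase-center fraction (averaged over cycles for
    waveform motion).
    """
    if a.modality != "CT4D":
        raise ValueError("simulate_ct requires modality CT4D")
    si_sp = a.grid.spacing[0]
    slab_slices = max(int(round(a.slab_thickness / si_sp)), 1)
    n_slabs = int(math.ceil(a.grid.size[0] / slab_slices))
    dwell = m.cycle_time + a.cine_margin
    n_img = int(math.floor(dwell / a.cine_interval)) + 1
    centers = np.arange(a.n_phases) / a.n_phases
    volumes = [np.empty(a.grid.size, dtype=float) for _ in range(a.n_phases)]
    for s in range(n_slabs):
        sl = slice(s * slab_slices, min((s + 1) * slab_slices, a.grid.size[0]))
        t0 = s * dwell
        t_img = t0 + np.arange(n_img) * a.cine_interval
        frac = cycle_fraction(t_img, m)
        disp = trajectory_at(t_img, m)
        rendered: dict[int, np.ndarray] = {}
        for k in range(a.n_phases):
            dists = _circular_distance(frac, centers[k])
            j = int(np.argmin(dists))
            if dists[j] > 0.5 / a.n_phases:
                log.warning(
                    "slab %d phase %d: nearest cine fraction %.3f is %.3f cycles "
                    "from the phase center",
                    s,
                    k,
                    frac[j],
                    dists[j],
                )
            if j not in rendered:
                rendered[j] = render_volume(p, disp[j], a.grid)
            volumes[k][sl] = rendered[j][sl]
    if a.noise_sd > 0:
        rng = np.random.default_rng(a.rng_seed)
        for k in range(a.n_phases):
            volumes[k] += rng.normal(0.0, a.noise_sd, size=volumes[k].shape)
    truth = _ideal_phase_displacements(m, a.n_phases)
    center0 = np.asarray(p.center if p.center is not None else a.grid.center_mm, float)
    pvs = PhaseVolumeSet(volumes, a.grid, list(range(a.n_phases)), "CT4D")
    return pvs, GroundTruth(list(range(a.n_phases)), truth, center0)


def _ideal_phase_displacements(m: MotionSpec, n_phases: int) -> np.ndarray:
    """True displacement at each phase-center cycle fraction k/n."""
    centers = np.arange(n_phases) / n_phases
    if m.kind == "sine":
        phase = 2 * np.pi * centers  # fraction already includes the offset
        return np.stack([e / 2 * np.sin(phase) for e in m.excursion], axis=-1)
    # waveform: average the per-axis displacement at fraction k/n over cycles
    surrogate = m.surrogate if m.surrogate is not None else m.waveform[0]
    frac_of = _surrogate_cycle_parser(surrogate, min_separation=1.0)
    t_lo = max(tr.times[0] for tr in m.waveform)
    t_hi = min(tr.times[-1] for tr in m.waveform)
    t = np.linspace(t_lo, t_hi, 4000)
    f = frac_of(t)
    disp = trajectory_at(np.clip(t, 0, None), m)
    out = np.empty((n_phases, 3))
    bins = np.minimum((n_phases * f).astype(int), n_phases - 1)
    for k in range(n_phases):
        sel = bins == k
        out[k] = disp[sel].mean(axis=0) if np.any(sel) else np.nan
    return out
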