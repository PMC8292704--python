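"""Surrogate-trace processing: smoothing, peak/trough statistics, and
scaling of patient breathing traces into per-axis tumor-motion waveforms.

A recorded surrogate amplitude trace is first resampled to a uniform
rate and denoised with a Savitzky–Golay filter, its mean peak-to-trough
excursion is measured from alternating extrema, and the zero-mean trace
is then rescaled per axis so that its excursion matches the tumor
excursion measured on planning 4D CT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .io_formats import Trace

__all__ = [
    "SmoothingConfig",
    "PeakSet",
    "resample_uniform",
    "smooth_sg",
    "find_peaks_troughs",
    "scale_to_tumor",
    "synthetic_breathing_trace",
]

DEFAULT_RATE_HZ = 25.0


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky–Golay parameters: odd window length (samples) and
    polynomial order. Defaults (21 samples at 25 Hz = 0.84 s, cubic)
    are sized to respiratory periods of 3–7 s."""

    window_length: int = 21
    poly_order: int = 3

    def __post_init__(self):
        if self.window_length % 2 != 1:
            raise ValueError("window_length must be odd")
        if self.window_length <= self.poly_order:
            raise ValueError("window_length must exceed poly_order")


@dataclass(frozen=True)
class PeakSet:
    """Alternating breathing extrema and their mean levels (mm)."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    mean_peak: float
    mean_trough: float

    @property
    def excursion(self) -> float:
        """Mean peak minus mean trough (mm)."""
        return self.mean_peak - self.mean_trough


def resample_uniform(t: Trace, rate_hz: float = DEFAULT_RATE_HZ) -> Trace:
    """Linearly resample a trace onto a uniform grid at ``rate_hz``."""
    n = int(np.floor(t.duration * rate_hz)) + 1
    times = t.times[0] + np.arange(n) / rate_hz
    return Trace(times, np.interp(times, t.times, t.values))


def smooth_sg(t: Trace, cfg: SmoothingConfig = SmoothingConfig()) -> Trace:
    """Savitzky–Golay smoothing (uniform sampling required; resample
    first if needed). Edges use a polynomial fit of the terminal windows,
    so polynomials up to ``poly_order`` pass through unchanged."""
    if not t.is_uniform(rtol=1e-4):
        raise ValueError("smooth_sg requires uniform sampling; resample first")
    if len(t.values) < cfg.window_length:
        raise ValueError(
            f"trace length {len(t.values)} shorter than window {cfg.window_length}"
        )
    sm = savgol_filter(t.values, cfg.window_length, cfg.poly_order, mode="interp")
    return Trace(t.times, sm)


def find_peaks_troughs(t: Trace, min_separation: float = 1.0) -> PeakSet:
    """Detect alternating local maxima/minima separated by at least
    ``min_separation`` seconds.

    Consecutive same-sign extrema (possible after independent peak and
    trough detection) are pruned by keeping the more extreme one.
    """
    fs = t.sample_rate()
    dist = max(int(round(min_separation * fs)), 1)
    pk, _ = find_peaks(t.values, distance=dist)
    tr, _ = find_peaks(-t.values, distance=dist)
    if pk.size == 0 or tr.size == 0:
        raise ValueError("no peaks/troughs found (is the trace monotone or flat?)")
    events = sorted(
        [(i, +1) for i in pk] + [(i, -1) for i in tr], key=lambda e: e[0]
    )
    pruned: list[tuple[int, int]] = []
    for idx, sign in events:
        if pruned and pruned[-1][1] == sign:
            prev = pruned[-1][0]
            better = idx if sign * t.values[idx] > sign * t.values[prev] else prev
            pruned[-1] = (better, sign)
        else:
            pruned.append((idx, sign))
    pk = np.array([i for i, s in pruned if s == +1], dtype=int)
    tr = np.array([i for i, s in pruned if s == -1], dtype=int)
    if pk.size == 0 or tr.size == 0:
        raise ValueError("no alternating peak/trough pair found")
    return PeakSet(pk, tr, float(t.values[pk].mean()), float(t.values[tr].mean()))


def scale_to_tumor(
    t: Trace,
    target_excursion: tuple[float, float, float],
    min_separation: float = 1.0,
) -> tuple[tuple[Trace, Trace, Trace], tuple[float, float, float]]:
    """Scale a surrogate trace into per-axis (SI, AP, LR) tumor waveforms.

    Each axis d gets ``k_d * (trace - mean(trace))`` with
    ``k_d = target_excursion_d / (mean_peak - mean_trough)``, so the
    scaled trace's own mean peak-to-trough excursion equals the
    requested tumor excursion; motion is symmetric about phantom zero.
    Returns the scaled traces and the scale factors.
    """
    if any(e < 0 for e in target_excursion):
        raise ValueError("target excursions must be >= 0")
    peaks = find_peaks_troughs(t, min_separation)
    if peaks.excursion <= 0:
        raise ValueError("degenerate trace: mean peak equals mean trough")
    centered = t.values - t.values.mean()
    factors = tuple(e / peaks.excursion for e in target_excursion)
    traces = tuple(Trace(t.times, k * centered) for k in factors)
    return traces, factors


def synthetic_breathing_trace(
    duration: float = 240.0,
    mean_period: float = 4.0,
    mean_amplitude: float = 10.0,
    period_jitter: float = 0.1,
    amplitude_jitter: float = 0.15,
    drift_mm: float = 0.5,
    noise_sd: float = 0.0,
    rate_hz: float = DEFAULT_RATE_HZ,
    rng: np.random.Generator | int | None = 0,
) -> Trace:
    """Generate a patient-like quasi-periodic breathing surrogate.

    Cycle-to-cycle period and amplitude vary log-normally (fractional
    SDs ``period_jitter`` / ``amplitude_jitter``), a slow baseline drift
    is added, and each cycle is a raised-cosine breath (sharper peaks
    than a pure sine, as real abdominal traces show). Jitter magnitudes
    default to the 10–15% cycle variability typical of free breathing.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t_edges = [0.0]
    amps = []
    while t_edges[-1] < duration:
        t_edges.append(t_edges[-1] + mean_period * rng.lognormal(0, period_jitter))
        amps.append(mean_amplitude * rng.lognormal(0, amplitude_jitter))
    n = int(np.floor(duration * rate_hz)) + 1
    times = np.arange(n) / rate_hz
    cyc = np.searchsorted(t_edges, times, side="right") - 1
    cyc = np.clip(cyc, 0, len(amps) - 1)
    start = np.asarray(t_edges)[cyc]
    length = np.asarray(t_edges)[cyc + 1] - start
    u = (times - start) / length
    values = np.asarray(amps)[cyc] / 2 * np.cos(2 * np.pi * u)
    values += drift_mm * np.sin(2 * np.pi * times / duration)
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, size=values.shape)
    return Trace(times, values)
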