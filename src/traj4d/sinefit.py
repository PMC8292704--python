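"""Sinusoidal fitting of centroid-versus-phase data.

The per-phase target centroid along one axis is modeled as

    x_k = A sin(2 pi f k + theta) + c,      k = phase index 0..9,

with amplitude coefficient A, frequency f in cycles per phase step,
phase shift theta and vertical offset c, all free, fitted by nonlinear
least squares with a deterministic multi-start over theta. The reported
motion "amplitude" is the peak-to-trough excursion 2|A|, the convention
under which fitted values track the motion controller's programmed
amplitudes one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .segmentation import Trajectory

__all__ = ["SineFitResult", "fit_sine", "amplitude_pair"]

F_BOUNDS = (0.05, 0.2)  # cycles per phase step; one cycle per 10 phases = 0.1
N_THETA_STARTS = 8


@dataclass(frozen=True)
class SineFitResult:
    amplitude_coeff: float  # A, mm (signed)
    frequency: float  # cycles per phase step
    phase_shift: float  # radians
    offset: float  # mm
    rmse_residual: float  # mm
    n_points: int

    @property
    def excursion(self) -> float:
        """Peak-to-trough motion amplitude, 2|A| (mm)."""
        return 2 * abs(self.amplitude_coeff)

    def __call__(self, phases) -> np.ndarray:
        phases = np.asarray(phases, dtype=float)
        return (
            self.amplitude_coeff
            * np.sin(2 * np.pi * self.frequency * phases + self.phase_shift)
            + self.offset
        )


def fit_sine(phases, positions) -> SineFitResult:
    """Least-squares sine fit of positions (mm) against phase indices.

    Initialization: A0 = (max-min)/2, f0 = 0.1, c0 = mean, theta0 from
    the argmax phase, refined from 8 equispaced theta starts (no RNG);
    f is bounded to [0.05, 0.2] to prevent aliasing on 10 samples.
    Raises ``RuntimeError`` with diagnostics if no start converges.
    """
    phases = np.asarray(phases, dtype=float)
    y = np.asarray(positions, dtype=float)
    if phases.shape != y.shape or phases.ndim != 1:
        raise ValueError("phases and positions must be equal-length 1D arrays")
    if len(y) < 5:
        raise ValueError(f"need >= 5 points to fit 4 parameters, got {len(y)}")
    if np.ptp(y) == 0:
        return SineFitResult(0.0, 0.1, 0.0, float(y[0]), 0.0, len(y))

    a0 = np.ptp(y) / 2
    f0 = 0.1
    c0 = float(y.mean())
    # place the initial crest at the phase of the maximum position
    theta_peak = np.pi / 2 - 2 * np.pi * f0 * phases[int(np.argmax(y))]

    def residuals(p):
        a, f, th, c = p
        return a * np.sin(2 * np.pi * f * phases + th) + c - y

    best = None
    diagnostics = []
    for dth in theta_peak + 2 * np.pi * np.arange(N_THETA_STARTS) / N_THETA_STARTS:
        try:
            sol = least_squares(
                residuals,
                x0=[a0, f0, dth, c0],
                bounds=([-np.inf, F_BOUNDS[0], -np.inf, -np.inf],
                        [np.inf, F_BOUNDS[1], np.inf, np.inf]),
                method="trf",
            )
        except Exception as exc:  # pragma: no cover - scipy failure path
            diagnostics.append(f"start theta={dth:.3f}: {exc}")
            continue
        if not sol.success:
            diagnostics.append(f"start theta={dth:.3f}: {sol.message}")
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            "sine fit failed to converge from all starts:\n" + "\n".join(diagnostics)
        )
    a, f, th, c = best.x
    rmse = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return SineFitResult(float(a), float(f), float(th), float(c), rmse, len(y))


def amplitude_pair(
    traj_ct: Trajectory, traj_cbct: Trajectory, axis: str = "SI"
) -> tuple[float, float, float]:
    """Fitted excursions (mm) of both modalities on one axis and their
    absolute difference."""
    fit_ct = fit_sine(traj_ct.phases, traj_ct.axis(axis))
    fit_cbct = fit_sine(traj_cbct.phases, traj_cbct.axis(axis))
    return (
        fit_ct.excursion,
        fit_cbct.excursion,
        abs(fit_ct.excursion - fit_cbct.excursion),
    )
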