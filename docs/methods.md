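# Methods

`traj4d` measures how well two phase-resolved imaging chains — 4D CT
(cine acquisition, retrospective phase binning) and 4D CBCT
(oversampled on-board cone-beam acquisition, phase-binned frames) —
agree on the motion amplitude of a moving target, and validates the
whole measurement chain on a digital motion phantom with known ground
truth. This note records the models, the conventions chosen where the
problem was genuinely open, and what the synthetic data can and cannot
show.

## Coordinate and amplitude conventions

All physical quantities are millimetres in (SI, AP, LR) axis order with
0-based voxel indices and a voxel-center convention: voxel (i, j, k)
sits at `origin + index * spacing`. DICOM's patient axes (x = LR,
y = AP, z = SI) are remapped on read; the handedness of this remap is a
package convention, exercised by round-trip tests.

"Amplitude" throughout is the **peak-to-trough excursion** E: sine
motion is `(E/2)·sin(2πt/T + φ)` per axis, so a sphere of diameter D
sweeps an envelope of SI extent D + E. This convention is what makes
fitted amplitudes, envelope readings and programmed controller
amplitudes directly comparable, and it is the only convention under
which the benchmark table's envelope readings track its programmed
values one-to-one.

## Digital phantom and acquisition models

The phantom is a soft-tissue sphere (default D = 20 mm, intensity +40)
in a uniform low-intensity lung background (−800), optionally with a
high-contrast marker sphere (+800) rigidly offset from the target — the
binning aid used on real phantoms. Intensities are CT-number-like
configuration values, not claims about any physical insert. Rendering
uses fractional (partial-volume) filling: voxels the sphere surface
crosses get a 4×4×4-subsample occupancy fraction, which keeps the
rendered intensity centroid within 0.05 mm of the requested position
and the rendered volume within 2% of (π/6)D³.

**4D CBCT.** Frame times are uniform over the scan (default 975 frames
/ 240 s). Each frame's respiratory cycle fraction u(t) assigns it to
bin `floor(10·u)`; the phase volume is the mean of its frames'
renderings plus optional white Gaussian noise (default SD 20, seeded).
Within-bin temporal averaging stands in for reconstruction blur; no
projection/FDK model is used, since the analysis never touches
projections. Ground truth per phase is the mean true displacement of
the frames in the bin. For sine motion at cycle fraction u the bin mean
equals the analytic integral of (E/2)·sin over the bin to < 0.05 mm
(checked against closed form).

Bin averaging attenuates the *intensity*-centroid excursion by
sin(π/10)/(π/10) ≈ 0.984, up to 0.31 mm at E = 19; the binarized-mask
centroid used by the segmentation stage partially compensates (the
thresholded footprint of the smeared sphere reaches toward the
high-dwell end of the bin sweep), and the measured chain error stays
≤ 0.18 mm over E ∈ {5, …, 19}.

**4D CT.** The grid is covered by contiguous axial slabs (default
40 mm = 16 × 2.5 mm slices), imaged sequentially, each over one cycle
time plus a 1.5 s margin. Cine images are rendered every
`cine_interval` seconds (default 0.25 s). The gantry `rotation_time`
(1 s) is retained as acquisition metadata but is *not* the image
spacing: cine reconstruction produces images at sub-rotation intervals,
and modeling one image per rotation would alias the cycle-fraction
lattice (at T = 5 s, exactly five distinct fractions) into a staircase
that biases the fitted amplitude by ≈ 5% of E. With a fraction lattice
whose spacing divides the bin width, the residual fraction offset is
common to all phases and is absorbed by the fitted phase shift, leaving
the amplitude unbiased. Each phase takes, per slab, the image whose
cycle fraction is circularly nearest the phase center k/10, and
concatenates the slabs — so irregular breathing produces authentic
stitching artifacts at slab boundaries (a double-amplitude outlier
breath measurably breaks inter-slab continuity, and the suite asserts
it). Ground truth per phase is the displacement at the phase-center
cycle fraction.

**Phase binning.** Binning is phase-based on the surrogate's cycle
fraction: for sine motion, frac(t/T + φ/2π); for waveform motion,
linear interpolation between successive surrogate peaks. Real systems
bin on landmark positions; the marker-driven surrogate approximates
that and the approximation is deliberate.

## Surrogate waveforms

Recorded surrogate traces are resampled to 25 Hz, smoothed with a
Savitzky–Golay filter (window 21 samples = 0.84 s, cubic; sized to 3–7 s
breathing periods — the smoother passes polynomials of its order
through exactly and halves 0.5 mm white noise on breathing-like
signals), and reduced to alternating peaks/troughs at least 1 s apart
(same-sign extrema pruned by keeping the more extreme). Scaling to
tumor motion is linear about the trace mean, with per-axis factor
`target excursion / (mean peak − mean trough)`, so the scaled trace's
own excursion measurement reproduces the request (fixed-point property,
tested to 0.01 mm). The synthetic breathing generator produces
raised-cosine breaths with log-normal cycle-to-cycle period and
amplitude jitter (defaults 10%/15%, typical of free breathing) plus a
slow baseline drift; it does not emulate apnea, coughs, or baseline
shifts between imaging sessions.

## Segmentation and tracking

The ten phase volumes are pooled and binarized at a single global Otsu
threshold (256 bins between the pooled min/max) so the foreground
decision cannot flicker between phases; a per-phase threshold is
available by configuration. Morphological opening (ball element) is
opt-in with default radius 0 — it was only ever needed against noise.
Components are 26-connected with unweighted voxel-center centroids;
the target is the component nearest a seed point, ties broken by larger
size then smaller label. The seed for phase k > 0 is the phase k−1
centroid (tracking), because a large excursion can carry the target
closer to clutter than to the original seed. With no seed, the largest
component is taken.

## Sine fitting

Per-phase centroids x_k are fitted with `A·sin(2πf·k + θ) + c` by
bounded nonlinear least squares; f is free within [0.05, 0.2]
cycles/phase (one breathing cycle per 10 phases is f = 0.1; the bounds
prevent aliased optima on 10 samples). Initialization uses
A₀ = (max−min)/2, f₀ = 0.1, c₀ = mean, θ₀ from the argmax phase, with a
deterministic 8-point multi-start over θ — no randomness in fitting. A
constant series short-circuits to A = 0 exactly. The reported amplitude
is 2|A|. Under 0.25 mm centroid noise the estimator is unbiased within
0.01 mm with SD ≈ 0.23 mm (200-replicate Monte Carlo in the suite).

## Envelope measurement

The phase volumes are averaged voxelwise; the region around the
seed-selected component is trilinearly interpolated to 0.1 mm,
binarized, and the target component's bounding-box extents are read
off; amplitude = extent − D, floored at 0. Two threshold conventions
are provided:

* **display emulation** — the window/level rule returns the window
  center (the paper-style W/L 1500/−400 lung window gives −400);
* **faint edge** — lung background + 50 intensity units, the default
  for quantitative use.

The faint-edge choice is deliberate: on a *time-averaged* image the
mid-contrast isosurface encloses only the ≥50%-dwell region, whose
extent is far short of D + E (a target dwells only briefly at the
extremes of travel), while a human reading a wide display window
perceives the envelope out to where it first rises above background.
At lung + 50 the competing errors — the partial-volume/blur skirt
(positive, ≈ half a voxel per side) and the dwell truncation (negative,
growing with E) — stay within ±0.5 mm of the D + E rule across
E ∈ {5, …, 19} on the 1 mm CBCT grid, and within 0.33 mm of the sine-fit
amplitude. The threshold remains an explicit argument everywhere; the
"most visually appropriate contour" of a human operator cannot be
reconstructed and is not claimed.

## Equivalence statistics

For paired amplitudes (a = 4D CT, b = 4D CBCT, d = a − b, so a negative
mean means CBCT reads larger): mean, sample SD (n−1), SE, t-based 95%
CI half-width, RMSE = √(mean d²); Shapiro–Wilk normality (Royston
AS R94 via scipy); TOST with default ±1 mm limits — t_L = (d̄ − δ_L)/SE
tested against the upper tail, t_U = (d̄ − δ_U)/SE against the lower,
TOST p = max of the two one-sided p-values, equivalence declared at
p < 0.05; Pearson r and OLS regression of measured on programmed
amplitude with R² = r². The "±" value quoted alongside a mean
difference is reported as three separately named statistics (SD, SE, CI
half-width) because summary "± " conventions are ambiguous; the
patient-waveform comparison uses the printed absolute differences,
the sine-motion comparison signed ones.

## Problem sizes and numerical choices

Default simulation grids are sized to hold the largest envelope
(D + E = 39 mm) with margin rather than a clinical FOV: CBCT 64×48×48
at 1 mm, CT 32×48×48 at 2.5/1.27 mm. The acceptance script simulates
E ∈ {5, 9, 14, 19} mm at T = 5 s noiselessly for recovery and envelope
checks and runs in about a minute; tests share these simulations
through session fixtures. Determinism: a single run seed fans out to
per-scenario substreams by CRC-32 of the scenario label (kept < 2³¹),
so identical seeds give bit-identical volumes and byte-identical
reports, and adding a scenario does not perturb the others. Scenarios
whose segmentation or fit fails are listed as excluded rows with the
reason, mirroring non-analyzable cells in a measurement campaign.

## Limitations

No projection-domain physics (scatter, beam hardening, arc geometry,
gantry-angle-dependent sampling), no couch/rod mechanics, no deformable
targets, no intensity-weighted centroids, and no landmark-position
binning — agreement numbers obtained on this simulator characterize the
*measurement chain*, not scanner hardware. The bundled benchmark-table
statistics are recomputed from transcribed published measurements; the
underlying phantom images are not publicly deposited, so those numbers
validate the statistics stage only.
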