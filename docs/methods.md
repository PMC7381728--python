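# Methods

## Signal model

A microbubble contrast agent infused at constant rate is a blood-pool tracer:
its steady-state concentration in an ROI is proportional to fractional blood
volume, and its refill rate after destruction is proportional to blood flow
velocity. The package models the ROI-mean linear-scale intensity of one
acquisition as a piecewise process:

1. **Wash-in.** From the start of the infusion the signal rises as
   `y0 + A(1 − e^(−t/τ))` with τ = 60 s by default, so the plateau is reached
   (> 99%) by the 5-minute mark at which the monitoring protocol fires its
   first flash. The protocol only specifies "steady state by 5 min"; the
   saturating-exponential shape and its time constant are this package's
   choice, made once so the pre-flash plateau is well defined.
2. **Flash destruction.** A high-MI pulse is idealized as an instantaneous
   reset of the intensity to the baseline `y0`. Real destructive pulses last
   seconds; that dead-time is absorbed into the recirculation delay below.
3. **Recirculation.** After a flash the signal is clamped at `y0` for
   `recirculation_delay` seconds (default 30 s, the protocol's recirculation
   gap) while fresh bubbles re-enter the field.
4. **Replenishment.** The signal then follows
   `y0 + A(1 − e^(−β(t − t_flash − delay)))` with region-specific (A, β).

A treatment effect multiplies β of the *treated* region for every
replenishment after a chosen flash index (default: after the first flash),
mirroring a therapy block applied between the two fitted flashes. The control
region keeps its kinetics, so treated-vs-control comparison isolates the
effect from systemic drifts.

## Noise and compression

CEUS magnitude images are speckle-dominated, so the default noise is
multiplicative and mean-preserving: each pixel value is scaled by
`1 + s·(R/E[R] − 1)` with `R ~ Rayleigh(1)`, giving relative standard
deviation ≈ 0.52·s (the default scale 0.1 ≈ 5% per pixel). Additive Gaussian
noise is available for unit tests. ROI-level curves generated directly
(`simulate_tic`, curves-only cohorts) scale the noise by `1/√n_pixels` of the
region mask so they are statistically equivalent to extracting a mean TIC
from a rendered image. The noise families are stand-ins — the scanner's
actual signal statistics are not published — so tests quantify recovery under
speckle-like conditions, not instrument calibration.

Optional log compression stores `code = max_code·(1 + (20/DR)·log10(v/ref))`
(amplitude convention, 20·log10; the scanner's true mapping is not published,
so the convention is recorded in the sequence metadata). `linearize` inverts
it on a normalized scale where `max_code → 1.0`, or back to absolute units
when the reference is recorded. Codes are kept as floats; integer
quantization would dominate the round-trip error budget.

## TIC extraction, flash detection, segmentation

TICs are the arithmetic mean of linear intensities over an ROI mask per frame
(log-compressed input is refused, not silently converted; a background ROI's
per-frame mean can be subtracted with clamping at zero). Flash events are
detected as ratio drops: frame *i* is an event when its intensity is below
`(1 − drop_fraction)` of the trailing 10-s median *and* the signal was still
above that threshold `window` frames earlier — the transition condition
prevents re-triggering during the post-flash dead-time, and the ratio form
makes detection invariant to global intensity scaling. Events within a 5-s
refractory period merge to the first.

Each flash yields one replenishment segment: the fit origin is
`t_flash + recirculation_delay` (the instant the clamp releases), samples run
from there to one frame before the next flash (or the sequence end, or a
fixed duration), and times are re-zeroed to the origin. Anchoring the origin
at the clamp release rather than at the flash itself makes noiseless recovery
exact; whether the recirculation gap was inside the authors' fitted windows
is not stated, so the start offset is exposed and recorded. Segments with
fewer than 8 samples are dropped with a warning.

## Fitting

`ReplenishmentRegressor` solves bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, analytic Jacobian,
tolerances 1e-10, ≤ 500 evaluations) for (A, β) with an optional baseline
`y0 ≥ 0`. The printed replenishment equation has no baseline, but real TICs
have a nonzero floor; the default fits `y0` and reports it, and
`fit_offset=False` gives the strict two-parameter form. Bounds: `A ≥ 0`,
`β ∈ (1e-6, 10] s⁻¹`. Initialization is deterministic and data-driven:
plateau = mean of the last 20% of samples, floor = first sample, `Â₀` their
difference, `β̂₀ = 1/t63` from the first crossing of 63.2% of the rise
(fallback 0.01 s⁻¹ when the curve never crosses). Intensities are normalized
by their maximum before optimisation, making the fit exactly equivariant
under global intensity scaling (β invariant; A, y0 proportional). Degenerate
segments (near-zero variance) and stalled optimizations return
`converged=False` with a reason instead of raising; 95% intervals come from
the local curvature (Gauss–Newton) covariance with a t critical value.

Derived metrics: analytic AUC on `[0, T]` and the flow proxy `A·β`. Neither
has a published reference value in the motivating study; they are provided as
metrics only.

## Volumetrics

Each sweep slice is a slab of thickness `step` (no inter-slice
interpolation), so TV is exactly computable and additive; box phantoms whose
dimensions are multiples of the step and pixel spacing are recovered exactly,
and a 5-mm-radius sphere at the protocol's 0.2 mm step is recovered within
0.1%. 3D RBV is defined as the summed supra-threshold linear contrast inside
the tumor masks (threshold default 0, recorded in the output; a
pixel-count mode is provided as the alternative reading of "arbitrary pixel
units" — the study does not state which was used). Tumor masks are inputs,
not auto-segmented.

## Treatment analysis and statistics

Per subject, the first and last detected flashes anchor the pre and post
fits; intermediate therapy-cycle transients are never fitted. Percent changes
use the pre-phase parameter as the base. Control normalization defaults to
the difference of percent changes (`Δ_treated − Δ_control`), with a
ratio-of-ratios mode available; the mode is stamped into every output row
because the study names the normalization without a formula.

Cohort statistics report mean ± sd of the per-subject normalized change plus
two paired tests against no change: a two-sided one-sample t on the
per-subject changes and a Wilcoxon signed-rank (exact null for n ≤ 25, normal
approximation above; zero differences dropped, the "wilcox" convention, and
all-zero cohorts reported as undefined rather than given a p-value). The
primary p-value follows the Wilcoxon below n = 8 and the t-test from n = 8
up. Subjects with any non-converged required fit are excluded and counted,
never silently NaN-ed.

## Problem sizes and defaults

The canonical scenario is a 750 s acquisition at 4 Hz over a 64×64 grid
(0.1 mm pixels): flashes at 300 s and 630 s, 30 s recirculation, treated disk
(A = 10 a.u., β = 0.05 s⁻¹), control disk (A = 8, β = 0.05), background strip
(A = 0), speckle scale 0.1. β = 0.05 s⁻¹ puts the fitted rates on the same
scale as reperfusion rates reported for comparable preparations
(a few times 10⁻² s⁻¹). The final 120 s of replenishment after the last flash
is this package's choice — the protocol states when the final flash fires but
not how long replenishment was imaged — and is enough to identify β down to
≈ 0.0125 s⁻¹ (multiplier 0.25).

Cohorts draw subject-level A and β from mean-preserving lognormals (CV 0.2)
around the template values and a β multiplier per subject (constant or
lognormal; non-positive draws are rejected, logged, and redrawn). Image-based
cohorts render full sequences; `curves_only=True` generates ROI-level TICs
with the √n-scaled noise above and is used for the 1000-repetition null
calibration, where rendering 20 images per repetition would add nothing but
runtime. A human-protocol preset (`human_preset`) exercises the
short-window flash-replenishment cycling regime in which fitted plateaus
underestimate RBV.

## What the phantom does and does not show

Passing tests demonstrate parameter recovery, detection reliability, and
statistical calibration under idealized conditions: piecewise-constant
region kinetics (an optional intra-region β gradient exists for robustness
tests), instantaneous flashes, no motion, no attenuation or depth-dependent
gain, stationary speckle, and exactly known ROIs. They do not validate
performance under probe motion, tissue inhomogeneity, nonlinear propagation
artifacts, or scanner-specific compression — on real data the linearization
parameters must come from the instrument, and motion correction is out of
scope.

## Known limitations

- Frame timestamps are `start + i/frame_rate`; per-frame DICOM time jitter is
  not corrected.
- DICOM support is read-only (multi-frame files and single-frame series
  ordered by InstanceNumber).
- The flash detector assumes replenishment windows longer than the refractory
  period (5 s); faster protocols need the thresholds adjusted.
- Percent-change statistics treat per-subject fitted parameters as exact;
  fit uncertainty is reported (CIs) but not propagated into the cohort tests.
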