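# Methods

This note documents the models, estimators and numerical choices behind
`pcmri`: what the phantom simulates, how each analysis stage works, which
parameters matter, and what the package's tests do and do not establish
about real scanner data.

## The phantom

The simulated object is a straight cylindrical vessel imaged in exact
cross-section: a circular lumen of radius R (default 0.5 mm, the scale of
a rat common carotid artery) centered in a 40 mm field of view, embedded
in static tissue.

**Flow.** Through-plane velocity is separable into a radial profile and a
cardiac waveform, v(d, t) = v_c(t)·(1 − (d/R)^p). The profile exponent
p = 2 gives Poiseuille flow (steady laminar flow in a tube; `numpy.inf`
gives plug flow for oracle constructions). The waveform is a diastolic
baseline plus a raised-cosine systolic pulse:
v_c(t) = v_dia + (v_sys − v_dia)·g(t), with g a raised cosine of width
`systolic_fraction`·RR centered at RR/4, so the pulse sits in the first
half-cycle and g attains exactly 1 at its center. Defaults: v_sys = 80,
v_dia = 20 cm/s, systolic_fraction = 0.3, RR = 150 ms (≈ 400 bpm). These
are stated assumptions at rat physiology scale, not measured values —
published protocols do not print the vessel's waveform or diameter. The
cycle mean of g is exactly `systolic_fraction`/2, which the quadrature
test uses as its oracle.

**Signal model.** PC-MRI derives velocity from the phase difference of
two velocity-encoding segments. The phantom simulates a flow-compensated
reference segment S_ref (zero phase) and an encoded segment S_enc with
phase π·v/VENC plus the background offset, both with magnitude
`blood_magnitude` inside the lumen and `tissue_magnitude` (default 0.3×)
outside. Both segments receive independent complex Gaussian noise with
per-channel σ = blood_magnitude/(snr·√NEX). The stored phase image is
arg(S_enc·conj(S_ref)) wrapped to [−π, π) and the magnitude image is
|S_ref|. Modelling the two segments explicitly is what makes the phase
noise come out as √2·σ/|S| — the factor the VNR noise model assumes —
while keeping every noiseless value identical to a single-image
formulation.

**Partial volume.** All signal is built on a supersampled grid
(`supersample_factor` 8 per axis) and *complexly* box-averaged into
acquisition pixels. Averaging complex signal, not magnitudes or phases
separately, is the physical mixing mechanism: a boundary pixel's phase
becomes the argument of the magnitude-weighted complex mean, dominated by
the brighter blood. The whole-FOV flux implied by pixel phases and
magnitudes matches the supersampled ground truth to better than 1% even
at 0.63 mm, while individual boundary pixels are strongly biased — which
is exactly the resolution effect the studies measure.

**Gating.** A gated scan acquires one frame per temporal-resolution slot
2·TR inside the gating window (frame k at t = (k + ½)·2·TR;
n_frames = ⌊gating_fraction·RR/(2·TR)⌋, 4 frames at the default
protocol). A non-gated scan is modelled as the complex mean of the
encoded segment over 32 uniform cardiac phases — a k-space averaging
surrogate, documented as a modelling choice rather than a claim of
sequence fidelity. Because the complex mean of spread phases has a
smaller argument than the arithmetic phase mean for the skewed
(short-systole) waveform, the non-gated scan systematically
underestimates mean velocity and flow (~3–9% per subject at default
settings) while leaving the *shape* of the profile nearly unchanged, so
WSS is much less affected — the gating effect the studies report.

**Noise calibration.** The per-excitation blood SNR default (36) is the
one free noise parameter; it was calibrated once so the reference
protocol (gated, VENC 120 cm/s, NEX 8, matrix 128) yields a
velocity-to-noise ratio of ≈ 22, the value published for that protocol.
NEX enters as 1/√NEX on σ, which also implements the NEX/resolution
coupling of the resolution study ({4, 8, 12, 16} repetitions at
0.63/0.31/0.21/0.16 mm).

**Coordinates and units.** Pixel centers sit at (i + ½)·spacing from the
FOV corner, x along columns, y along rows; lengths are mm, times ms,
velocities cm/s, phases rad throughout; WSS is the only SI conversion
(a gradient of 1 (cm/s)/mm is 10 s⁻¹).

## Analysis chain

**Phase to velocity.** v = φ·VENC/π. The convention (φ = π at v = VENC)
is fixed package-wide; it is exactly invertible for |v| ≤ VENC.

**Background offset correction.** Eddy-current and concomitant-gradient
phase offsets are emulated as a smooth polynomial and corrected by
fitting the temporal-mean velocity over *static tissue* with ordinary
least squares on [1, x, y] (order 1, default) or [1, x, y, x²+y²]
(order 2). Static tissue is defined as: temporal-mean magnitude above
0.2× the robust (99th-percentile) maximum, temporal velocity SD below
VENC/20, and outside the lumen mask dilated by 2 pixels; the fit refuses
to run on fewer than 200 pixels or less than 5% of the FOV. On noiseless
polynomial backgrounds the recovery is exact to machine precision
(least squares on noiseless data in the model class); a `corrected`
flag makes the correction idempotent by contract. Correction runs
*before* unwrapping because an offset ramp can push near-VENC voxels
across the wrap boundary.

**Aliasing correction.** Velocities beyond ±VENC wrap by 2·VENC.
Correction is region-median unwrapping inside a caller-supplied ROI:
voxels are visited from the ROI boundary inward (chessboard-distance
ordering; boundary voxels are assumed unwrapped in the seeding pass,
because near-wall flow is slow), and a voxel whose velocity differs from
the median of its already-settled 8-neighbours by more than VENC is
shifted by ±2·VENC, whichever reduces the difference. Up to 9 further
relaxation sweeps cover the whole ROI — including the boundary ring,
where wraps can sit when the lumen is only a couple of pixels across —
and non-convergence returns a flagged partial result. The correction is
a single-wrap budget (|v| ≤ 3·VENC after correction) and assumes the
grid resolves the radial gradient: if the velocity step between
neighbouring pixels approaches VENC, a wrap is indistinguishable from a
real gradient (a Nyquist-like condition). Within that regime the
wrap→unwrap round trip is exact to 10⁻⁶ cm/s on noiseless phantoms, and
noisy low-VENC scans in the study driver reproduce the VENC-120 flows to
±0.6%.

**Lumen segmentation.** The boundary is found on the frame-averaged
magnitude image. A detection threshold is placed at a fraction (default
0.35) of the way from the background intensity (window median) to the
robust lumen intensity (99.5th percentile) within a 5 mm window around
the seed (the brightest point, or a user-supplied position — a manual
ROI can still be supplied as a mask). The contour is the iso-contour of
the grayscale image at that level, traced after 4× cubic upsampling for
sub-pixel smoothness, then least-squares fitted by a closed *uniform
periodic cubic B-spline* with K = 12 control points (the basis is
implemented in-package; SciPy's spline fitting has no fixed-K periodic
parametric least-squares mode). Fits are rejected if self-intersecting
(retried once at K−2) or if the RMS boundary distance exceeds 0.5 px.
Area is the shoelace integral on a 512-point evaluation; masks rasterise
pixel centers by the even-odd rule.

Placing the threshold near the detection level rather than the 50%
midpoint is deliberate: it emulates a rater tracing the visible outer
rim of the bright vessel, which is how partial-volume spreading inflates
measured lumen size at coarse resolution *in vivo*. The consequence is a
small one-sided positive area bias at the finest grid (≈ +8% for the
reference 0.5 mm radius at 0.16 mm, growing like pixel/R for smaller
vessels) in exchange for the physically correct monotone overestimation
across the resolution sweep. The fraction is configurable
(`threshold_fraction=0.5` recovers the midpoint rule).

**Flow, mean velocity.** Flow is Σ v·(spacing/10)² mL/s over the
contour mask per frame, with the cycle mean attached (the single frame
for non-gated scans); mean velocity is the arithmetic mask mean.

**Wall shear stress.** WSS = η·|dv/dr| at the wall, with η = 3.5×10⁻³
N·s/m². For each of 36 rays from the contour centroid the wall radius
R_θ is interpolated from the contour; velocity is sampled bilinearly at
20 radii spanning [0.4·R_θ, R_θ]. Samples within 0.75 px of the wall are
excluded (their bilinear support mixes extraluminal, partial-volume
corrupted pixels which otherwise bend the fit upward near the wall), and
the radial model is extrapolated to R_θ. The default model is a
quadratic without a wall-zero constraint — exact for a parabolic profile
— but it is only trusted when the guarded window spans ≥ 1 px with ≥ 6
samples; below that (lumens 1–2 px across) the extrapolated curvature is
numerically unstable and a linear fit is used, which degrades gracefully
toward the underestimation that coarse resolution produces physically.
When the guard band would leave fewer than 4 samples, the innermost
on-grid samples are used. Rays with fewer than 4 usable samples are
dropped; > 25% dropped rays is an error. A `linear-with-wall-zero`
variant (v = s·(R−r)) is provided for sensitivity checks; it
underestimates curved profiles by construction. Gated WSS is averaged
over frames then rays; non-gated over rays only. On the noiseless
Poiseuille phantom at 0.16 mm the estimator recovers 2η·v_max/R within
7%, and it is consistent with 4ηQ/(πR³) from measured flow and radius
within 20%.

**VNR.** The velocity noise of an interior lumen pixel follows
σ_v = (VENC/π)·√2/SNR. SNR is measured as the blood signal (90th
percentile of in-mask temporal-mean magnitude, robust to the
partial-volume-dimmed rim) over the noise SD of a background region (the
lowest-intensity decile outside the 3-px-dilated lumen). The noise SD is
the pooled within-pixel across-frame SD: selecting the region by its own
intensity truncates the between-pixel distribution, and a plain regional
SD would read ~12% low; the pooled estimator is independent of the
selection and matches a 200-seed Monte-Carlo velocity SD within 2%.
Single-frame (non-gated) data fall back to the spatial SD, which is
slightly conservative. Noiseless data return an infinite VNR, flagged.

## Study drivers

Each simulated subject is the base phantom with multiplicative Gaussian
jitter (default 10% SD) on radius and the two waveform levels, seeded
per subject; repeats share anatomy and differ only in the noise seed,
emulating back-to-back scans without repositioning. Study 1 crosses
{gated, non-gated} with VENC 60–120 cm/s in 10 cm/s steps at matrix 128,
NEX 8, two repeats; Study 2 sweeps matrix {64, 128, 192, 256} (0.63,
0.31, 0.21, 0.16 mm) with NEX {4, 8, 12, 16} at gated VENC 120. Failed
cells are recorded and tolerated up to 10% of the grid. Reproducibility
is CoVⱼ = (1/I)·Σᵢ SDₖ/meanₖ (sample SD), reported in percent; the
implementation is property-tested against a literal two-loop reference.
ANOVA-style hypothesis testing is deliberately out of scope — the raw
per-cell table is exported for any statistics package.

Desk-scale problem sizes used by the test suite and the acceptance
script: 12 subjects with 1 noiseless repeat for the resolution sweep,
12 subjects × 2 repeats × full VENC grid for the noisy gating study, and
200 noise seeds for the Monte-Carlo VNR check. The gating comparison is
made on per-subject means across the VENC grid (the same pooling the
original ANOVA design implies); at a single VENC the weakest subject's
~3% bias is of the same order as the ~1.4% scan-to-scan noise.

## What the phantom does and does not establish

Passing tests show the *estimators* are correct and that the acquisition
physics modelled here (complex partial-volume mixing, cycle averaging,
wrapping, thermal noise) reproduce the directional findings: non-gated
flow is biased low with WSS nearly unchanged; coarse resolution inflates
flow and area and suppresses WSS, with 0.21 mm comparable to 0.16 mm;
VENC choice is immaterial once unwrapping is applied. They do not
establish absolute in vivo accuracy: the phantom has no physiological
variability between repeats (its CoVs of ~1% are far below the ~7–8%
reported in vivo, where physiology dominates), no in-plane flow,
motion, ghosting or k-space artifacts, a perfectly circular lumen, and a
stylised waveform. Numerical edge cases: degenerate contours, empty
masks, uniform images, too-few static pixels and non-converged unwraps
all raise typed errors rather than returning silent values.
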