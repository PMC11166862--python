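# Methods

This note records the models, conventions, parameter defaults and
numerical choices behind `effcnr`, and what the synthetic-phantom tests do
and do not establish about real scanner data.

## Coordinates and units

Hounsfield units (HU) are the universal internal unit; raster formats that
cannot store negative values (16-bit PNG) carry an affine offset/scale in
a JSON sidecar. Pixel coordinates are 0-based `(row, col)` with pixel
centers at integer positions; pixel `(i, j)` spans
`[i−0.5, i+0.5] × [j−0.5, j+0.5]`. All analysis operates in pixel units;
physical pixel spacing (mm) is carried as metadata only.

## Apparent noise

`moving_average_sd` averages every fully-contained r×r window of the ROI
(stride 1, `(side−r+1)²` windows) and returns the sample SD (n−1
denominator) of the window means. Fully-contained windows avoid
edge-padding artifacts; the stride-1 overlap matches how the filter is
conventionally slid. At `r = side` only one window exists and no SD can be
formed, so the valid range is `1 ≤ r < side`. `r = 1` reduces to the
ordinary pixel SD ("Noise SD").

`fit_apparent_noise` fits `σ_SD(r) = σ_Apparent / r` over `5 ≤ r ≤ 10`.
Because the law has a single parameter, the log-space least-squares
solution with slope fixed at −1 is the closed form
`σ_Apparent = exp(mean(ln σ_SD + ln r))`. The unconstrained log–log slope
is reported as a linearity diagnostic (`free_slope`), and
`single_point_apparent_noise` provides the graph-free shortcut
`r · σ_SD(r)` at `r = 7`.

Two estimator properties worth knowing, both visible in the test suite:

* **Finite-ROI bias.** On a 40×40 ROI the window means at large r share
  most of their pixels, the grand mean absorbs part of the variance, and
  σ_SD(r) is biased slightly low at large r. For i.i.d. noise the
  free slope therefore averages ≈ −1.08 rather than −1.00 and σ_Apparent
  sits ≈ 3% below the true pixel SD. Both effects are far smaller than
  the texture signal the index is designed to detect (inflation factors
  of 2–4).
* **Sampling noise.** For strongly correlated noise a 40×40 ROI holds few
  independent texture patches, so single-ROI σ_Apparent values scatter by
  ±20% or so; multi-seed averages are used wherever a calibrated value is
  asserted.

Default ROI: 40×40 pixels at the image center, configurable.

## Edge profile extraction

`extract_radial_profile` casts `n_angles = 360` rays (1° spacing) from the
signal center and samples the image at integer distances `1..50` along
each ray, averaging samples of equal distance. Bilinear interpolation is
the default — it makes the profile stable under image rotation (verified
to < 1 HU RMS at 37°) — with nearest-neighbor available for strict
pixel-level replication. Rays that would leave the image raise an error
naming the maximum usable radius rather than silently truncating.

The radial axis maps to the model's t-axis as `t = radius − radius[0]`,
i.e. t = 0 at the first profile point near the center, so a 50-point
profile spans `t ∈ [0, 49]`, strictly inside the model's domain `t < T`.
The measured differential profile subtracts adjacent means,
`Δ[i] = mean[i] − mean[i+1]`, oriented so a bright insert gives a positive
peak.

`estimate_center` is a convenience for synthetic and well-behaved phantom
images: the centroid of supra-threshold pixels weighted by their excess
over the threshold (background-level-free, sub-pixel, accurate to
< 0.1 px on rendered disks). It is not a segmentation algorithm.

## The edge model and the sharpness index

The edge profile is modeled as `f(t) = B + C0 · Φ(g(t))` with
`g(t) = [λ + (γ + σ²/2)(T − t)] / (σ √(T − t))`, `T = 50`,
`λ = ln 10⁻¹³ ≈ −29.93` fixed. Φ(g) decays from ~1 at t = 0 to exactly 0
as t → T (g → −∞ because λ < 0), producing the plateau–edge–background
shape. σ acts as a diffusion (blur) coefficient; γ moves the transition
(the half-max sits where `λ + (γ + σ²/2)(T − t) = 0`); the baseline B
absorbs the background HU level so background-shifted profiles can be
fitted directly (the alternative — pre-subtracting the tail mean and
fitting the 3-parameter form — is available by passing a custom `init`
and bounds pinning `baseline`).

**Differential-profile convention.** The sharpness index is the maximum
of the *per-1-pixel difference* `D(t) = Φ(g(t)) − Φ(g(t+1))`, evaluated
on a fine grid of step Δt = 0.10 over `[0, T−1)`. This mirrors the
measured differential profile (adjacent subtraction at 1 px spacing) and
makes the unblurred limit exact: as σ → 0 the whole unit mass of Φ falls
within one pixel and max D = 1, so C1 = C0. The sign is chosen
signal-minus-background (positive peak for a bright insert), which is the
orientation in which the index lies in (0, 1]. The continuous derivative
`dΦ(g)/dt = φ(g(t)) · g′(t)`, `g′(t) = −(a·u − λ)/(2σu^{3/2})` with
`u = T − t`, `a = γ + σ²/2`, is exposed as `analytic_differential` purely
as a cross-check (it matches stable central finite differences to 1e−6
relative over the differential's support); the per-pixel-difference value
is canonical.

**Fitting.** `(C0, σ, γ, B)` are fitted by bounded least squares
(scipy TRF) with `σ ∈ [10⁻³, 50]`, `|C0| ≤ 5000` HU, B within the
observed HU range ± the data span, γ free. Initialization: B₀ = outer-20%
mean, C0₀ = inner-20% mean − B₀, σ₀ = 1, and γ₀ placing the model
half-max at the measured half crossing. If the first solve fails, three
deterministically perturbed restarts are tried and the best result is
returned with its convergence flag (never an exception); profiles whose
inner/outer level difference is below 1 HU are rejected as flat.

**Identifiability.** When the edge is heavily smeared relative to the
window (σ ≈ 2 with the half-max at t ≈ 15, i.e. Φ(g(0)) ≈ 0.82), the
plateau never enters the 50 px profile and C0 becomes an extrapolated
parameter: noiseless recovery is still exact, but a 2 HU measurement
noise produces heavy-tailed C0 errors (tens of percent). This is a
property of the model/geometry, not of the optimizer; noisy-recovery
tolerances are therefore asserted on the canonical well-posed edge
(C0 = 60 HU, σ = 1), where the 10-seed mean error is ≈ 1.5%.

## Synthetic phantoms

`make_disk_phantom` renders `background + contrast · coverage + noise`,
where coverage is the anti-aliased disk indicator (8×8 supersampling per
pixel), optionally smoothed with a Gaussian of `edge_blur_sigma`. Noise is
generated independently of the signal (stationary across insert and
background): a white Gaussian field, optionally smoothed at
`noise_corr_sigma` and rescaled by the smoothing kernel's L2 norm so the
marginal SD is preserved while the correlation changes. Identical spec +
seed yields bit-identical images.

**What the generator does not emulate:** streaks and other anisotropic
FBP texture, noise nonstationarity across the field of view, beam
hardening, scanner MTF shape beyond a Gaussian blur, and the nonlinear,
locally adaptive behavior of real IR/DLR algorithms. Passing tests
establish the estimators' correctness and calibration on Gaussian
stationary texture, not the physical fidelity of any preset.

**Pixel-sampling floor on sharpness.** A rendered *unblurred* disk edge
still spreads over ~1.5 px (pixel-area coverage plus bilinear sampling),
so the fitted sharpness index of a blur-0 phantom is ≈ 0.70, not 1 — the
index 1 calibration is exact for a true step *profile*, which is how the
calibration test asserts it. Consequently the identity "effective CNR =
conventional CNR for white noise and no blur" also holds at profile
level, while the end-to-end rendered version carries the ≈ 0.7 sampling
factor. On real scanner images the same floor applies to any analysis at
1 px radial sampling and cancels in comparisons between reconstructions.

**Presets.** The three reconstruction-style presets were calibrated, via
the measured inflation-ratio-vs-correlation curve of the estimator
itself, to land near the noise characteristics reported for modern
scanner reconstructions (inflation ratios σ_Apparent / Noise SD of ≈ 1.0
for FBP, ≈ 3.7 for IR, ≈ 2.3 for DLR), with the FBP/IR edges more gradual
than the sharper DLR edge:

| preset | noise SD (HU) | corr. scale (px) | edge blur (px) | typical σ_App (HU) |
|---|---|---|---|---|
| `fbp_like` | 30 | 0 (white) | 1.6 | ≈ 29 |
| `ir_like` | 5 | 1.3 | 1.4 | ≈ 18 |
| `dlr_like` | 7 | 0.75 | 0.8 | ≈ 16 |

The default insert is a 12 px-radius, +60 HU ("iodine-like") disk in a
0 HU water background on a 128×128 grid; a low-contrast "blood-like"
insert is obtained by setting `insert_contrast_hu` to 12–17. With these
presets the ranking-reversal demo is stable: conventional CNR orders
IR > DLR > FBP while effective CNR orders DLR > IR > FBP, across every
seed tested (10/10). The presets are qualitative stand-ins — no claim is
made that they reproduce any vendor's algorithm.

## Effective CNR conventions

Effective CNR uses the *magnitude* of the effective contrast (a
detectability index should be non-negative; the signed C0 is preserved in
the report). The noise ROI and the signal image may come from different
images — noise is best measured in a large uniform region — and both
provenances, the estimated center, the fit diagnostics and a config hash
are recorded in the report.

## Problem sizes and determinism

Test and acceptance runs use 128×128 phantoms, 40×40 noise ROIs, 10–20
noise realizations per Monte-Carlo assertion, and the 12-cell parameter
grid for fit recovery; the full suite runs in seconds. Every stochastic
step draws from `numpy.random.default_rng` seeded explicitly —
`scripts/acceptance.py` derives all sub-seeds from its `--seed` argument
— so identical invocations are bit-reproducible.

## Known limitations

* Single circular bright insert only; no automatic segmentation, no
  non-circular signals, no MTF or noise-power-spectrum estimation, no
  observer models (d′, NPWE).
* 2-D single-slice analysis; no volumes or multi-frame DICOM.
* The apparent-noise index summarizes texture with one number; noise
  fields whose correlation is anisotropic or non-Gaussian may share a
  σ_Apparent yet look different.
* The sharpness index inherits the 1 px radial sampling floor described
  above; comparisons between images are meaningful, the absolute value
  of a near-ideal edge saturates around 0.7 end-to-end.
* The edge model's C0 is poorly identified for edges much wider than the
  profile window (see Identifiability above).
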