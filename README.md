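# effcnr — effective contrast-to-noise ratio analysis for CT images

`effcnr` quantifies the contrast resolution of CT images in a way that
tracks what readers actually see. The conventional contrast-to-noise ratio

```
CNR = (P_signal − P_background) / Noise SD
```

uses the pixel SD of a uniform background region as its noise term, and it
misranks images produced by nonlinear reconstructions: iterative (IR) and
deep-learning (DLR) algorithms suppress the pixel SD aggressively while
leaving spatially correlated, "blocky" noise texture and blurred edges that
the CNR never sees. `effcnr` implements a texture- and sharpness-aware
alternative, the **effective CNR**, together with a synthetic phantom
generator so the whole chain is testable without scanner data. It is aimed
at medical physicists and image-quality researchers doing phantom QA and
reconstruction-algorithm comparisons.

## Method

**Apparent noise.** An r×r moving-average filter (r = 1…20) slides in
1-pixel steps over a 40×40 ROI of a uniform region, and the SD of the
window means, σ_SD(r), is recorded. For uncorrelated noise the central
limit theorem gives σ_SD(r) = σ_Apparent / r with σ_Apparent equal to the
pixel SD; spatially correlated noise decays more slowly, so the
one-parameter 1/r law fitted over the empirically linear range 5 ≤ r ≤ 10
(log–log, slope fixed at −1) yields an **apparent noise index** σ_Apparent
that exceeds the pixel SD by exactly the texture penalty.

**Sharpness.** 360 rays, one per degree and 50 px long, are cast from the
center of a circular insert; sampled CT numbers at equal radial distance
are averaged into a 50-point edge profile. The profile is fitted by the
closed-form solution of a stochastic differential equation for CT numbers,

```
f(t) = B + C0 · Φ(g(t)),   g(t) = [λ + (γ + σ²/2)(T − t)] / (σ √(T − t)),
```

with Φ the standard normal CDF, T = 50 px, λ = ln 10⁻¹³ fixed, and
(C0, σ, γ, B) fitted by bounded nonlinear least squares. The **sharpness
index** is the peak of the model's per-pixel differential profile
max_t [Φ(g(t)) − Φ(g(t+1))] on a Δt = 0.10 grid — exactly 1 for an
unblurred edge, smaller with blur — and the **effective contrast** is
C0 × sharpness index.

**Effective CNR.**

```
effective CNR = |C0 × Sharpness Index| / σ_Apparent
```

## Worked example

The built-in demo renders three synthetic phantoms whose noise SD, noise
correlation scale and edge blur emulate FBP-, IR- and DLR-style
reconstructions at matched insert contrast (60 HU), then analyzes each:

```
$ effcnr demo --seed 1
{
 "presets": {
  "fbp_like": {"noise_sd_hu": 29.31, "sigma_apparent_hu": 27.81,
               "sharpness_index": 0.201, "conventional_cnr": 2.10,
               "effective_cnr": 0.45},
  "ir_like":  {"noise_sd_hu": 5.31,  "sigma_apparent_hu": 20.66,
               "sharpness_index": 0.246, "conventional_cnr": 11.38,
               "effective_cnr": 0.73},
  "dlr_like": {"noise_sd_hu": 6.99,  "sigma_apparent_hu": 16.95,
               "sharpness_index": 0.426, "conventional_cnr": 8.46,
               "effective_cnr": 1.50}
 }
}
conventional CNR ranking: ir_like > dlr_like > fbp_like
effective CNR ranking:    dlr_like > ir_like > fbp_like
```

Reading the numbers: the IR-like image wins conventional CNR purely on its
tiny pixel SD (5.3 HU), but its apparent noise is four times larger
(20.7 HU) because the noise is spatially correlated, and its edge is soft
(index 0.246). The effective CNR therefore puts the DLR-like image first —
sharper edge (0.426) at comparable apparent noise — and the ranking
reverses, while the noisy FBP-like image stays last under both metrics.

The same analysis is available from Python:

```python
import effcnr

reports = effcnr.compare_presets(seed=1)
print(reports["dlr_like"].effective_cnr)        # 1.497...
```

or on your own images via `effcnr cnr --noise-input bg.dcm
--signal-input insert.dcm`, which prints the full report as JSON
(`effcnr --help` lists the `simulate`, `noise`, `edge`, `cnr` and `demo`
subcommands).

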