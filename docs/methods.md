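# Methods

This note documents the models, defaults and design choices behind `oacd`:
what the forward simulator emulates, how the attenuation estimators and the
decorrelation are computed, and which behaviors are intrinsic limitations
rather than bugs.

## Forward model (phantom)

The phantom generates post-reconstruction linear-intensity volumes directly;
spectral-domain reconstruction is out of scope.  One A-line of frame `m` is

    I_m[z] = s_m · h(z) · R_m[z] · exp(−2Δ Σ_{z'<z} μ_m[z']) + n[z]

* `μ` — attenuation coefficient (mm⁻¹).  Background (cortical parenchyma)
  defaults to 1.5 mm⁻¹; blood is strongly scattering at 1310 nm and vessel
  voxels default to 10 mm⁻¹.
* `R` — local reflectivity.  Static voxels draw `R ~ max(0, 1 + σ_s ξ)`
  once at construction (frozen speckle texture, σ_s = 0.2 by default).
* flow — inside a vessel, per frame: the reflectivity resamples per voxel
  (`R·(1 + f ξ)`, clipped at 0, `f` = `flow_decorr`), and the attenuation
  resamples **per A-line column** (`μ_v·(1 + f ξ)`, clipped).  The column
  granularity models the fact that the light transmitted through a vessel
  traverses the same moving blood along its whole path: coherent draws make
  the transmitted intensity fluctuate strongly between frames, which is the
  tail-artifact mechanism.  Independent per-voxel attenuation draws average
  out along the path and produce tails far weaker than the phenomenon this
  method exists to remove.
* `h(z) = (((z−z_cf)/z_R)² + 1)⁻¹` — confocal axial PSF (optional;
  `z_R = απn w₀²/λ`, α = 1 specular / 2 diffuse).
* `s_m` — optional per-frame source-power scalar (`1 + σ_p ξ`), modelling
  light-source instability.
* `n[z]` — additive half-normal noise floor (scale `noise_floor_level`,
  default 10⁻⁴ relative to unit incident intensity), so a noise floor exists
  and is estimable.

Two consequences are load-bearing and tested: (i) in a noiseless phantom,
static voxels beneath a vessel differ between frames only by a
depth-constant multiplicative factor; (ii) a static phantom produces
bit-identical frames and exactly zero decorrelation.

The default acquisition mimics a repeated-B-scan protocol: M = 10 repeats,
7.5 µm axial pitch, grid 192 (z) × 96 (x) × 48 (y) — scaled so the full
pipeline runs in seconds while keeping two full 450 µm slabs below the
surface.  The canonical study phantom has one large superficial vessel
(radius 7 px ≈ 105 µm diameter, the tail source) and one small deep vessel
(radius 2 px) laterally offset from the large vessel's shadow.

What the phantom does **not** emulate: fully developed speckle statistics
(reflectivity is a clipped Gaussian, not Rayleigh), multiple scattering,
bulk tissue motion between repeats, phase noise, and lateral beam blur.
Passing tests therefore demonstrate the mechanism and the pipeline's
correctness, not performance on in-vivo data, whose absolute quality
metrics depend on all of the above.

## Attenuation estimation

All OAC arithmetic is done on linear intensity; decibels appear only in the
5 dB noise rule.  Processing order per position: confocal correction →
noise-floor boundary → tail fit → estimator.

* **Noise floor** — adjacent A-lines are averaged in blocks of 8 (the
  averaging width is not critical; 8 balances SNR gain against lateral
  resolution), the floor is the mean of the deepest 10 % of samples, and
  the usable boundary `N` is the deepest sample ≥ floor·10^(5/10).
  A-lines that never clear the floor are flagged and excluded.
* **Tail fit** — `y = a·e^{−2μz} + b` least-squares (Levenberg–Marquardt,
  log-linear seed) over the last 30 valid samples above the boundary;
  a fit that fails or returns μ ≤ 0 falls back to the plain estimator for
  that A-line.
* **DR / ODRE** — as in the README.  The suffix sum is accumulated bottom-up
  so that (a) no catastrophic cancellation against the large shallow signal
  occurs at depth, and (b) a common scale factor on all depths ≥ z cancels
  exactly (bit-exactly for power-of-two factors).  The last pixel's empty
  sum takes `μ[N]` from the tail fit when available, else is flagged 0.
  Negative intensities are clamped to 0 and denominators below 10⁻¹² flag
  the pixel as 0.
* **Repeats share the boundary and the tail fit.**  Both are estimated once
  per position from the temporal mean of the M frames.  They describe the
  system and the static anatomy, and per-frame estimates would jitter with
  noise: a boundary that moves between repeats changes the summation range
  and injects spurious decorrelation into static tissue, defeating the
  cancellation the method relies on.

Known intrinsic behavior: the estimator at depth z depends on the signal
*below* z, so dynamic blood below a depth leaks a small decorrelation
upward (a faint haze above vessels in OAC decorrelation images).  This is
the mirror image of the amplitude tail, much weaker, and not removable
within the estimator; it slightly widens segmented vessels in OACD en-face
images.

## Decorrelation and en-face rendering

Decorrelation uses adjacent frame pairs only, as written above; the pair
term is a normalized correlation of two numbers, so D ∈ [0, 1] for any
input (fuzz-tested).  A pair with both samples zero contributes a pair term
of 1 (D contribution 0): below the noise floor the values carry no flow
information and treating dead pixels as static keeps them out of
maximum-intensity projections; they are flagged and masked downstream.

The tissue surface is detected per A-line as the first sustained (3
consecutive samples) 5 dB crossing above the noise floor, median-smoothed
laterally (window 5); slabs follow the detected surface because cortical
depth bands are anatomical, not planar.  Superficial = [surface, +450 µm),
deep = [+450 µm, +900 µm); at 7.5 µm pitch each slab is 60 px.  Projection
defaults to the per-column maximum (standard OCTA rendering); mean is
available.

**Residual large-vessel tail removal** (deep en-face): (i) binarize the
superficial en-face at its 75th positive percentile and keep components
whose median distance-transform diameter ≥ 4 px (large vessels); (ii) find
the best lateral registration of the large-vessel pattern to the deep image
over a ±2 px search and compute a local (9×9) normalized cross-correlation;
(iii) where the correlation ≥ 0.5 inside the dilated footprint, subtract
the least-squares-scaled pattern, clamped at 0.  The NCC + least-squares
realization and its thresholds are this package's reconstruction of
"pattern matching and subtraction"; pixels outside the footprint are never
touched, and an image with no large vessel passes through unchanged.

## Vascular quantification

* **Binarization** — local adaptive region growth.  Seeds: pixels above the
  98th global percentile plus pixels ≥ 6 robust SDs (median/MAD, 15×15
  window) above their neighborhood, so a dim vessel on a dim background is
  seeded even when brighter vasculature dominates the histogram.  Growth:
  a border pixel joins when it is ≥ local background mean + 3·SD, or above
  the local background mean *and* closer to the local vessel mean than to
  the background mean.  The two-class clause is needed because early in the
  growth the "background" window still contains the vessel's own unaccepted
  interior, which inflates the SD and would stall a pure mean + k·SD rule.
* **Skeleton** — components < 5 px are removed (they produce spurious
  endpoints, not vasculature), then Lee-method thinning to one-pixel width;
  this preserves connectivity and keeps the medial line of straight tubes
  exactly straight, which the tortuosity identity (straight ⇒ VT = 1)
  requires.
* **Diameter** — 2 × Euclidean distance transform of the mask, sampled at
  skeleton pixels.
* **Nodes** — endpoints have exactly one 8-connected skeleton neighbor;
  branch candidates (≥ 3 neighbors) merge by 8-connectivity into one node
  (thick junctions yield several adjacent candidates for one anatomical
  branch point).  Segments are traced between node pixels; an isolated ring
  is one cyclic segment whose chord is defined as its path length.
* **Metrics** — VPD = vessel pixels / image pixels; VL = Σ skeleton steps
  (1 axial, √2 diagonal — step weighting removes the diagonal bias of raw
  pixel counts); VAD = mean skeleton diameter (the interpretation consistent
  with a mean vessel caliber that grows under dilation); VT = Σ path / Σ
  chord over segments, a ratio of sums rather than a mean of per-segment
  ratios (configurable choice; the global ratio weights long segments more
  and is the convention used here).  Empty skeleton ⇒ zero metrics with
  VT = 1 by convention, flagged.

## Quality metrics

Pearson r (scipy), PSNR and mean Gaussian-window SSIM (scikit-image,
window 11, K₁ = 0.01, K₂ = 0.03, σ = 1.5), and GMSD implemented here
(Prewitt gradients normalized by 3, stability constant c = 0.0026 on [0,1]
images, deviation of the gradient-magnitude-similarity map) since no
installed library provides it; the implementation is cross-checked in the
tests against a literal loop transcription of the definition.  Images are
min–max normalized to [0, 1] before SSIM/GMSD and peak = 1.  On the
phantom, the reference image for PSNR/SSIM/GMSD is the ground-truth deep
vessel footprint, and the Pearson pairing is superficial en-face vs deep
en-face — fixed, documented choices; tail suppression is read from the
*ordering* of the two methods, not from absolute values.

## Determinism and problem sizes

Every stochastic step flows from a single integer seed through one
`numpy` generator per phantom; identical seeds give bit-identical volumes,
en-face images and CSVs.  Tests run the full pipeline on the default
192×96×48 grid (seconds per run); the source-fluctuation experiment uses a
static 160×64×8 grid, and estimator closed-form checks use single synthetic
A-lines.  These sizes were chosen to make the whole suite convenient to run
interactively while leaving every mechanism (two slabs, shadowing, noise
floor, truncation bias) fully expressed.
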