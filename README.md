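# oacd — OCT angiography by attenuation-coefficient decorrelation

`oacd` is a Python library and command-line tool for optical coherence
tomography angiography (OCTA) that extracts blood flow from the
frame-to-frame decorrelation of the depth-resolved **optical attenuation
coefficient** (OAC) instead of the backscattered amplitude, together with
the downstream vascular quantification (perfusion density, length, diameter,
tortuosity) used to characterize cortical vasculature.

## The problem: tail artifacts

OCTA repeats B-scans at each slow-axis position and maps flow as the
decorrelation of the signal between repeats.  Flowing red blood cells also
modulate the light *transmitted* through a vessel, so the static tissue
beneath every vessel flickers between repeats and lights up as a spurious
"tail" (projection artifact), hiding the deep microvasculature.

The attenuation coefficient removes the artifact at its root.  From a
linear-intensity A-line `I[z]` (axial pitch Δ, in mm), the depth-resolved
estimator is

    μ[z] = I[z] / (2Δ · Σ_{i=z+1}^{N} I[i])                       (DR)

and its optimized variant, which corrects the truncation bias at the bottom
of the usable range `N` with an exponential-tail term fitted from
`y = a·e^{−2μz} + b`,

    μ[z] = I[z] / (2Δ · Σ_{i=z+1}^{N} I[i] + I[N]/μ[N])           (ODRE)

Both depend only on the signal at and below `z`: a multiplicative
transmission change common to a depth and everything beneath it — exactly
what a flowing vessel imprints on the tissue below — cancels.  Decorrelating
OAC frames,

    D(x,z) = 1 − 1/(M−1) · Σ_m  S_m S_{m+1} / (½S_m² + ½S_{m+1}²),

therefore keeps intravascular flow contrast while suppressing tails and the
background decorrelation caused by source-power fluctuation.

Because no deposited in-vivo volumes exist for this method, the package
ships a physics-based phantom (`oacd.phantom`): layered tissue following
Beer–Lambert attenuation, a confocal axial PSF, and vessels whose
reflectivity and attenuation resample between repeats — reproducing both
flow contrast and the tail mechanism, with paired ground truth.

## Worked example

Run the full pipeline (phantom → confocal/OAC → amplitude and OACD
decorrelation → surface-following 450 µm slabs → en-face rendering →
residual-tail removal → quantification → quality report):

```
oacd pipeline all --seed 1 --out example/
```

or equivalently from Python:

```python
from oacd.cli import run_pipeline
summary = run_pipeline({"seed": 1}, "example/")
```

`example/quality.csv` compares the deep-slab en-face image of each method
against the phantom's ground-truth deep vasculature (PSNR/SSIM/GMSD) and
against the superficial vessel pattern (Pearson r — values near 0 mean the
deep slab no longer mirrors the superficial vessels, i.e. fewer tails):

```
   method  pearson_r  psnr_db  ssim  gmsd
amplitude      0.565   15.272 0.699 0.338
     oacd     -0.058   20.075 0.921 0.161
```

Amplitude decorrelation leaves a deep-slab ghost of the superficial vessel
(r = 0.57); OACD removes it (r ≈ 0) and matches the true deep vasculature
better on every fidelity metric.  `example/metrics.csv` holds the vascular
morphometry of each en-face image (VPD, VL, VAD, VT, branch/endpoint
counts), e.g. the superficial amplitude slab quantifies as a single straight
vessel: VT = 1.000, 0 branch nodes, 2 endpoints.

Individual stages are exposed as subcommands: `oacd phantom make`,
`oacd oac estimate --method dr|odre`, `oacd angio run`, `oacd quantify`,
`oacd quality report`.

## Layout

```
src/oacd/phantom.py        seeded Beer–Lambert forward simulator + ground truth
src/oacd/attenuation.py    confocal PSF correction, noise floor, DR/ODRE
src/oacd/angiography.py    decorrelation, surface/slabs, residual-tail removal
src/oacd/vasculometry.py   region-growth binarization, skeleton morphometry
src/oacd/quality.py        Pearson similarity, PSNR, SSIM, GMSD
src/oacd/volio.py          TIFF/JSON/CSV/YAML I/O
src/oacd/cli.py            subcommands and pipeline orchestration
docs/methods.md            model, parameter and design documentation
```
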