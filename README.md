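# saxskit

Planar small-angle X-ray scattering (pSAXS) data reduction and a
desk-scale simulation of SAXS computed tomography (SAXS-CT) of a mouse
head, for researchers studying nanoscale tissue structure — myelin in
particular — with scanning SAXS.

Scanning a thin brain slice through a pencil beam yields one scatter
profile I(q) per stage position, with q = 4π sin(θ)/λ the momentum
transfer.  Myelin's periodic lamellae produce characteristic peaks near
1 nm⁻¹ whose amplitude maps white matter, gray matter and the corpus
callosum.  The same cross sections, renormalized to the independent
atomic approximation (IAA) asymptote F²_IAA(q) = Σ_Z w_Z F_Z²(q), define
the coherent scattering of simulation materials for an *in vivo*
SAXS-CT design study: a translate–rotate pencil-beam scan of a
cylindrical mouse-head phantom, evaluated for radiation dose and
reconstructed-image SNR.

## What the package does

* **reduction** — detector frames → calibrated absolute profiles via the
  four-step chain: dark current with per-position offset,
  I′ = I − D_c − offset; transmission normalization I″ = I′/I′(0);
  holder-window background subtraction I‴ = I″ − I″_BG; absolute scaling
  I⁗ = C_f·I‴ against a glassy-carbon standard, with AgBe q-axis
  calibration (q_n = 2πn/d, d = 5.838 nm).
* **mapping** — per-q intensity maps over the scan raster, threshold
  segmentation into intensity bands, region-mean profiles (±σ), and peak
  tables with parabolic refinement.
* **materials** — Slater-orbital atomic form factors, IAA construction,
  renormalization and small-q/wide-q splicing, and attenuation
  coefficients (photoelectric/incoherent/coherent) with inverse-CDF
  coherent sampling tables.
* **forward** (`phantom`, `mc`, `expected`) — analog Monte Carlo photon
  transport through the concentric phantom (WM ∅8 mm split into two
  halves, GM 1 mm annulus likewise, skull 0.2 mm shell; 1.03/1.85 g/cm³)
  with per-region dose tallies, plus a deterministic single-scatter
  expected-sinogram model that makes full-fluence (10⁹
  histories/position) Poisson noise emulation tractable on a laptop.
* **recon** — ramp-filtered parallel-beam FBP per q bin, phantom-derived
  material masks, recovered material cross sections, and pixel SNR =
  μ/σ per material at a chosen q (default 1.03 nm⁻¹).
* **synthetic** — a generator of raw planar scans with planted ground
  truth (peaks at 0.96/1.60 nm⁻¹, class-dependent amplitudes, dark
  drift, window scatter, hidden calibration factor and q-scale error)
  used by the end-to-end tests.

## Worked example

Dose for one SAXS-CT slice of the mouse-head phantom, from a subsampled
Monte Carlo (every 4th translation, every 20th projection, 10⁴ histories
each) rescaled to the full plan's 10⁹ histories per beam position:

```python
from saxskit import *
from saxskit.mc import run_scan, dose_to_mGy

materials = default_brain_materials(20.0)
phantom = default_mouse_phantom()
plan = ScanPlan()                      # 100 x 360, 1e9 histories/position
detector = DetectorModel()             # 3 cm radius, 30 cm, 300 bins

sub = plan.subsample(every_translation=4, every_projection=20,
                     histories=10_000)
sino, tally = run_scan(phantom, materials, sub, detector, seed=42)
doses = dose_to_mGy(tally, scale_histories=plan.histories_per_position)
for k, v in doses.items():
    print(f"{k:>6}: {v:7.2f} mGy")
```

prints

```
   WM1:   11.81 mGy
   WM2:   11.80 mGy
   GM1:   11.71 mGy
   GM2:   11.70 mGy
 skull:   73.48 mGy
 total:  120.50 mGy
```

The dense 1.85 g/cm³ skull shell at the perimeter absorbs roughly six
times the dose of the soft brain materials; the total is the sum of the
five per-region mean doses.  The `expected` + `recon` modules then give
the white-matter pixel SNR at q = 1.03 nm⁻¹ (≈ 22 at full fluence with
the packaged synthetic stand-in cross sections).

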