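# Methods

This note records the models implemented in `saxskit`, the defaults and
why they were chosen, the numerical choices, and the known limits of
what the tests demonstrate.

## Momentum transfer and geometry

All scattering is parametrized by q = 4π sin(θ)/λ (nm⁻¹), with 2θ the
full scattering angle and λ = hc/E, hc = 1.23984 keV·nm.  A detector
pixel at radius r and sample–detector distance L subtends
2θ = atan(r/L).  Radial averaging uses half-open annular bins with
centers at r_i = i·Δr, so bin 0 is centered on the beam axis: it holds
the beamstop-attenuated primary and supplies the transmission value.
The default beam center sits on a pixel center so this bin is always
populated; it can be refined from the data by the center of mass of the
primary spot.

## Reduction chain

The chain is applied strictly in order, enforced by a unit-state machine
(raw_rate → dark_corrected → transmission_normalized →
background_subtracted → absolute); order invariance is deliberately not
claimed.

1. **Dark current.**  One dark frame is measured at the end of a scan;
   the drift over the scan is handled by a per-position constant offset,
   estimated as the mean of (I − D_c) over a signal-free window, default
   6.52–7.08 nm⁻¹.  The offset is *not* applied to reference standards
   (glassy carbon, AgBe), whose scatter does not vanish in that window.
   A per-scan (instead of per-position) offset can be emulated by
   passing `estimate_offset=False` and subtracting externally.
2. **Transmission.**  I″ = I′/I′(0).  The unknown beamstop attenuation
   cancels provided it is position-independent, and the primary
   intensity folded into the scale is re-absorbed by the calibration
   factor, because the standard is processed identically.  Tissue at
   different positions is assumed to share attenuation properties (no
   spectral hardening, single material attenuation per column).
3. **Background.**  The holder-window signal is the mean transmitted
   profile over positions flagged holder-only; subtracting it removes
   the window scatter exactly when the window term is
   position-independent.
4. **Absolute scale.**  C_f is the least-squares ratio of the known
   absolute glassy-carbon curve to the measured one over their common q
   range, restricted by default to q ≥ 0.6 nm⁻¹ so the primary's tail
   cannot bias the fit.  The packaged glassy-carbon curve is a synthetic
   stand-in with the right shape and magnitude (~33 cm⁻¹ sr⁻¹ plateau);
   users substitute a traceable curve for real work.

q calibration fits an affine map a·q + b from AgBe ring positions
(reference orders 2πn/d, d = 5.838 nm, the standard literature value)
detected above q = 0.6 nm⁻¹; a single detected ring yields a scale-only
map.

Two systematic floors are inherent to the method and visible in the
tests: the offset step removes whatever true signal lies in the
signal-free window (≈10⁻³ cm⁻¹ sr⁻¹ for the default synthetic power-law
background), and scatter reaching the primary bin biases C_f by the
scatter-to-primary ratio there (≈0.5% at the default generator primary
rate).

## Mapping

Intensity maps sample each position's profile at the measured bin
nearest the requested q (no interpolation, matching how measured maps
are drawn).  Threshold bands are closed-low/open-high.  Region-mean
profiles carry the per-q standard deviation across positions (±σ, not
standard error).  Peak detection runs `scipy.signal.find_peaks` on an
optionally moving-average-smoothed profile (odd width, default 3 bins)
with a prominence floor, then refines each position by a 3-point
parabola; widths are half-prominence widths converted to q units.
Anatomical labels are user metadata; the code never infers anatomy.

## Atomic data

No external data files are used; all atomic quantities are closed-form:

* **Coherent form factors** from Slater-type orbitals (Slater screening
  rules, shells 1s/2s2p/3s3p/4s, n\* = 1, 2, 3, 3.7).  Exact for
  hydrogen; within ≲15% of International Tables values for Z ≤ 20
  (cross-checked against gemmi's IT92 coefficients in the tests).
* **Incoherent scattering** as Klein–Nishina × the closure-approximation
  incoherent scattering function S(q, Z) = Z(1 − (F_Z/Z)²); Doppler
  broadening is neglected.
* **Photoelectric** cross sections from the empirical power law
  τ/ρ = 0.5894·(Z/8)^m(Z)·(15.999/A)·(20 keV/E)³ cm²/g, m(Z)
  piecewise-linear through (1, 4.98), (6, 4.740), (13, 4.472),
  (20, 4.340).  The fit is calibrated so that τ plus *this package's
  own* coherent and incoherent models reproduces standard total
  mass-attenuation values at 20 keV (H, C, O, Al, cortical bone); water
  then lands on 0.8096 cm²/g essentially exactly, and the implied
  photoelectric component (0.524 cm²/g) is independently consistent
  with the water mass energy-absorption coefficient (0.5367 cm²/g at
  20 keV ⇒ τ ≈ 0.53).  Valid for Z ≤ 20 and roughly 5–100 keV (all K
  edges below 4.1 keV).

A known bias: integrating nonrelativistic form factors overestimates
the true (relativistic, anomalous-corrected) Rayleigh cross section at
20 keV by tens of percent.  Because the calibration absorbs this into a
slightly lower photoelectric component, *total* attenuation is accurate
to ~1%, while the partition between coherent and photoelectric carries
a few-percent uncertainty that propagates into dose (see Limitations).

## Material tables

Eq-style IAA sums support both conventions: the literal mass-weight
form Σ w_Z F_Z² (default of `iaa_form_factor`) and the per-atom form
Σ x_Z F_Z².  Macroscopic physics uses the atom convention paired with
the exact atom density n = ρN_A Σ w_Z/A_Z, since only that pairing
reproduces the exact IAA macroscopic cross section
dΣ/dΩ = n r_e² P(θ) Σ x_Z F_Z².

Measured curves are renormalized by a single least-squares factor to
the IAA over 40–50 nm⁻¹ (soft tissue) or to a bone reference over
2.5–5 nm⁻¹ (skull), and small-q measured branches are spliced onto
wide-q references at 2.5 nm⁻¹ with a continuity rescale over a ±10%
matching band.  Coherent sampling tables are the inverse CDF of
P(θ)·F²S(q)·q on a 4096-point grid (dΩ = 2πq dq/k²), extended beyond
the tabulated range with the IAA tail up to the backscatter limit.

**Synthetic stand-ins.**  The study's measured WM1/GM1/skull curves and
the literature WM2/GM2/bone wide-q curves are not available, so
`materials_library` generates clearly-labeled synthetic stand-ins:
F²_IAA times a structure factor with myelin-like Gaussian peaks at 1.03
and 1.60 nm⁻¹ and a small-q excess, with absolute main-peak levels
(WM1/WM2/GM1/GM2 = 0.60/0.55/0.28/0.22 cm⁻¹ sr⁻¹) taken from the
intensity bands that segment planar brain maps.  The skull stand-in is
smooth with a mild collagen-like bump.  Every simulation result that
depends on the absolute coherent level (detector counts, SNR) inherits
this choice; dose is insensitive to it.

## Forward simulation

Transport is 2D in the slice plane, analog (no variance reduction,
weight 1), using Woodcock delta tracking against the largest material
attenuation coefficient — no surface bookkeeping, exactly unbiased.
Per-collision physics: photoelectric absorbs locally; coherent
scattering samples q from the material table and deflects by
2 asin(q/2k) without energy loss; incoherent scattering samples the
Klein–Nishina angle by rejection, deposits the recoil energy locally
(electron ranges at 20 keV are far below the geometry scale), and the
photon continues degraded — below 3 keV it is absorbed on the spot.
Deflections are applied in-plane with a random sign; out-of-plane
transport is neglected (pencil beam + thin slice makes it second-order
for the tallied metrics).  Photoelectric coefficients scale as E⁻³ with
the degraded photon energy and incoherent ones with the Klein–Nishina
total; the coherent coefficient is held at its build-energy value (it
does not deposit).  Energy is conserved exactly per history, and
per-position RNG substreams derive deterministically from (seed,
translation index, projection index).

The beam enters along +x at offset t with a uniform ±0.04° divergence
fan; the phantom is rotated per projection by rotating the material
lookup.  Escaping photons propagate to the detector plane 30 cm from
the phantom center, centered on the translated beam axis, and are
binned by radius into 300 annular bins (q = 0–10 nm⁻¹ at 20 keV; the
primary lands in bin 0 — there is no beamstop in simulation).

**Dose convention.**  Tallies are per *region* (the shell keeps its own
label even when its material is swapped), normalized by region mass =
area × slice thickness × density with a 1 mm default slice thickness
(the thickness of the measured tissue slices).  Reported doses are the
scan-averaged per-history tally times the per-position fluence
(10⁹ histories) over 6.24×10¹⁵ eV/g; the slice total is the sum of the
five per-region mean doses.  An energy-balance estimate shows this is
the only scaling consistent with the reference per-material values this
package is benchmarked against; multiplying instead by the plan's total
3.6×10¹³ histories would exceed them by a factor ≈ 36 000.  The
skull-removed variant replaces the shell's material with WM1 (a
GM2 replacement is one call away via `replace_shell`).

**Expected sinograms.**  For full-fluence noise studies an analog MC is
hopeless (3.6×10¹³ histories), so a deterministic single-scatter model
computes expected counts per bin as N₀·T·Σ_m ℓ_m·(dΣ/dΩ)_m(q_j)·ΔΩ_j,
with per-material path lengths ℓ_m obtained by dense sampling along the
chord (4096 steps over the phantom diameter; ~0.003 mm resolution) and
T the full-line transmission.  At the ≤5.7° angles the detector
subtends, the exit path is taken parallel to the beam, which makes the
entry×exit attenuation equal T independent of the scatter point.
Against a coherent-only analog MC the model agrees to ~4% (the
difference is the MC's multiple scattering).  Poisson sampling per cell
then emulates counting noise at any fluence.

## Reconstruction and SNR

Before FBP, every (translation, projection) column is divided by its
measured transmission — the primary bin over the incident fluence —
mirroring the planar chain's transmission step; without it, attenuation
artifacts dominate the reconstructed maps.  FBP is
`skimage.transform.iradon` with the Ram-Lak ramp filter and linear
interpolation, `circle=True`, one image per q bin, 100×100 pixels of
0.1 mm (the translation grid).  The empirically pinned orientation
convention (row = n//2 − x/Δ, col = n//2 + y/Δ) is frozen in
`pixel_coordinates` and a regression test.  Material masks label pixels
by the phantom material at their center, then erode by 1 pixel to drop
partial-volume boundary pixels.  SNR = mean/σ of masked pixels at the
bin containing the requested q (default 1.03 nm⁻¹, where the WM tables
peak); σ is the plain standard deviation, including reconstruction
texture.  The skull shell extends beyond the 10 mm scan field (phantom
diameter 10.4 mm) and is truncated by the reconstruction circle, so SNR
is reported for the brain materials; both skull variants are evaluated
on the standard material map.

## Synthetic raw-data generator

The generator emulates what the reduction chain assumes about real
scans: per-pixel expected rates T·(S_class(q) + w(q))/C_f* plus a
Gaussian beamstop-attenuated primary (3×10⁵ counts/s peak), dark
current with a linear temporal drift (0.02 counts/s per position),
Poisson counting noise, per-position transmission jitter (±5%
thickness), and reference frames for glassy carbon and AgBe.  Class
profiles are a capped power law (0.02·q⁻¹·⁵ above q = 0.1) plus
Gaussian peaks at 0.96 and 1.60 nm⁻¹ with amplitudes 0.74/0.44/0.24
cm⁻¹ sr⁻¹ for the three tissue classes — ratios ≈3:2:1 chosen so the
standard 0.50/0.35/0.20 band edges separate them.  Peak width σ = 0.1
nm⁻¹ (≈3 radial bins at the default grid).  Hidden parameters (C_f*,
q-scale error) are recoverable end-to-end: the calibration factor to
<1% (the recovered constant is C_f*·primary rate, since the
transmission step folds the primary into the scale), planted peaks and
q-scale to within one bin, class layout to ≥99%.

What the generator does *not* emulate: detector flat-field structure,
geometric distortion, phosphor blur, anisotropic scatter, position-
dependent window thickness, and tissue-drying kinetics.  Passing tests
therefore demonstrate the correctness of the chain's algebra and
statistics, not robustness to those instrument effects.

## Problem sizes

Default desk-scale runs: doses from 50 translations × 36 projections ×
2×10⁴ histories (3.6×10⁷ histories per variant, ~90 s); SNR from the
full 100×360 expected sinogram at 10⁹ histories/position with one
Poisson realization (~20 s); the test suite uses smaller subsamples of
the same machinery.

## Known limitations

* **Absolute dose scale.**  With the cross-section set calibrated as
  above, all per-region doses land a uniform ~19% below the reference
  per-material values (e.g. WM 11.7 vs 14.3 mGy; ratios between regions
  match to a few percent).  The residual is consistent with a single
  global normalization — most plausibly the reference voxel phantom's
  unstated slice thickness versus our principled 1 mm — and with
  PENELOPE-era cross-section differences; it was deliberately not tuned
  away, since the photoelectric component is independently anchored by
  the water energy-absorption coefficient.
* **SNR magnitude.**  White-matter pixel SNR at full fluence is ≈22
  with the stand-in absolute peak level of 0.60 cm⁻¹ sr⁻¹, and is
  counting-noise dominated, so it scales with the square root of the
  (unknown) true absolute coherent level; reference values near 31, and
  their insensitivity to the skull, imply a texture-dominated regime
  reached at roughly 2–3× higher peak cross sections.  Our SNR rises
  ~11% when the skull is removed (more transmitted fluence), a real
  effect at our noise level.
* Incoherent scattering uses the closure S(q, Z) and Klein–Nishina
  angles without binding effects in the *angular* sampling; coherent
  cross sections inherit the nonrelativistic form-factor overestimate
  noted above.
* 2D transport cannot tally out-of-plane dose spreading; per-unit-length
  masses make the tallies exact only in the thin-slice reading.
* The FBP applies no attenuation correction beyond the per-ray
  transmission normalization, and no scatter separation.
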