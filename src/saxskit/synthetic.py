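"""Synthetic pSAXS raw data with full ground truth.

The generator emulates the statistical structure a planar brain-slice
scan presents to the reduction chain: per-position detector frames whose
radial content is a class-dependent absolute profile (power-law diffuse
background plus myelin-like Gaussian peaks at 0.96 and 1.60 nm⁻¹, with
amplitudes varying by tissue class), divided by a hidden calibration
factor and multiplied by a per-position transmission; plus holder-window
scatter, a dark current with a linear temporal drift, Poisson counting
noise, and reference standards (glassy carbon at a known absolute level,
AgBe rings at q_n = 2πn/d).  A hidden q-scale error can be planted to
exercise the AgBe q calibration.  All outputs are deterministic under a
fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .geometry import InstrumentGeometry
from .reduction import AGBE_D_SPACING_NM, DetectorFrame
from .scanio import ScanContainer, glassy_carbon_reference_curve

DEFAULT_PEAKS = (0.96, 1.60)
#: per-class peak amplitudes, cm⁻¹ sr⁻¹ (classes 1..3, ratio ≈ 3:2:1,
#: placing the class intensities at the myelin peaks near 0.75/0.45/0.25
#: so the usual 0.50/0.35/0.20 band edges separate them)
DEFAULT_AMPLITUDES = (0.74, 0.44, 0.24)


@dataclass
class TissueLayout:
    """2D class-label map over scan positions (0 = holder only)."""

    labels: np.ndarray
    pitch_mm: float = 0.5

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.any(self.labels == 0):
            raise ValueError("layout needs at least one holder-only position")

    @classmethod
    def nested(cls, ny: int = 11, nx: int = 11, pitch_mm: float = 0.5
               ) -> "TissueLayout":
        """Nested rectangular blobs: holder border, then classes 3→1."""
        lab = np.zeros((ny, nx), dtype=int)
        for cls_id, margin in ((3, 1), (2, 2), (1, 3)):
            lab[margin:ny - margin, margin:nx - margin] = cls_id
        return cls(labels=lab, pitch_mm=pitch_mm)

    @property
    def positions(self) -> np.ndarray:
        ny, nx = self.labels.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        return np.column_stack([xx.ravel() * self.pitch_mm,
                                yy.ravel() * self.pitch_mm])

    @property
    def flat_labels(self) -> np.ndarray:
        return self.labels.ravel()


@dataclass
class GroundTruth:
    """Planted generator parameters (the recovery targets of the tests)."""

    peak_positions: tuple[float, ...] = DEFAULT_PEAKS
    peak_amplitudes: tuple[float, ...] = DEFAULT_AMPLITUDES
    peak_width: float = 0.10                  # Gaussian σ, nm⁻¹
    background_amp: float = 0.02              # power-law A·q^−p, cm⁻¹ sr⁻¹
    background_exp: float = 1.5
    window_amp: float = 0.06                  # holder-window scatter level
    dark_base_rate: float = 5.0               # counts/s per pixel
    dark_bump: float = 40.0
    drift_per_position: float = 0.02          # counts/s per acquisition step
    cf_true: float = 0.02                     # hidden calibration factor
    q_scale_error: float = 1.0                # hidden q-axis distortion
    transmission_mean: float = 0.8
    thickness_jitter: float = 0.05
    primary_rate: float = 3.0e5               # beamstop-attenuated, counts/s
    primary_sigma_px: float = 1.0
    noise: bool = True
    effective_cf: float = field(init=False, default=np.nan)

    def class_profile(self, cls_id: int, q) -> np.ndarray:
        """Absolute tissue profile of a class, cm⁻¹ sr⁻¹ (0 for holder)."""
        q = np.asarray(q, dtype=float)
        if cls_id == 0:
            return np.zeros_like(q)
        amp = self.peak_amplitudes[cls_id - 1]
        # the diffuse power law levels off below the resolvable q range so
        # it cannot contaminate the beamstop/primary bin
        out = self.background_amp * np.maximum(q, 0.1) ** (-self.background_exp)
        for p in self.peak_positions:
            out = out + amp * np.exp(-0.5 * ((q - p) / self.peak_width) ** 2)
        return out

    def window_profile(self, q) -> np.ndarray:
        """Holder-window scatter w(q), vanishing by the offset window."""
        q = np.asarray(q, dtype=float)
        return self.window_amp * np.exp(-q / 1.5) + 0.002

    def dark_rate(self, q, order: int) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return (self.dark_base_rate + self.dark_bump * np.exp(-q / 2.0)
                + self.drift_per_position * order)


def _frame_from_rate(rate, exposure_s, order, rng, noise):
    lam = np.clip(rate, 0.0, None) * exposure_s
    counts = rng.poisson(lam).astype(float) if noise else lam
    return DetectorFrame(counts=counts, exposure_s=exposure_s, order=order)


def generate_planar_scan(layout: TissueLayout, truth: GroundTruth,
                         geometry: InstrumentGeometry, seed: int,
                         exposure_s: float = 300.0
                         ) -> tuple[ScanContainer, GroundTruth]:
    """Synthesize a full scan container (frames, dark, standards).

    The hidden absolute scale recovered end-to-end is
    ``truth.effective_cf = cf_true · primary_counts``: the transmission
    division (Eq-2 style) folds the primary intensity into the profile
    scale and the fitted C_f absorbs it together with ``cf_true``.
    """
    rng = np.random.default_rng(seed)
    q_pix = geometry.q_of_radius(geometry.pixel_radii_mm())
    q_gen = q_pix * truth.q_scale_error          # planted q-axis distortion
    r_px = geometry.pixel_radii_mm() / geometry.binned_pitch_mm
    primary_shape = np.exp(-0.5 * (r_px / truth.primary_sigma_px) ** 2)

    labels = layout.flat_labels
    n_pos = len(labels)
    window = truth.window_profile(q_gen)
    frames = []
    transmissions = truth.transmission_mean * np.exp(
        rng.uniform(-truth.thickness_jitter, truth.thickness_jitter, n_pos))
    for i, cls_id in enumerate(labels):
        tissue = truth.class_profile(int(cls_id), q_gen)
        rate = (transmissions[i] * ((tissue + window) / truth.cf_true
                                    + truth.primary_rate * primary_shape)
                + truth.dark_rate(q_pix, i))
        frames.append(_frame_from_rate(rate, exposure_s, i, rng, truth.noise))

    # end-of-scan dark frame
    dark = _frame_from_rate(truth.dark_rate(q_pix, n_pos), exposure_s,
                            n_pos, rng, truth.noise)

    # glassy-carbon standard (no holder window at the standard's mount)
    gc_ref = glassy_carbon_reference_curve()
    t_gc = truth.transmission_mean
    gc_rate = (t_gc * (np.interp(q_gen, gc_ref.q, gc_ref.intensity)
                       / truth.cf_true
                       + truth.primary_rate * primary_shape)
               + truth.dark_rate(q_pix, n_pos + 1))
    gc_frame = _frame_from_rate(gc_rate, exposure_s, n_pos + 1, rng,
                                truth.noise)

    # AgBe standard: diffraction rings at q_n = 2πn/d
    q_max = float(np.nanmax(q_gen))
    agbe = np.zeros_like(q_gen)
    n_orders = max(1, int(q_max * AGBE_D_SPACING_NM / (2 * np.pi)))
    for n in range(1, n_orders + 1):
        q_n = 2 * np.pi * n / AGBE_D_SPACING_NM
        agbe += (60.0 / n) * np.exp(-0.5 * ((q_gen - q_n) / 0.05) ** 2)
    agbe_rate = (t_gc * (agbe + truth.primary_rate * primary_shape)
                 + truth.dark_rate(q_pix, n_pos + 2))
    agbe_frame = _frame_from_rate(agbe_rate, exposure_s, n_pos + 2, rng,
                                  truth.noise)

    truth.effective_cf = truth.cf_true * truth.primary_rate
    container = ScanContainer(frames=frames, positions=layout.positions,
                              background_flags=labels == 0,
                              dark_frame=dark, glassy_carbon_frame=gc_frame,
                              agbe_frame=agbe_frame,
                              glassy_carbon_reference=gc_ref,
                              geometry=geometry)
    return container, truth


def default_geometry(binning: int = 8, n_pixels: int = 260,
                     energy_keV: float = 8.05,
                     distance_mm: float = 70.0) -> InstrumentGeometry:
    """A compact Cu-Kα camera used by tests and examples.

    The default distance puts the full 8×8-binned frame's corner near
    q ≈ 18.9 nm⁻¹ with the first bins near 0.5 nm⁻¹, mirroring the
    wide-q planar configuration.  Smaller ``n_pixels`` shrink the frame
    (and the q range) for fast tests.
    """
    return InstrumentGeometry(energy_keV=energy_keV, distance_mm=distance_mm,
                              pixel_pitch_um=24.0,
                              detector_shape=(n_pixels * binning,
                                              n_pixels * binning),
                              binning=binning)


def generate_expected_counts_fixture(materials, plan, detector,
                                     n_steps: int = 1024):
    """Small deterministic expected-sinogram fixture for regression tests.

    Returns ``(SinogramStack, sha256 hex of the counts rounded to 1e-6)``;
    repeated invocation is bit-identical.
    """
    from .expected import expected_sinogram

    stack = expected_sinogram(materials=materials, plan=plan,
                              detector=detector, n_steps=n_steps,
                              phantom=_fixture_phantom())
    digest = hashlib.sha256(
        np.ascontiguousarray(np.round(stack.counts, 6)).tobytes()).hexdigest()
    return stack, digest


def _fixture_phantom():
    from .phantom import default_mouse_phantom

    return default_mouse_phantom()
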