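"""Instrument geometry and momentum-transfer (q) conversions.

The scattering variable is q = 4π sin(θ)/λ with 2θ the full scattering
angle and λ the wavelength; q is carried in nm⁻¹ throughout the package.
A detector pixel at radius r from the beam center subtends 2θ = atan(r/L)
for sample–detector distance L, so q(r) = (4π/λ) sin(½ atan(r/L)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: hc in keV·nm (photon energy E [keV] = HC_KEV_NM / λ [nm])
HC_KEV_NM = 1.23984


def wavelength_nm(energy_keV: float) -> float:
    """Photon wavelength in nm for an energy in keV."""
    if energy_keV <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_NM / energy_keV


def q_of_radius(r_mm, distance_mm: float, energy_keV: float):
    """q (nm⁻¹) at detector radius r (mm) for the given geometry."""
    if distance_mm <= 0:
        raise ValueError("sample-detector distance must be positive")
    lam = wavelength_nm(energy_keV)
    theta = 0.5 * np.arctan(np.asarray(r_mm, dtype=float) / distance_mm)
    return (4.0 * np.pi / lam) * np.sin(theta)


def radius_of_q(q_nm_inv, distance_mm: float, energy_keV: float):
    """Inverse of :func:`q_of_radius`: detector radius (mm) at a given q."""
    lam = wavelength_nm(energy_keV)
    theta = np.arcsin(np.asarray(q_nm_inv, dtype=float) * lam / (4.0 * np.pi))
    return distance_mm * np.tan(2.0 * theta)


@dataclass(frozen=True)
class InstrumentGeometry:
    """Planar SAXS camera geometry.

    ``beam_center`` is a continuous (row, col) position in *binned* pixel
    coordinates (0-based).  ``pixel_pitch_um`` is the unbinned pitch; the
    effective pitch is ``pixel_pitch_um * binning``.
    """

    energy_keV: float
    distance_mm: float
    pixel_pitch_um: float = 24.0
    detector_shape: tuple[int, int] = (2084, 2084)
    beam_center: tuple[float, float] | None = None
    binning: int = 1
    beamstop_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.energy_keV <= 0 or self.distance_mm <= 0:
            raise ValueError("energy and distance must be positive")
        if self.binning < 1:
            raise ValueError("binning factor must be >= 1")

    @classmethod
    def with_wavelength(cls, wavelength_nm_: float, **kwargs) -> "InstrumentGeometry":
        """Build from a wavelength, asserting E = hc/λ consistency to 1e-4."""
        energy = HC_KEV_NM / wavelength_nm_
        if "energy_keV" in kwargs:
            stated = kwargs.pop("energy_keV")
            if abs(stated - energy) / energy > 1e-4:
                raise ValueError(
                    f"energy {stated} keV inconsistent with wavelength "
                    f"{wavelength_nm_} nm (expected {energy:.5f} keV)"
                )
            energy = stated
        return cls(energy_keV=energy, **kwargs)

    @property
    def wavelength_nm(self) -> float:
        return wavelength_nm(self.energy_keV)

    @property
    def binned_shape(self) -> tuple[int, int]:
        return (self.detector_shape[0] // self.binning,
                self.detector_shape[1] // self.binning)

    @property
    def binned_pitch_mm(self) -> float:
        return self.pixel_pitch_um * self.binning * 1e-3

    @property
    def center(self) -> tuple[float, float]:
        if self.beam_center is not None:
            return self.beam_center
        # default on a pixel center so the r = 0 (primary/transmission)
        # radial bin is populated
        ny, nx = self.binned_shape
        return (float(ny // 2), float(nx // 2))

    def pixel_radii_mm(self) -> np.ndarray:
        """Radius from the beam center of every binned pixel, in mm."""
        ny, nx = self.binned_shape
        cy, cx = self.center
        yy, xx = np.mgrid[0:ny, 0:nx]
        return np.hypot(yy - cy, xx - cx) * self.binned_pitch_mm

    def max_radius_mm(self) -> float:
        ny, nx = self.binned_shape
        cy, cx = self.center
        corners = [(0.0, 0.0), (0.0, nx - 1.0), (ny - 1.0, 0.0), (ny - 1.0, nx - 1.0)]
        return max(np.hypot(y - cy, x - cx) for y, x in corners) * self.binned_pitch_mm

    def q_of_radius(self, r_mm):
        return q_of_radius(r_mm, self.distance_mm, self.energy_keV)


def compute_q_grid(geometry: InstrumentGeometry, n_radial_bins: int) -> np.ndarray:
    """Radial q grid for azimuthal averaging.

    Bin centers are placed at radii i·Δr, i = 0 … n-1 (arithmetic midpoints
    of the half-open radial bins [iΔr − Δr/2, iΔr + Δr/2)), so the first bin
    is centered on the beam axis and carries q = 0 — it holds the
    beamstop-attenuated primary and provides the transmission value.
    """
    if n_radial_bins < 2:
        raise ValueError("need at least 2 radial bins")
    dr = geometry.max_radius_mm() / (n_radial_bins - 1)
    r_centers = np.arange(n_radial_bins) * dr
    q = geometry.q_of_radius(r_centers)
    q[0] = 0.0
    return q


def radial_bin_index(geometry: InstrumentGeometry, n_radial_bins: int) -> np.ndarray:
    """Bin index of every binned pixel under the :func:`compute_q_grid` bins."""
    dr = geometry.max_radius_mm() / (n_radial_bins - 1)
    idx = np.floor(geometry.pixel_radii_mm() / dr + 0.5).astype(np.int64)
    return np.clip(idx, 0, n_radial_bins - 1)
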