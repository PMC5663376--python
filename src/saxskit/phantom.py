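"""Cylindrical mouse-head phantom, acquisition plan, detector model.

The default phantom is a concentric-cylinder mouse head slice: an 8 mm
diameter white-matter core split into upper/lower halves (WM1/WM2), a
1 mm gray-matter annulus likewise split (GM1/GM2), and a 0.2 mm skull
shell; densities 1.03/1.03/1.85 g/cm³.  Transport is 2D in the slice
plane; per-material masses use the region areas times a nominal slice
thickness (1 mm by default).

The acquisition is translate–rotate pencil-beam CT: 100 translations at
0.1 mm over a 1×1 cm² field and 360 projections at 1°, 10⁹ histories per
beam position at 20 keV, recorded by an ideal annular detector of 3 cm
radius at 30 cm with 300 radial bins (q = 0–10 nm⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import q_of_radius


@dataclass(frozen=True)
class Region:
    r_inner_mm: float
    r_outer_mm: float
    material: str
    half: str | None = None        # None | "upper" | "lower" (sign of y)
    label: str | None = None       # tally label; defaults to the material

    def __post_init__(self):
        if not 0 <= self.r_inner_mm < self.r_outer_mm:
            raise ValueError("need 0 <= r_inner < r_outer")
        if self.half not in (None, "upper", "lower"):
            raise ValueError("half must be None, 'upper' or 'lower'")

    @property
    def tally_label(self) -> str:
        return self.label if self.label is not None else self.material


@dataclass(frozen=True)
class Phantom:
    regions: tuple[Region, ...]
    slice_thickness_mm: float = 1.0

    def __post_init__(self):
        # every (radius, half) cell must map to exactly one region
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                overlap_r = (a.r_inner_mm < b.r_outer_mm
                             and b.r_inner_mm < a.r_outer_mm)
                overlap_h = (a.half is None or b.half is None
                             or a.half == b.half)
                if overlap_r and overlap_h:
                    raise ValueError(f"regions overlap: {a} / {b}")

    @property
    def material_names(self) -> list[str]:
        return [r.material for r in self.regions]

    @property
    def outer_radius_mm(self) -> float:
        return max(r.r_outer_mm for r in self.regions)

    def region_index_at(self, x_mm, y_mm) -> np.ndarray:
        """Region index per point (−1 outside every region)."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        r = np.hypot(x, y)
        out = np.full(r.shape, -1, dtype=np.int64)
        for i, reg in enumerate(self.regions):
            sel = (r >= reg.r_inner_mm) & (r < reg.r_outer_mm)
            if reg.half == "upper":
                sel &= y >= 0
            elif reg.half == "lower":
                sel &= y < 0
            out[sel] = i
        return out

    def material_at(self, x_mm: float, y_mm: float) -> str | None:
        i = int(self.region_index_at(np.array(x_mm), np.array(y_mm)))
        return None if i < 0 else self.regions[i].material

    def region_areas_cm2(self) -> np.ndarray:
        """Analytic area of each region, cm²."""
        areas = []
        for reg in self.regions:
            a = np.pi * (reg.r_outer_mm ** 2 - reg.r_inner_mm ** 2) * 1e-2
            areas.append(a / 2 if reg.half else a)
        return np.array(areas)

    def region_masses_g(self, densities: dict[str, float]) -> np.ndarray:
        """Mass of each region for the nominal slice thickness, g."""
        t_cm = self.slice_thickness_mm * 0.1
        return self.region_areas_cm2() * t_cm * np.array(
            [densities[r.material] for r in self.regions])

    @property
    def region_labels(self) -> list[str]:
        return [r.tally_label for r in self.regions]

    def replace_shell(self, material: str) -> "Phantom":
        """Swap the outermost shell's material (skull-removal variant).

        The shell keeps a distinct tally label ("shell") so its dose
        remains separately reportable even when its material matches the
        core."""
        outer = max(self.regions, key=lambda r: r.r_outer_mm)
        new = tuple(replace(r, material=material, label="shell")
                    if r is outer else r for r in self.regions)
        return replace(self, regions=new)


def default_mouse_phantom(shell_material: str = "skull") -> Phantom:
    """The concentric mouse-head slice (WM ∅8 mm, GM 1 mm, skull 0.2 mm)."""
    return Phantom(regions=(
        Region(0.0, 4.0, "WM1", half="upper"),
        Region(0.0, 4.0, "WM2", half="lower"),
        Region(4.0, 5.0, "GM1", half="upper"),
        Region(4.0, 5.0, "GM2", half="lower"),
        Region(5.0, 5.2, shell_material, half=None),
    ))


@dataclass(frozen=True)
class ScanPlan:
    n_translations: int = 100
    step_mm: float = 0.1
    n_projections: int = 360
    angular_step_deg: float = 1.0
    histories_per_position: int = 1_000_000_000
    energy_keV: float = 20.0
    divergence_deg: float = 0.08
    field_width_mm: float = 10.0

    def __post_init__(self):
        if not np.isclose(self.n_translations * self.step_mm,
                          self.field_width_mm):
            raise ValueError("n_translations * step must equal field width")
        if not np.isclose(self.n_projections * self.angular_step_deg, 360.0):
            raise ValueError("projections must cover 360 degrees")

    @property
    def translations_mm(self) -> np.ndarray:
        """Beam offsets; the grid is centered like the reconstruction grid
        (offset i ↔ image column i, center at index n//2)."""
        n = self.n_translations
        return (np.arange(n) - n // 2) * self.step_mm

    @property
    def projection_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_projections) * self.angular_step_deg

    @property
    def total_histories(self) -> float:
        return (float(self.histories_per_position) * self.n_translations
                * self.n_projections)

    def subsample(self, every_translation: int = 1, every_projection: int = 1,
                  histories: int | None = None) -> "SubsampledPlan":
        return SubsampledPlan(self, every_translation, every_projection,
                              histories or self.histories_per_position)


@dataclass(frozen=True)
class SubsampledPlan:
    """A thinned view of a plan: the same beam geometry on a subset of
    (translation, projection) positions, used for desk-scale runs whose
    per-history tallies estimate the full plan's."""

    plan: ScanPlan
    every_translation: int = 1
    every_projection: int = 1
    histories_per_position: int = 10_000

    @property
    def translations_mm(self) -> np.ndarray:
        return self.plan.translations_mm[::self.every_translation]

    @property
    def projection_angles_deg(self) -> np.ndarray:
        return self.plan.projection_angles_deg[::self.every_projection]

    @property
    def energy_keV(self) -> float:
        return self.plan.energy_keV

    @property
    def divergence_deg(self) -> float:
        return self.plan.divergence_deg


@dataclass(frozen=True)
class DetectorModel:
    distance_mm: float = 300.0
    radius_mm: float = 30.0
    n_bins: int = 300
    efficiency: float = 1.0

    def __post_init__(self):
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")

    @property
    def bin_width_mm(self) -> float:
        return self.radius_mm / self.n_bins

    def bin_radii_mm(self) -> np.ndarray:
        """Annular bin center radii (bin 0 contains the primary)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_mm

    def q_bin_centers(self, energy_keV: float) -> np.ndarray:
        q = q_of_radius(self.bin_radii_mm(), self.distance_mm, energy_keV)
        q[0] = 0.0  # primary bin
        return q

    def q_max(self, energy_keV: float) -> float:
        return float(q_of_radius(self.radius_mm, self.distance_mm, energy_keV))

    def solid_angles_sr(self) -> np.ndarray:
        """Exact solid angle of each annular bin seen from the sample."""
        edges = np.arange(self.n_bins + 1) * self.bin_width_mm
        cos_edges = np.cos(np.arctan(edges / self.distance_mm))
        return 2 * np.pi * (cos_edges[:-1] - cos_edges[1:])

    def bin_of_radius(self, r_mm) -> np.ndarray:
        """Annular bin index; −1 when beyond the detector edge."""
        idx = np.floor(np.asarray(r_mm, dtype=float)
                       / self.bin_width_mm).astype(np.int64)
        idx[idx >= self.n_bins] = -1
        return idx
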