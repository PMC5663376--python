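"""HDF5 scan-container I/O and packaged reference curves.

A scan container bundles everything one pSAXS acquisition produces: the
per-position frames, the end-of-scan dark frame, the glassy-carbon and
AgBe standard frames, stage positions, holder-only flags, and the
instrument geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import InstrumentGeometry
from .profiles import ScatterProfile, UnitState
from .reduction import DetectorFrame


def glassy_carbon_reference_curve(q=None) -> ScatterProfile:
    """Synthetic stand-in for the absolute glassy-carbon standard curve.

    Shaped like the real secondary standard (a ≈ 30 cm⁻¹ sr⁻¹ plateau
    below ~1 nm⁻¹ rolling off smoothly); replace with a traceable curve
    via :meth:`ScatterProfile.load_txt` when one is available.
    """
    if q is None:
        q = np.geomspace(0.02, 20.0, 400)
    q = np.asarray(q, dtype=float)
    intensity = 33.0 / (1.0 + (q / 4.0) ** 3.5) + 0.5
    return ScatterProfile(q=q, intensity=intensity,
                          sigma=0.01 * intensity,
                          unit_state=UnitState.absolute,
                          provenance=["synthetic glassy-carbon stand-in"])


@dataclass
class ScanContainer:
    frames: list[DetectorFrame]
    positions: np.ndarray
    background_flags: np.ndarray
    dark_frame: DetectorFrame
    glassy_carbon_frame: DetectorFrame
    agbe_frame: DetectorFrame | None
    glassy_carbon_reference: ScatterProfile
    geometry: InstrumentGeometry

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=np.stack(
                [fr.counts for fr in self.frames]))
            f.create_dataset("exposures_s", data=np.array(
                [fr.exposure_s for fr in self.frames]))
            f.create_dataset("orders", data=np.array(
                [fr.order for fr in self.frames]))
            f.create_dataset("positions_mm", data=self.positions)
            f.create_dataset("background_flags", data=self.background_flags)
            for name, fr in [("dark", self.dark_frame),
                             ("glassy_carbon", self.glassy_carbon_frame),
                             ("agbe", self.agbe_frame)]:
                if fr is None:
                    continue
                g = f.create_group(f"refs/{name}")
                g.create_dataset("counts", data=fr.counts)
                g.attrs["exposure_s"] = fr.exposure_s
                g.attrs["order"] = fr.order
            g = f.create_group("refs/glassy_carbon_reference")
            g.create_dataset("q_nm_inv", data=self.glassy_carbon_reference.q)
            g.create_dataset("intensity",
                             data=self.glassy_carbon_reference.intensity)
            geo = f.create_group("geometry")
            geo.attrs["energy_keV"] = self.geometry.energy_keV
            geo.attrs["distance_mm"] = self.geometry.distance_mm
            geo.attrs["pixel_pitch_um"] = self.geometry.pixel_pitch_um
            geo.attrs["detector_shape"] = self.geometry.detector_shape
            geo.attrs["binning"] = self.geometry.binning
            geo.attrs["beam_center"] = self.geometry.center

    @classmethod
    def load_hdf5(cls, path) -> "ScanContainer":
        import h5py

        with h5py.File(path, "r") as f:
            exposures = f["exposures_s"][()]
            orders = f["orders"][()]
            frames = [DetectorFrame(c, e, int(o)) for c, e, o in
                      zip(f["frames"][()], exposures, orders)]

            def ref_frame(name):
                if f"refs/{name}" not in f:
                    return None
                g = f[f"refs/{name}"]
                return DetectorFrame(g["counts"][()],
                                     float(g.attrs["exposure_s"]),
                                     int(g.attrs["order"]))

            gc_ref_g = f["refs/glassy_carbon_reference"]
            gc_ref = ScatterProfile(q=gc_ref_g["q_nm_inv"][()],
                                    intensity=gc_ref_g["intensity"][()],
                                    unit_state=UnitState.absolute,
                                    provenance=["loaded reference"])
            geo = f["geometry"].attrs
            geometry = InstrumentGeometry(
                energy_keV=float(geo["energy_keV"]),
                distance_mm=float(geo["distance_mm"]),
                pixel_pitch_um=float(geo["pixel_pitch_um"]),
                detector_shape=tuple(int(v) for v in geo["detector_shape"]),
                beam_center=tuple(float(v) for v in geo["beam_center"]),
                binning=int(geo["binning"]))
            return cls(frames=frames, positions=f["positions_mm"][()],
                       background_flags=f["background_flags"][()].astype(bool),
                       dark_frame=ref_frame("dark"),
                       glassy_carbon_frame=ref_frame("glassy_carbon"),
                       agbe_frame=ref_frame("agbe"),
                       glassy_carbon_reference=gc_ref, geometry=geometry)
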