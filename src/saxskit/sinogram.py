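"""Sinogram stacks: detector counts indexed (q_bin, translation, projection)."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class SinogramStack:
    counts: np.ndarray                 # (n_q_bins, n_translations, n_projections)
    q: np.ndarray                      # q at each annular bin center, nm⁻¹
    translations_mm: np.ndarray
    projection_angles_deg: np.ndarray
    histories_per_position: float
    meta: dict = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        expected = (len(self.q), len(self.translations_mm),
                    len(self.projection_angles_deg))
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if self.meta is None:
            self.meta = {}

    def bin_containing(self, q0: float) -> int:
        return int(np.argmin(np.abs(self.q - q0)))

    def scaled(self, factor: float) -> "SinogramStack":
        return replace(self, counts=self.counts * factor,
                       histories_per_position=self.histories_per_position * factor)

    def normalized_by_primary(self) -> "SinogramStack":
        """Divide every (translation, projection) column by its measured
        transmission, the primary (q = 0 bin) counts over the incident
        fluence — the CT analogue of the planar Eq-2 correction."""
        t = self.counts[0] / self.histories_per_position
        if np.any(t <= 0):
            raise ValueError("non-positive primary counts; cannot normalize")
        return replace(self, counts=self.counts / t[None, :, :],
                       meta={**self.meta, "transmission_normalized": True})

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts)
            f.create_dataset("q_nm_inv", data=self.q)
            f.create_dataset("translations_mm", data=self.translations_mm)
            f.create_dataset("projection_angles_deg",
                             data=self.projection_angles_deg)
            f.attrs["histories_per_position"] = self.histories_per_position
            for k, v in self.meta.items():
                f.attrs[str(k)] = v

    @classmethod
    def load_hdf5(cls, path) -> "SinogramStack":
        import h5py

        with h5py.File(path, "r") as f:
            meta = {k: v for k, v in f.attrs.items()
                    if k != "histories_per_position"}
            return cls(counts=f["counts"][()], q=f["q_nm_inv"][()],
                       translations_mm=f["translations_mm"][()],
                       projection_angles_deg=f["projection_angles_deg"][()],
                       histories_per_position=float(
                           f.attrs["histories_per_position"]),
                       meta=meta)
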