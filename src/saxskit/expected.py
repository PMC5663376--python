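"""Deterministic single-scatter expected sinograms and noise emulation.

For a pencil beam through the phantom the expected single-coherent-scatter
counts in annular detector bin j are a line integral along the beam path,

    N_j = N₀ · Σ_m ℓ_m · (dΣ/dΩ)_m(q_j) · ΔΩ_j · T_entry·T_exit ,

with ℓ_m the path length through material m and ΔΩ_j the bin's solid
angle.  At the small scattering angles subtended by the detector
(≤ 5.7°), the exit path is taken parallel to the beam, so the product of
entry and exit attenuations equals the full-line transmission
T = exp(−Σ ℓ_m μ_tot,m), independent of the scatter point.  The primary
(undeflected, unscattered) beam is recorded in bin 0, N₀·T.

This model is exact in the single-scatter, small-angle limit and allows
full-fluence (10⁹ histories/position) noise emulation by Poisson
sampling, which an analog Monte Carlo cannot reach at desk scale.
"""

from __future__ import annotations

import numpy as np

from .materials import Material
from .phantom import DetectorModel, Phantom, ScanPlan, SubsampledPlan
from .sinogram import SinogramStack


def path_lengths(phantom: Phantom, material_names: list[str],
                 t_mm: np.ndarray, phi_deg: float,
                 n_steps: int = 4096) -> np.ndarray:
    """Per-material path lengths (cm) of beams at offsets ``t_mm`` and
    projection angle ``phi_deg``, by dense sampling along the chord."""
    r_out = phantom.outer_radius_mm
    s = (np.arange(n_steps) + 0.5) / n_steps * 2 * r_out - r_out   # mm
    ds_cm = (2 * r_out / n_steps) * 0.1
    phi = np.deg2rad(phi_deg)
    cphi, sphi = np.cos(phi), np.sin(phi)
    t = np.asarray(t_mm, dtype=float)
    # beam frame point (s, t) → phantom frame via rotation by -phi
    x = cphi * s[None, :] + sphi * t[:, None]
    y = -sphi * s[None, :] + cphi * t[:, None]
    reg = phantom.region_index_at(x, y)
    mat_of_reg = np.array([material_names.index(r.material)
                           for r in phantom.regions])
    out = np.zeros((len(t), len(material_names)))
    for ri, mi in enumerate(mat_of_reg):
        out[:, mi] += (reg == ri).sum(axis=1) * ds_cm
    return out


def expected_sinogram(phantom: Phantom, materials: dict[str, Material],
                      plan: ScanPlan | SubsampledPlan,
                      detector: DetectorModel,
                      n_steps: int = 4096) -> SinogramStack:
    """Expected counts per (q bin, translation, projection); deterministic
    and bit-exactly repeatable."""
    sub = plan.subsample() if isinstance(plan, ScanPlan) else plan
    names = sorted(set(phantom.material_names))
    mats = [materials[n] for n in names]
    for m in mats:
        if abs(m.energy_keV - sub.energy_keV) > 1e-9:
            raise ValueError(f"material {m.name} not built at plan energy")
    n0 = float(sub.histories_per_position)
    q = detector.q_bin_centers(sub.energy_keV)
    domega = detector.solid_angles_sr()
    # counts per photon per cm of path, per material and bin (j >= 1)
    kmj = np.stack([m.differential_sigma_coh(q) * domega for m in mats])
    kmj[:, 0] = 0.0            # bin 0 is reserved for the primary
    mu_tot = np.array([m.mu_total for m in mats])

    trans = np.asarray(sub.translations_mm, dtype=float)
    angles = np.asarray(sub.projection_angles_deg, dtype=float)
    counts = np.zeros((detector.n_bins, len(trans), len(angles)))
    for j, phi in enumerate(angles):
        ell = path_lengths(phantom, names, trans, float(phi), n_steps)
        T = np.exp(-(ell * mu_tot[None, :]).sum(axis=1))
        scatter = np.einsum("tm,mj->jt", ell, kmj)
        counts[:, :, j] = n0 * T[None, :] * scatter
        counts[0, :, j] = n0 * T * detector.efficiency
    if detector.efficiency < 1.0:
        counts[1:] *= detector.efficiency
    return SinogramStack(counts=counts, q=q, translations_mm=trans,
                         projection_angles_deg=angles,
                         histories_per_position=n0,
                         meta={"mode": "expected"})


def sample_poisson_fluence(expected: SinogramStack, seed: int) -> SinogramStack:
    """Independent Poisson draws per cell with the expected means."""
    lam = expected.counts
    if not np.all(np.isfinite(lam)):
        raise ValueError("expected counts must be finite")
    rng = np.random.default_rng(seed)
    sampled = rng.poisson(lam).astype(float)
    return SinogramStack(counts=sampled, q=expected.q,
                         translations_mm=expected.translations_mm,
                         projection_angles_deg=expected.projection_angles_deg,
                         histories_per_position=expected.histories_per_position,
                         meta={**expected.meta, "mode": "sampled", "seed": seed})
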