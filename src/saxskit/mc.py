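"""Analog Monte Carlo pencil-beam photon transport with dose tallies.

Photons are transported in 2D in the slice plane of the cylindrical
phantom using Woodcock (delta) tracking against the largest material
attenuation coefficient, so no surface-intersection bookkeeping is
needed.  At a real collision the interaction type is sampled from
(μ_pe, μ_coh, μ_inc):

* photoelectric — the full photon energy is deposited locally;
* coherent — the momentum transfer q is drawn from the material's
  tabulated F²S(q)·polarization·q density (inverse CDF) and the photon
  deflects by 2θ = 2 asin(q/2k) without energy loss;
* incoherent — the deflection is drawn from the Klein–Nishina angular
  law by rejection, the Compton energy transfer is deposited locally
  (electrons are not transported; their range at 20 keV is sub-voxel),
  and the photon continues degraded; below 3 keV it is absorbed on the
  spot.

Deflections are applied in-plane with a random sign.  Escaping photons
are propagated to the annular detector plane (centered on the translated
beam axis) and binned by radius → q.  `DoseTally` accumulates deposited
energy per material, normalized by region mass (area × slice thickness ×
density); `dose_to_mGy` converts the scan-averaged per-history tally to
mGy at a reference per-position fluence using 1 Gy = 6.24×10¹⁵ eV/g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atomic import (ELECTRON_MC2_KEV, EV_PER_G_PER_GY, R_E_CM,
                     klein_nishina_total)
from .geometry import HC_KEV_NM
from .materials import Material
from .phantom import DetectorModel, Phantom, ScanPlan, SubsampledPlan
from .sinogram import SinogramStack

_ENERGY_CUTOFF_KEV = 3.0


@dataclass
class DoseTally:
    """Per-region deposited energy for a (possibly subsampled) scan.

    Regions are keyed by their tally label (= material name unless the
    phantom assigns one explicitly, e.g. the replaced "shell")."""

    region_labels: list[str]
    deposits_eV: np.ndarray            # (n_positions, n_regions)
    masses_g: np.ndarray               # per region
    histories_per_position: float
    seed: int

    @property
    def n_positions(self) -> int:
        return self.deposits_eV.shape[0]

    def per_history(self) -> dict[str, float]:
        """Scan-averaged tally in eV/g/history per region."""
        if self.n_positions == 0 or self.histories_per_position <= 0:
            raise ValueError("empty tally")
        total = self.deposits_eV.sum(axis=0)
        n_hist = self.histories_per_position * self.n_positions
        return {m: float(t / mg / n_hist) for m, t, mg in
                zip(self.region_labels, total, self.masses_g)}

    def per_history_se(self) -> dict[str, float]:
        """Standard error of the scan-averaged tally over beam positions."""
        per_pos = (self.deposits_eV / self.masses_g[None, :]
                   / self.histories_per_position)
        se = per_pos.std(axis=0, ddof=1) / np.sqrt(self.n_positions)
        return dict(zip(self.region_labels, se))


def dose_to_mGy(tally: DoseTally, scale_histories: float = 1e9
                ) -> dict[str, float]:
    """Convert per-history tallies to absorbed dose in mGy.

    ``scale_histories`` is the per-beam-position fluence being emulated
    (10⁹ for the reference scan).  The returned dict carries one entry per
    material plus ``"total"``, the sum of the per-material mean doses over
    all tallied regions.
    """
    if scale_histories <= 0:
        raise ValueError("scale_histories must be positive")
    per_hist = tally.per_history()
    doses = {m: v * scale_histories / EV_PER_G_PER_GY * 1e3
             for m, v in per_hist.items()}
    doses["total"] = float(sum(doses.values()))
    return doses


def _kn_differential(energy_keV, cos_theta):
    k = np.asarray(energy_keV) / ELECTRON_MC2_KEV
    ratio = 1.0 / (1.0 + k * (1.0 - cos_theta))
    return 0.5 * R_E_CM ** 2 * ratio ** 2 * (
        ratio + 1.0 / ratio - (1.0 - cos_theta ** 2))


def _sample_kn_cos(energy_keV: np.ndarray, rng) -> np.ndarray:
    """Rejection sampling of the Klein–Nishina deflection cosine."""
    n = len(energy_keV)
    out = np.empty(n)
    todo = np.arange(n)
    fmax = R_E_CM ** 2  # dσ/dΩ at θ = 0 for any energy
    while todo.size:
        c = rng.uniform(-1.0, 1.0, todo.size)
        f = _kn_differential(energy_keV[todo], c)
        accept = rng.random(todo.size) * fmax <= f
        out[todo[accept]] = c[accept]
        todo = todo[~accept]
    return out


class _MaterialPhysics:
    """Vectorized per-material coefficients for the transport kernel."""

    def __init__(self, materials: dict[str, Material], names: list[str],
                 energy_keV: float):
        missing = [n for n in names if n not in materials]
        if missing:
            raise KeyError(f"materials not built: {missing}")
        self.names = list(names)
        mats = [materials[n] for n in names]
        for m in mats:
            if abs(m.energy_keV - energy_keV) > 1e-9:
                raise ValueError(f"material {m.name} built at {m.energy_keV} "
                                 f"keV, plan wants {energy_keV}")
        self.energy0 = energy_keV
        self.mu_pe0 = np.array([m.mu_photoelectric for m in mats])   # cm⁻¹
        self.mu_inc0 = np.array([m.mu_incoherent for m in mats])
        self.mu_coh = np.array([m.mu_coherent for m in mats])
        self.kn0 = float(klein_nishina_total(energy_keV))
        self.materials = mats

    def mu_parts(self, mat_idx: np.ndarray, energy_keV: np.ndarray):
        """(μ_pe, μ_inc, μ_coh) in cm⁻¹; zero where mat_idx < 0 (vacuum)."""
        safe = np.maximum(mat_idx, 0)
        pe = self.mu_pe0[safe] * (self.energy0 / energy_keV) ** 3
        inc = (self.mu_inc0[safe]
               * klein_nishina_total(energy_keV) / self.kn0)
        coh = self.mu_coh[safe] * np.ones_like(pe)
        vac = mat_idx < 0
        if np.any(vac):
            pe, inc, coh = (np.where(vac, 0.0, a) for a in (pe, inc, coh))
        return pe, inc, coh

    def majorant(self, energy_keV: np.ndarray) -> np.ndarray:
        e = np.atleast_1d(np.asarray(energy_keV, dtype=float))
        pe = self.mu_pe0[:, None] * (self.energy0 / e[None, :]) ** 3
        inc = (self.mu_inc0[:, None]
               * (klein_nishina_total(e) / self.kn0)[None, :])
        return (pe + inc + self.mu_coh[:, None]).max(axis=0)


def simulate_position(phantom: Phantom, phys: _MaterialPhysics,
                      t_mm: float, phi_deg: float, n_histories: int,
                      detector: DetectorModel, rng,
                      divergence_deg: float = 0.0):
    """Transport one pencil-beam position.

    Returns ``(bin_counts, deposits_eV_per_material, escaped_eV)``;
    deposited plus escaped energy equals the injected energy exactly.
    """
    if n_histories <= 0:
        raise ValueError("need at least one history")
    region_mats = np.array([phys.names.index(r.material)
                            for r in phantom.regions] + [-1])
    e0 = phys.energy0
    r_out = phantom.outer_radius_mm
    phi = np.deg2rad(phi_deg)
    cphi, sphi = np.cos(phi), np.sin(phi)

    half = np.deg2rad(divergence_deg) / 2.0
    ang = (rng.uniform(-half, half, n_histories) if half > 0
           else np.zeros(n_histories))
    dirs = np.column_stack([np.cos(ang), np.sin(ang)])
    pos = np.column_stack([np.full(n_histories, -(r_out + 1.0)),
                           np.full(n_histories, t_mm)])
    energy = np.full(n_histories, e0)

    # advance analytically to the bounding circle (or escape directly)
    b = pos[:, 0] * dirs[:, 0] + pos[:, 1] * dirs[:, 1]
    c = (pos ** 2).sum(axis=1) - r_out ** 2
    disc = b ** 2 - c
    hits = (disc > 0) & (-b - np.sqrt(np.maximum(disc, 0)) > 0)
    s_entry = -b[hits] - np.sqrt(disc[hits])
    pos[hits] += dirs[hits] * (s_entry[:, None] + 1e-9)

    deposits = np.zeros(len(phantom.regions))
    esc_pos = [pos[~hits]]
    esc_dir = [dirs[~hits]]
    esc_E = [energy[~hits]]
    idx = np.flatnonzero(hits)
    for _ in range(100_000):
        if idx.size == 0:
            break
        e = energy[idx]
        mu_maj = phys.majorant(e) * 0.1                     # cm⁻¹ → mm⁻¹
        step = np.where(mu_maj > 0, -np.log(rng.random(idx.size))
                        / np.maximum(mu_maj, 1e-300), 1e9)
        pos[idx] += dirs[idx] * step[:, None]
        outside = (pos[idx] ** 2).sum(axis=1) >= r_out ** 2
        esc = idx[outside]
        esc_pos.append(pos[esc]); esc_dir.append(dirs[esc]); esc_E.append(energy[esc])
        idx = idx[~outside]
        if idx.size == 0:
            continue
        p = pos[idx]
        # phantom rotated by phi: look up material in the phantom frame
        xr = cphi * p[:, 0] + sphi * p[:, 1]
        yr = -sphi * p[:, 0] + cphi * p[:, 1]
        reg = phantom.region_index_at(xr, yr)
        mat = region_mats[reg]
        e = energy[idx]
        pe, inc, coh = phys.mu_parts(mat, e)
        mu_t_mm = (pe + inc + coh) * 0.1
        accept = rng.random(idx.size) * phys.majorant(e) * 0.1 <= mu_t_mm
        if not np.any(accept):
            continue
        real = idx[accept]                       # photon indices, real collision
        mat_r = mat[accept]
        reg_r = reg[accept]                      # tally by region
        e_r = energy[real]
        u = rng.random(real.size) * (pe + inc + coh)[accept]
        is_pe = u < pe[accept]
        is_coh = (~is_pe) & (u < (pe + coh)[accept])
        is_inc = ~(is_pe | is_coh)
        dead = np.zeros(real.size, dtype=bool)
        theta = np.zeros(real.size)

        if np.any(is_pe):
            np.add.at(deposits, reg_r[is_pe], e_r[is_pe] * 1e3)
            dead |= is_pe

        if np.any(is_coh):
            for mi in np.unique(mat_r[is_coh]):
                sel = is_coh & (mat_r == mi)
                q = phys.materials[mi].sample_coherent_q(rng.random(sel.sum()))
                k_e = 2 * np.pi * e_r[sel] / HC_KEV_NM      # nm⁻¹
                q = np.minimum(q, 2 * k_e * (1 - 1e-9))
                theta[sel] = 2 * np.arcsin(q / (2 * k_e))

        if np.any(is_inc):
            sel = is_inc
            cosv = _sample_kn_cos(e_r[sel], rng)
            kk = e_r[sel] / ELECTRON_MC2_KEV
            e_new = e_r[sel] / (1.0 + kk * (1.0 - cosv))
            np.add.at(deposits, reg_r[sel], (e_r[sel] - e_new) * 1e3)
            low = e_new < _ENERGY_CUTOFF_KEV
            if np.any(low):
                np.add.at(deposits, reg_r[sel][low], e_new[low] * 1e3)
            energy[real[sel]] = np.where(low, 0.0, e_new)
            theta[sel] = np.arccos(np.clip(cosv, -1.0, 1.0))
            dead[sel] |= low

        scattered = ~dead & ~is_pe
        if np.any(scattered):
            sc = real[scattered]
            rot = theta[scattered] * np.where(
                rng.random(scattered.sum()) < 0.5, 1.0, -1.0)
            ct, st = np.cos(rot), np.sin(rot)
            dx, dy = dirs[sc, 0].copy(), dirs[sc, 1].copy()
            dirs[sc, 0] = ct * dx - st * dy
            dirs[sc, 1] = st * dx + ct * dy

        still = np.ones(idx.size, dtype=bool)
        still[np.flatnonzero(accept)[dead]] = False
        idx = idx[still]
    else:  # pragma: no cover - safety net
        raise RuntimeError("transport did not terminate")

    esc_pos = np.concatenate(esc_pos)
    esc_dir = np.concatenate(esc_dir)
    esc_E = np.concatenate(esc_E)
    # bin escapes on the detector plane (centered on the beam axis)
    counts = np.zeros(detector.n_bins)
    fwd = esc_dir[:, 0] > 1e-9
    ep, ed, ee = esc_pos[fwd], esc_dir[fwd], esc_E[fwd]
    r_det = np.abs((ep[:, 1] - t_mm) + ed[:, 1] / ed[:, 0]
                   * (detector.distance_mm - ep[:, 0]))
    bins = detector.bin_of_radius(r_det)
    ok = bins >= 0
    np.add.at(counts, bins[ok], 1.0)
    if detector.efficiency < 1.0:
        counts *= detector.efficiency
    return counts, deposits, float(esc_E.sum() * 1e3)


def run_scan(phantom: Phantom, materials: dict[str, Material],
             plan: ScanPlan | SubsampledPlan, detector: DetectorModel,
             seed: int) -> tuple[SinogramStack, DoseTally]:
    """Simulate every (translation, projection) position of the plan.

    Per-position RNG substreams are derived deterministically from
    (seed, translation index, projection index), so identical seeds give
    identical scans regardless of execution order.
    """
    sub = plan.subsample() if isinstance(plan, ScanPlan) else plan
    hpp = sub.histories_per_position
    if hpp <= 0:
        raise ValueError("zero histories per position")
    names = sorted(set(phantom.material_names))
    phys = _MaterialPhysics(materials, names, sub.energy_keV)
    masses = phantom.region_masses_g(
        {n: materials[n].density for n in names})

    trans = sub.translations_mm
    angles = sub.projection_angles_deg
    counts = np.zeros((detector.n_bins, len(trans), len(angles)))
    deposits = np.zeros((len(trans) * len(angles), len(phantom.regions)))
    k = 0
    for j, phi in enumerate(angles):
        for i, t in enumerate(trans):
            rng = np.random.default_rng([seed, i, j])
            c, d, _ = simulate_position(phantom, phys, float(t), float(phi),
                                        int(hpp), detector, rng,
                                        sub.divergence_deg)
            counts[:, i, j] = c
            deposits[k] = d
            k += 1
    sino = SinogramStack(counts=counts,
                         q=detector.q_bin_centers(sub.energy_keV),
                         translations_mm=np.asarray(trans, dtype=float),
                         projection_angles_deg=np.asarray(angles, dtype=float),
                         histories_per_position=float(hpp),
                         meta={"seed": seed, "mode": "mc"})
    tally = DoseTally(region_labels=phantom.region_labels,
                      deposits_eV=deposits, masses_g=masses,
                      histories_per_position=float(hpp), seed=seed)
    return sino, tally
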