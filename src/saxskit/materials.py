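"""Material scattering tables and interaction coefficients.

The coherent scatter intensity of a material is I(q) = k F²(q) S(q); at
large q the measured F²S approaches the independent-atomic-approximation
(IAA) asymptote F²_IAA = Σ_Z w_Z F_Z²(q).  Measured relative curves are
put on an absolute (electron-units²) scale by fitting a single factor to
the IAA asymptote over a high-q window (40–50 nm⁻¹ for soft tissue,
2.5–5 nm⁻¹ against a bone reference for skull), and small-q measured data
are spliced onto wide-q reference curves with a continuity rescale at the
junction.

Two weighting conventions for the IAA sum are supported: the literal mass
weight fraction form (default, ``convention="mass"``) and the per-atom
form Σ_Z x_Z F_Z² with atom fractions x_Z (``convention="atom"``).  Only
the atom form, paired with the exact atom number density
n = ρ N_A Σ_Z w_Z/A_Z, yields the exact macroscopic IAA cross section, so
:func:`build_material` uses the atom convention internally for physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import atomic
from .atomic import (N_AVOGADRO, R_E_CM, element_zA,
                     klein_nishina_total, thomson_polarization_factor)
from .geometry import wavelength_nm


@dataclass(frozen=True)
class ElementalComposition:
    """Element → mass weight fraction; fractions must sum to 1."""

    fractions: dict[str, float]
    name: str = ""

    def __post_init__(self):
        if any(w < 0 for w in self.fractions.values()):
            raise ValueError("weight fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weight fractions sum to {total}, not 1")
        for sym in self.fractions:
            element_zA(sym)  # raises for unsupported elements

    def atom_fractions(self) -> dict[str, float]:
        mol = {s: w / element_zA(s)[1] for s, w in self.fractions.items()}
        tot = sum(mol.values())
        return {s: m / tot for s, m in mol.items()}

    def moles_per_gram(self) -> float:
        """Σ w_Z / A_Z — atoms (in moles) per gram of material."""
        return sum(w / element_zA(s)[1] for s, w in self.fractions.items())

    def electrons_per_gram(self) -> float:
        return N_AVOGADRO * sum(
            w * element_zA(s)[0] / element_zA(s)[1]
            for s, w in self.fractions.items())


# ICRP reference compositions (mass fractions) used for the simulation
# tissues; densities follow the phantom definition, not these references.
ICRP_BRAIN = ElementalComposition(
    {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712, "Na": 0.002,
     "P": 0.004, "S": 0.002, "Cl": 0.003, "K": 0.003}, name="brain (ICRP)")
ICRP_CORTICAL_BONE = ElementalComposition(
    {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
     "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225},
    name="cortical bone (ICRP)")
WATER = ElementalComposition({"H": 0.111894, "O": 0.888106}, name="water")


@dataclass
class FormFactorProfile:
    """Tabulated F²(q)S(q) curve.

    ``values`` are in electron-units² per composition unit once absolute
    (source "iaa" or after renormalization); measured curves may carry an
    arbitrary scale until renormalized.
    """

    q: np.ndarray
    values: np.ndarray
    source: str = "measured"            # measured | reference | iaa
    scale_note: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("F²S values must be non-negative")

    def interp(self, q) -> np.ndarray:
        return np.interp(q, self.q, self.values)

    def save_txt(self, path) -> None:
        np.savetxt(path, np.column_stack([self.q, self.values]),
                   header=f"source: {self.source}\nscale: {self.scale_note}\n"
                          "q_nm_inv F2S")

    @classmethod
    def load_txt(cls, path, source="measured") -> "FormFactorProfile":
        data = np.loadtxt(path)
        return cls(q=data[:, 0], values=data[:, 1], source=source)


def iaa_form_factor(comp: ElementalComposition, q_grid,
                    convention: str = "mass") -> FormFactorProfile:
    """F²_IAA(q) = Σ_Z w_Z F_Z²(q) (or Σ x_Z F_Z² with atom fractions)."""
    q = np.asarray(q_grid, dtype=float)
    if convention == "mass":
        weights = comp.fractions
    elif convention == "atom":
        weights = comp.atom_fractions()
    else:
        raise ValueError("convention must be 'mass' or 'atom'")
    f2 = np.zeros_like(q)
    for sym, w in weights.items():
        f2 += w * atomic.atomic_form_factor(sym, q) ** 2
    return FormFactorProfile(q=q, values=f2, source="iaa",
                             scale_note=f"IAA ({convention} weights)")


def renormalize_to_iaa(measured: FormFactorProfile, comp: ElementalComposition,
                       window: tuple[float, float],
                       convention: str = "mass") -> FormFactorProfile:
    """Scale a measured curve to the IAA asymptote over a high-q window."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("degenerate renormalization window")
    sel = (measured.q >= lo) & (measured.q <= hi)
    if not np.any(sel) or lo < measured.q[0] or hi > measured.q[-1]:
        raise ValueError("window outside the measured q range")
    target = iaa_form_factor(comp, measured.q[sel], convention).values
    m = measured.values[sel]
    s = float(np.sum(target * m) / np.sum(m ** 2))
    return replace(measured, values=measured.values * s,
                   scale_note=f"renormalized to IAA ({convention}), s={s:.6g}",
                   source="measured")


def renormalize_to_reference(measured: FormFactorProfile,
                             reference: FormFactorProfile,
                             window: tuple[float, float]) -> FormFactorProfile:
    """Scale a measured curve to an absolute reference over a window."""
    lo, hi = window
    sel = (measured.q >= lo) & (measured.q <= hi)
    if not np.any(sel):
        raise ValueError("window outside the measured q range")
    target = reference.interp(measured.q[sel])
    m = measured.values[sel]
    s = float(np.sum(target * m) / np.sum(m ** 2))
    return replace(measured, values=measured.values * s,
                   scale_note=f"renormalized to {reference.source}, s={s:.6g}")


def splice_profiles(small_q: FormFactorProfile, wide_q: FormFactorProfile,
                    junction: float, band_frac: float = 0.1) -> FormFactorProfile:
    """Piecewise composite: small-q branch below the junction, wide-q at
    and above it, with the small-q branch rescaled by the mean ratio
    wide/small over a matching band around the junction."""
    lo, hi = junction * (1 - band_frac), junction * (1 + band_frac)
    band = (small_q.q >= lo) & (small_q.q <= hi)
    if (not np.any(band) or small_q.q[-1] < hi or wide_q.q[0] > lo):
        raise ValueError("no overlap band around the junction")
    ratio = wide_q.interp(small_q.q[band]) / small_q.values[band]
    scale = float(np.mean(ratio))
    ql = small_q.q[small_q.q < junction]
    vl = small_q.values[small_q.q < junction] * scale
    qr = wide_q.q[wide_q.q >= junction]
    vr = wide_q.values[wide_q.q >= junction]
    return FormFactorProfile(q=np.concatenate([ql, qr]),
                             values=np.concatenate([vl, vr]),
                             source=wide_q.source,
                             scale_note=f"spliced at {junction} nm⁻¹, "
                                        f"small-q scale {scale:.6g}")


# ---------------------------------------------------------------------------
# built materials
# ---------------------------------------------------------------------------

@dataclass
class Material:
    """A simulation material at a fixed build energy.

    ``coherent_table`` holds F²S per *atom* (electron-units², atom
    convention); ``mu_*`` are linear attenuation coefficients in cm⁻¹ at
    ``energy_keV``.  The coherent sampling table is the normalized inverse
    CDF of F²S(q)·(Thomson polarization factor)·q over the accessible q
    range at the build energy.
    """

    name: str
    composition: ElementalComposition
    density: float
    energy_keV: float
    coherent_table: FormFactorProfile
    mu_photoelectric: float
    mu_incoherent: float
    mu_coherent: float
    n_atoms_per_cm3: float
    sample_q: np.ndarray = field(repr=False, default=None)
    sample_cdf: np.ndarray = field(repr=False, default=None)

    @property
    def mu_total(self) -> float:
        return self.mu_photoelectric + self.mu_incoherent + self.mu_coherent

    @property
    def electrons_per_cm3(self) -> float:
        return self.density * self.composition.electrons_per_gram()

    def mu_photoelectric_at(self, energy_keV) -> np.ndarray:
        """τ scaled from the build energy with the E⁻³ law."""
        return self.mu_photoelectric * (self.energy_keV / np.asarray(energy_keV)) ** 3

    def mu_incoherent_at(self, energy_keV) -> np.ndarray:
        return (self.mu_incoherent * klein_nishina_total(energy_keV)
                / klein_nishina_total(self.energy_keV))

    def mu_total_at(self, energy_keV) -> np.ndarray:
        # coherent held at its build-energy value (slowly varying; it does
        # not deposit energy)
        return (self.mu_photoelectric_at(energy_keV)
                + self.mu_incoherent_at(energy_keV) + self.mu_coherent)

    def differential_sigma_coh(self, q) -> np.ndarray:
        """Macroscopic coherent dΣ/dΩ (cm⁻¹ sr⁻¹) at the build energy."""
        k = 2 * np.pi / wavelength_nm(self.energy_keV)
        cos2t = 1.0 - np.asarray(q, dtype=float) ** 2 / (2 * k ** 2)
        pol = thomson_polarization_factor(cos2t)
        return (self.n_atoms_per_cm3 * R_E_CM ** 2 * pol
                * self.coherent_table.interp(q))

    def sample_coherent_q(self, u) -> np.ndarray:
        """Inverse-CDF sample of the coherent momentum transfer (nm⁻¹)."""
        return np.interp(u, self.sample_cdf, self.sample_q)


def build_material(name: str, comp: ElementalComposition, density: float,
                   coherent_table: FormFactorProfile, energy_keV: float,
                   n_sampling: int = 4096) -> Material:
    """Assemble attenuation coefficients and sampling tables.

    The coherent table is extended beyond its tabulated range with the
    (atom-convention) IAA so that the full accessible q range at the build
    energy, q_max = 4π/λ, is covered.
    """
    if not (1.0 < energy_keV < 100.0):
        raise ValueError("energy outside the tabulated 1-100 keV range")
    if density <= 0:
        raise ValueError("density must be positive")
    lam = wavelength_nm(energy_keV)
    k = 2 * np.pi / lam
    q_max = 2 * k  # backscatter limit

    # extend the coherent table to q_max with the IAA tail
    q_tab, v_tab = coherent_table.q, coherent_table.values
    if q_tab[-1] < q_max:
        q_ext = np.geomspace(q_tab[-1] * 1.01, q_max, 256)
        v_ext = iaa_form_factor(comp, q_ext, convention="atom").values
        q_tab = np.concatenate([q_tab, q_ext])
        v_tab = np.concatenate([v_tab, v_ext])
    table = FormFactorProfile(q=q_tab, values=v_tab, source=coherent_table.source,
                              scale_note=coherent_table.scale_note
                              + " + IAA tail")

    n_atoms = density * N_AVOGADRO * comp.moles_per_gram()
    mu_pe = density * sum(
        w * atomic.photoelectric_mass_attenuation(s, energy_keV)
        for s, w in comp.fractions.items())
    mu_inc = density * sum(
        w * atomic.incoherent_mass_attenuation(s, energy_keV)
        for s, w in comp.fractions.items())

    # dσ/dq per atom ∝ P(θ) F²S(q) q  (dΩ = 2π q dq / k²)
    qs = np.linspace(0.0, q_max, n_sampling)
    cos2t = 1.0 - qs ** 2 / (2 * k ** 2)
    pdf = thomson_polarization_factor(cos2t) * table.interp(qs) * qs
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1])
                                           * np.diff(qs))])
    integral = cdf[-1]          # ∫ P F²S q dq
    mu_coh = n_atoms * R_E_CM ** 2 * 2 * np.pi * integral / k ** 2
    if integral > 0:
        cdf = cdf / integral
    else:                       # vanishing coherent table: degenerate CDF
        cdf = np.linspace(0.0, 1.0, len(cdf))
    # strictly increasing CDF for a well-defined inverse
    cdf = np.maximum.accumulate(cdf)
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    return Material(name=name, composition=comp, density=density,
                    energy_keV=energy_keV, coherent_table=table,
                    mu_photoelectric=float(mu_pe), mu_incoherent=float(mu_inc),
                    mu_coherent=float(mu_coh), n_atoms_per_cm3=float(n_atoms),
                    sample_q=qs[keep], sample_cdf=cdf[keep])
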