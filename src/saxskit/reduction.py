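"""pSAXS data reduction: frames → calibrated absolute 1D profiles.

The correction chain applied to every scan position (x, y), strictly in
order:

1. dark-current subtraction with a per-position constant offset,
   I′(q) = I(q) − D_c(q) − offset, the offset estimated as the mean of
   (I − D_c) over a signal-free q window (default 6.52–7.08 nm⁻¹);
2. transmission normalization I″ = I′/I′(0), using the q = 0 bin through
   the semi-transparent beamstop — the (unknown but position-independent)
   beamstop attenuation cancels between sample and standard;
3. holder/window background subtraction I‴ = I″ − ⟨I″⟩ over holder-only
   positions;
4. absolute scaling I⁗ = C_f · I‴, C_f fitted by least squares against the
   known absolute curve of a glassy-carbon secondary standard.

The q axis is optionally corrected with silver behenate (AgBe), whose
diffraction orders sit at q_n = 2πn/d (d = 5.838 nm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import InstrumentGeometry, compute_q_grid, radial_bin_index
from .profiles import GridError, ScatterProfile, UnitState

#: default signal-free offset window, nm⁻¹
DEFAULT_OFFSET_WINDOW = (6.52, 7.08)
#: standard literature AgBe layer spacing, nm
AGBE_D_SPACING_NM = 5.838


class ReductionError(ValueError):
    pass


@dataclass
class DetectorFrame:
    """A single 2D area-detector exposure (counts, not rates)."""

    counts: np.ndarray
    exposure_s: float
    order: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.exposure_s <= 0:
            raise ValueError("exposure must be positive")


@dataclass
class DarkCurrent:
    """End-of-scan dark-current profile plus the offset-estimation window."""

    profile: ScatterProfile
    offset_window: tuple[float, float] = DEFAULT_OFFSET_WINDOW

    def __post_init__(self):
        lo, hi = self.offset_window
        if lo < self.profile.q[0] or hi > self.profile.q[-1]:
            raise ValueError("offset window outside dark-current q range")


@dataclass
class CalibrationSet:
    """Reference standards: glassy carbon (absolute) and AgBe (q axis)."""

    glassy_carbon_measured: ScatterProfile | None = None
    glassy_carbon_reference: ScatterProfile | None = None
    agbe_measured: ScatterProfile | None = None
    agbe_reference_peaks: tuple[float, ...] = ()
    calibration_factor: float | None = None
    #: q range used for the C_f fit; the low edge keeps the
    #: beamstop/primary-contaminated first bins out of the fit
    fit_window: tuple[float, float] = (0.6, np.inf)

    @staticmethod
    def agbe_peaks(q_max: float, d_nm: float = AGBE_D_SPACING_NM) -> tuple[float, ...]:
        """AgBe reference peak positions q_n = 2πn/d up to q_max."""
        n_max = int(q_max * d_nm / (2 * np.pi))
        return tuple(2 * np.pi * n / d_nm for n in range(1, n_max + 1))


@dataclass
class PlanarScan:
    """Grid of profiles indexed by stage position.

    ``positions`` is an (N, 2) array of (x, y) stage coordinates in mm;
    ``background_flags`` marks holder-only positions.
    """

    positions: np.ndarray
    profiles: list[ScatterProfile]
    transmission: np.ndarray | None = None
    background_flags: np.ndarray = field(default=None)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.background_flags is None:
            self.background_flags = np.zeros(len(self.profiles), dtype=bool)
        self.background_flags = np.asarray(self.background_flags, dtype=bool)
        if len(self.profiles) != len(self.positions):
            raise ValueError("positions/profiles length mismatch")
        q0 = self.profiles[0].q
        for p in self.profiles[1:]:
            if not np.array_equal(p.q, q0):
                raise GridError("all scan profiles must share one q grid")

    @property
    def q(self) -> np.ndarray:
        return self.profiles[0].q

    def background_mean(self) -> ScatterProfile:
        """Mean profile over holder-only positions (I_BG)."""
        if not np.any(self.background_flags):
            raise ReductionError("no background positions flagged")
        sel = [p for p, f in zip(self.profiles, self.background_flags) if f]
        stack = np.stack([p.intensity for p in sel])
        ref = sel[0]
        return ScatterProfile(q=ref.q, intensity=stack.mean(axis=0),
                              sigma=stack.std(axis=0, ddof=0),
                              unit_state=ref.unit_state,
                              provenance=["background mean"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def radial_average(frame: DetectorFrame, geometry: InstrumentGeometry,
                   q_grid: np.ndarray) -> ScatterProfile:
    """Azimuthal average of a frame onto the radial q bins.

    Each bin holds the mean count *rate* (counts/exposure) of unmasked
    pixels falling in the half-open radial bin; sigma is the standard error
    of the bin mean.  Empty bins are flagged with NaN intensity and
    npix = 0.
    """
    if frame.counts.shape != geometry.binned_shape:
        raise ReductionError(
            f"frame shape {frame.counts.shape} != binned detector "
            f"shape {geometry.binned_shape}")
    cy, cx = geometry.center
    ny, nx = geometry.binned_shape
    if not (0 <= cy <= ny - 1 and 0 <= cx <= nx - 1):
        raise ReductionError("beam center outside the frame")
    n = len(q_grid)
    idx = radial_bin_index(geometry, n)
    rate = frame.counts / frame.exposure_s
    if geometry.beamstop_mask is not None:
        keep = ~geometry.beamstop_mask.ravel()
    else:
        keep = np.ones(rate.size, dtype=bool)
    if not np.any(keep):
        raise ReductionError("all pixels masked")
    flat_idx = idx.ravel()[keep]
    flat_rate = rate.ravel()[keep]
    npix = np.bincount(flat_idx, minlength=n)
    total = np.bincount(flat_idx, weights=flat_rate, minlength=n)
    total2 = np.bincount(flat_idx, weights=flat_rate ** 2, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / npix
        var = total2 / npix - mean ** 2
        sem = np.sqrt(np.clip(var, 0, None) / np.maximum(npix, 1))
    sem[npix == 0] = 0.0
    return ScatterProfile(q=q_grid, intensity=mean, sigma=sem,
                          unit_state=UnitState.raw_rate,
                          provenance=["radial average"], npix=npix)


def subtract_dark(profile: ScatterProfile, dark: DarkCurrent,
                  estimate_offset: bool = True) -> ScatterProfile:
    """Eq-1 correction: I′ = I − D_c − offset, offset = ⟨I − D_c⟩ window.

    ``estimate_offset=False`` skips the per-position offset (offset = 0);
    used for reference standards such as glassy carbon whose scatter does
    not vanish in the tissue chain's signal-free window.
    """
    profile.require_state(UnitState.raw_rate)
    profile.same_grid(dark.profile)
    corrected = profile.intensity - dark.profile.intensity
    if estimate_offset:
        win = profile.window_slice(dark.offset_window)
        offset = float(np.nanmean(corrected[win]))
    else:
        offset = 0.0
    sigma = np.hypot(profile.sigma, dark.profile.sigma)
    return profile.evolve(step=f"dark subtracted (offset={offset:.6g})",
                          new_state=UnitState.dark_corrected,
                          intensity=corrected - offset, sigma=sigma)


def transmission_normalize(profile: ScatterProfile) -> ScatterProfile:
    """Eq-2 correction: I″ = I′/I′(0), the q = 0 (primary) bin intensity."""
    profile.require_state(UnitState.dark_corrected)
    i0 = int(np.argmin(np.abs(profile.q)))
    t = float(profile.intensity[i0])
    if not np.isfinite(t) or t <= 0:
        raise ReductionError(f"degenerate transmission value {t}")
    return profile.evolve(step=f"transmission normalized (I0={t:.6g})",
                          new_state=UnitState.transmission_normalized,
                          intensity=profile.intensity / t,
                          sigma=profile.sigma / t)


def subtract_background(profile: ScatterProfile, scan: PlanarScan) -> ScatterProfile:
    """Eq-3 correction: I‴ = I″ − I″_BG (mean over holder-only positions)."""
    profile.require_state(UnitState.transmission_normalized)
    bg = scan.background_mean()
    profile.same_grid(bg)
    return profile.evolve(step="background subtracted",
                          new_state=UnitState.background_subtracted,
                          intensity=profile.intensity - bg.intensity,
                          sigma=np.hypot(profile.sigma, bg.sigma))


def fit_calibration_factor(cal: CalibrationSet) -> float:
    """Least-squares C_f such that C_f·measured ≈ reference (glassy carbon)."""
    meas, ref = cal.glassy_carbon_measured, cal.glassy_carbon_reference
    if meas is None or ref is None:
        raise ReductionError("calibration set lacks glassy-carbon curves")
    lo = max(meas.q[0], ref.q[0], cal.fit_window[0])
    hi = min(meas.q[-1], ref.q[-1], cal.fit_window[1])
    if hi <= lo:
        raise ReductionError("glassy-carbon measured/reference q ranges disjoint")
    sel = (meas.q >= lo) & (meas.q <= hi)
    r = np.interp(meas.q[sel], ref.q, ref.intensity)
    m = meas.intensity[sel]
    ok = np.isfinite(m) & np.isfinite(r)
    cf = float(np.sum(r[ok] * m[ok]) / np.sum(m[ok] ** 2))
    if cf <= 0:
        raise ReductionError("fitted calibration factor is non-positive")
    cal.calibration_factor = cf
    return cf


def absolute_calibrate(profile: ScatterProfile, cal: CalibrationSet) -> ScatterProfile:
    """Eq-4 correction: I⁗ = C_f · I‴ in absolute cm⁻¹ sr⁻¹."""
    profile.require_state(UnitState.background_subtracted)
    cf = cal.calibration_factor
    if cf is None:
        cf = fit_calibration_factor(cal)
    return profile.evolve(step=f"absolute calibration (Cf={cf:.6g})",
                          new_state=UnitState.absolute,
                          intensity=profile.intensity * cf,
                          sigma=profile.sigma * cf)


def fit_q_calibration(cal: CalibrationSet, min_prominence: float | None = None,
                      q_min: float = 0.6) -> tuple[float, float]:
    """Affine q map (a, b) matching detected AgBe peaks to reference ones.

    Peaks are searched above ``q_min`` so the beamstop-attenuated primary
    spike near q = 0 cannot masquerade as a diffraction ring.  With a
    single detectable peak the map is scale-only (b = 0).
    """
    from .mapping import detect_peaks  # local import to avoid a cycle

    if cal.agbe_measured is None or not cal.agbe_reference_peaks:
        raise ReductionError("AgBe measurement or reference peak list missing")
    full = cal.agbe_measured
    sel = full.q >= q_min
    if sel.sum() < 5:
        raise ReductionError("AgBe measurement too short above q_min")
    meas = ScatterProfile(q=full.q[sel], intensity=full.intensity[sel],
                          sigma=full.sigma[sel], unit_state=full.unit_state,
                          provenance=list(full.provenance))
    if min_prominence is None:
        finite = meas.intensity[np.isfinite(meas.intensity)]
        min_prominence = 0.05 * (finite.max() - finite.min())
    table = detect_peaks(meas, min_prominence=min_prominence)
    if len(table) == 0:
        raise ReductionError("no detectable peak in the AgBe measurement")
    detected = np.asarray(table["q_nm_inv"])
    ref = np.asarray(cal.agbe_reference_peaks, dtype=float)
    # pair each detected peak with the nearest reference order
    pairs = [(d, ref[np.argmin(np.abs(ref - d))]) for d in detected]
    d = np.array([p[0] for p in pairs])
    r = np.array([p[1] for p in pairs])
    if len(d) == 1:
        a = float(r[0] / d[0])
        return a, 0.0
    A = np.vstack([d, np.ones_like(d)]).T
    (a, b), *_ = np.linalg.lstsq(A, r, rcond=None)
    return float(a), float(b)


def calibrate_q(profile: ScatterProfile, cal: CalibrationSet) -> ScatterProfile:
    """Apply the AgBe affine q correction to a profile's grid."""
    a, b = fit_q_calibration(cal)
    q_new = a * profile.q + b
    if np.isclose(profile.q[0], 0.0):
        q_new = q_new - q_new[0]  # keep the primary bin at q = 0
    out = ScatterProfile(q=q_new, intensity=profile.intensity.copy(),
                         sigma=profile.sigma.copy(), unit_state=profile.unit_state,
                         provenance=list(profile.provenance)
                         + [f"q calibrated (a={a:.6g}, b={b:.6g})"],
                         npix=profile.npix)
    return out


def refine_beam_center(frame: DetectorFrame, geometry: InstrumentGeometry,
                       half_width: int = 8) -> tuple[float, float]:
    """Center of mass of the attenuated primary near the nominal center."""
    cy, cx = geometry.center
    iy, ix = int(round(cy)), int(round(cx))
    ny, nx = frame.counts.shape
    y0, y1 = max(0, iy - half_width), min(ny, iy + half_width + 1)
    x0, x1 = max(0, ix - half_width), min(nx, ix + half_width + 1)
    patch = frame.counts[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    w = patch.sum()
    if w <= 0:
        return cy, cx
    return float((yy * patch).sum() / w), float((xx * patch).sum() / w)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def reduce_scan(container, geometry: InstrumentGeometry, n_radial_bins: int = 256,
                offset_window: tuple[float, float] = DEFAULT_OFFSET_WINDOW,
                apply_q_calibration: bool = True) -> PlanarScan:
    """Run the full chain on a scan container (see :mod:`saxskit.scanio`).

    Returns a :class:`PlanarScan` of absolute profiles (cm⁻¹ sr⁻¹).
    """
    q_grid = compute_q_grid(geometry, n_radial_bins)
    dark_profile = radial_average(container.dark_frame, geometry, q_grid)
    dark = DarkCurrent(profile=dark_profile, offset_window=offset_window)

    def chain_to_tn(frame, estimate_offset=True):
        p = radial_average(frame, geometry, q_grid)
        p = subtract_dark(p, dark, estimate_offset=estimate_offset)
        return transmission_normalize(p)

    profiles_tn = [chain_to_tn(f) for f in container.frames]
    scan_tn = PlanarScan(positions=container.positions, profiles=profiles_tn,
                         background_flags=container.background_flags)

    cal = CalibrationSet(
        glassy_carbon_measured=chain_to_tn(container.glassy_carbon_frame,
                                           estimate_offset=False),
        glassy_carbon_reference=container.glassy_carbon_reference,
        agbe_measured=chain_to_tn(container.agbe_frame, estimate_offset=False)
        if container.agbe_frame is not None else None,
        agbe_reference_peaks=CalibrationSet.agbe_peaks(q_grid[-1]),
    )
    fit_calibration_factor(cal)

    out = []
    for p in profiles_tn:
        p = subtract_background(p, scan_tn)
        p = absolute_calibrate(p, cal)
        if apply_q_calibration and cal.agbe_measured is not None:
            p = calibrate_q(p, cal)
        out.append(p)
    transmission = np.array([
        float(p.provenance[-1].split("I0=")[1].rstrip(")"))
        if "I0=" in p.provenance[-1] else np.nan
        for p in profiles_tn
    ]) if profiles_tn else None
    return PlanarScan(positions=container.positions, profiles=out,
                      transmission=transmission,
                      background_flags=container.background_flags)
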