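"""The four-step correction chain and the q/absolute calibrations."""

import numpy as np
import pytest

from saxskit.geometry import InstrumentGeometry, compute_q_grid
from saxskit.profiles import ScatterProfile, UnitState
from saxskit.reduction import (CalibrationSet, DarkCurrent, DetectorFrame,
                               ReductionError, absolute_calibrate,
                               calibrate_q, fit_calibration_factor,
                               fit_q_calibration, radial_average,
                               subtract_background, subtract_dark,
                               transmission_normalize, PlanarScan)

GEOM = InstrumentGeometry(energy_keV=8.05, distance_mm=70.0,
                          detector_shape=(512, 512), binning=8)
QG = compute_q_grid(GEOM, 64)


def profile(intensity, state=UnitState.raw_rate, q=None):
    q = QG if q is None else q
    return ScatterProfile(q=q, intensity=np.broadcast_to(
        np.asarray(intensity, dtype=float), q.shape).copy(), unit_state=state)


# ---------------------------------------------------------------- radial
def test_radial_average_of_uniform_frame_is_flat():
    frame = DetectorFrame(np.full(GEOM.binned_shape, 42.0), exposure_s=2.0)
    p = radial_average(frame, GEOM, QG)
    assert np.allclose(p.intensity[p.npix > 0], 21.0)
    assert p.unit_state == UnitState.raw_rate


def test_radial_average_locates_a_planted_ring():
    r_star = 3.0  # mm
    rr = GEOM.pixel_radii_mm()
    frame = DetectorFrame(np.where(np.abs(rr - r_star) < 0.1, 1000.0, 1.0),
                          exposure_s=1.0)
    p = radial_average(frame, GEOM, QG)
    q_star = GEOM.q_of_radius(r_star)
    j = np.nanargmax(p.intensity)
    dq = np.diff(QG).max()
    assert abs(p.q[j] - q_star) <= dq


def test_beamstop_mask_conserves_pixel_count():
    rr = GEOM.pixel_radii_mm()
    mask = rr < 0.5
    geom = InstrumentGeometry(energy_keV=8.05, distance_mm=70.0,
                              detector_shape=(512, 512), binning=8,
                              beamstop_mask=mask)
    frame = DetectorFrame(np.ones(geom.binned_shape), exposure_s=1.0)
    p = radial_average(frame, geom, QG)
    assert p.npix.sum() == mask.size - mask.sum()


def test_radial_average_rejects_all_masked():
    geom = InstrumentGeometry(energy_keV=8.05, distance_mm=70.0,
                              detector_shape=(512, 512), binning=8,
                              beamstop_mask=np.ones((64, 64), dtype=bool))
    frame = DetectorFrame(np.ones((64, 64)), exposure_s=1.0)
    with pytest.raises(ReductionError):
        radial_average(frame, geom, QG)


# ------------------------------------------------------------------ dark
def test_dark_subtraction_of_identical_profile_gives_zero():
    base = profile(np.exp(-QG))
    dark = DarkCurrent(profile(np.exp(-QG)), offset_window=(3.0, 5.0))
    out = subtract_dark(base, dark)
    assert np.allclose(out.intensity, 0.0, atol=1e-14)
    assert out.unit_state == UnitState.dark_corrected


def test_planted_constant_offset_is_recovered():
    dark_vals = 5.0 + 40.0 * np.exp(-QG / 2)
    dark = DarkCurrent(profile(dark_vals), offset_window=(3.0, 5.0))
    planted = profile(dark_vals + 0.37)   # signal-free everywhere
    out = subtract_dark(planted, dark)
    assert np.allclose(out.intensity, 0.0, atol=1e-12)
    assert "offset=0.37" in out.provenance[-1]


def test_offset_is_the_window_mean_of_31_points():
    # a window holding exactly 31 grid points: the offset is the plain
    # mean of the 31 dark-corrected values there
    q = np.linspace(6.52, 7.08, 31)
    q = np.concatenate([np.linspace(0.0, 6.0, 20), q])
    rng = np.random.default_rng(0)
    vals = rng.normal(10.0, 1.0, q.size)
    base = ScatterProfile(q=q, intensity=vals)
    dark = DarkCurrent(ScatterProfile(q=q, intensity=np.zeros_like(q)),
                       offset_window=(6.52, 7.08))
    out = subtract_dark(base, dark)
    window_mean = vals[20:].mean()
    assert np.allclose(vals - window_mean, out.intensity)
    # corrected profile averages to zero over the window (chain invariant)
    assert abs(out.intensity[20:].mean()) < 1e-9 * np.abs(out.intensity).max()


# -------------------------------------------------------------- transmission
def test_transmission_normalization_fixes_q0_to_one_and_is_scale_free():
    base = profile(np.exp(-QG) + 1.0, UnitState.dark_corrected)
    out = transmission_normalize(base)
    assert out.intensity[0] == pytest.approx(1.0)
    scaled = profile(7.7 * (np.exp(-QG) + 1.0), UnitState.dark_corrected)
    assert np.allclose(transmission_normalize(scaled).intensity,
                       out.intensity)


def test_degenerate_transmission_is_an_error():
    bad = profile(np.concatenate([[0.0], np.ones(QG.size - 1)]),
                  UnitState.dark_corrected)
    with pytest.raises(ReductionError):
        transmission_normalize(bad)


# -------------------------------------------------------------- background
def make_scan(profiles, flags):
    pos = np.column_stack([np.arange(len(profiles), dtype=float),
                           np.zeros(len(profiles))])
    return PlanarScan(positions=pos, profiles=profiles,
                      background_flags=np.asarray(flags))


def test_background_mean_and_subtraction():
    b = np.exp(-QG)
    eps = 0.1 * np.ones_like(QG)
    scan = make_scan([profile(b, UnitState.transmission_normalized),
                      profile(b + eps, UnitState.transmission_normalized),
                      profile(b + 3.0, UnitState.transmission_normalized)],
                     [True, True, False])
    bg = scan.background_mean()
    assert np.allclose(bg.intensity, b + eps / 2)
    out = subtract_background(scan.profiles[2], scan)
    assert np.allclose(out.intensity, 3.0 - eps / 2)
    # a profile equal to the background mean reduces to zero
    equal = profile(b + eps / 2, UnitState.transmission_normalized)
    assert np.allclose(subtract_background(equal, scan).intensity, 0.0)


def test_background_requires_flagged_positions():
    scan = make_scan([profile(1.0, UnitState.transmission_normalized)],
                     [False])
    with pytest.raises(ReductionError):
        subtract_background(scan.profiles[0], scan)


# ---------------------------------------------------------------- absolute
def test_calibration_factor_exact_ratio_cases():
    ref = profile(np.exp(-QG) + 1.0, UnitState.absolute)
    same = profile(np.exp(-QG) + 1.0, UnitState.background_subtracted)
    cal = CalibrationSet(glassy_carbon_measured=same,
                         glassy_carbon_reference=ref, fit_window=(0.0, np.inf))
    assert fit_calibration_factor(cal) == pytest.approx(1.0)
    out = absolute_calibrate(same, cal)
    assert np.allclose(out.intensity, same.intensity)
    assert out.unit_state == UnitState.absolute

    fifth = profile((np.exp(-QG) + 1.0) / 5.0,
                    UnitState.background_subtracted)
    cal5 = CalibrationSet(glassy_carbon_measured=fifth,
                          glassy_carbon_reference=ref,
                          fit_window=(0.0, np.inf))
    assert fit_calibration_factor(cal5) == pytest.approx(5.0)


def test_disjoint_q_ranges_are_a_calibration_error():
    ref = ScatterProfile(q=np.linspace(20, 30, 10), intensity=np.ones(10),
                         unit_state=UnitState.absolute)
    meas = profile(1.0, UnitState.background_subtracted)
    cal = CalibrationSet(glassy_carbon_measured=meas,
                         glassy_carbon_reference=ref)
    with pytest.raises(ReductionError):
        fit_calibration_factor(cal)


# ---------------------------------------------------------------- q axis
def agbe_profile(scale=1.0, d_nm=5.838):
    q = np.linspace(0.0, 8.0, 400)
    vals = np.zeros_like(q)
    for n in (1, 2, 3, 4):
        q_n = 2 * np.pi * n / d_nm
        vals += (10.0 / n) * np.exp(-0.5 * ((q - q_n * scale) / 0.05) ** 2)
    return ScatterProfile(q=q, intensity=vals,
                          unit_state=UnitState.transmission_normalized)


def test_reference_peaks_follow_the_d_spacing():
    peaks = CalibrationSet.agbe_peaks(8.0)
    assert peaks[0] == pytest.approx(2 * np.pi / 5.838)
    assert len(peaks) == int(8.0 * 5.838 / (2 * np.pi))


def test_q_calibration_identity_and_planted_scale():
    cal = CalibrationSet(agbe_measured=agbe_profile(),
                         agbe_reference_peaks=CalibrationSet.agbe_peaks(8.0))
    a, b = fit_q_calibration(cal)
    assert a == pytest.approx(1.0, abs=0.01)
    assert b == pytest.approx(0.0, abs=0.02)

    # rings displaced by a hidden 1.02 scale: the affine fit undoes it
    cal2 = CalibrationSet(agbe_measured=agbe_profile(scale=1.02),
                          agbe_reference_peaks=CalibrationSet.agbe_peaks(8.0))
    a2, b2 = fit_q_calibration(cal2)
    dq = 8.0 / 399
    assert abs(a2 * 1.02 - 1.0) * 2 * np.pi / 5.838 < dq + abs(b2)


def test_q_calibration_needs_a_detectable_peak():
    flat = ScatterProfile(q=np.linspace(0, 8, 100),
                          intensity=np.ones(100),
                          unit_state=UnitState.transmission_normalized)
    cal = CalibrationSet(agbe_measured=flat,
                         agbe_reference_peaks=(1.076,))
    with pytest.raises(ReductionError):
        fit_q_calibration(cal, min_prominence=0.5)


def test_calibrate_q_applies_the_affine_map():
    base = profile(np.exp(-QG), UnitState.absolute)
    cal = CalibrationSet(agbe_measured=agbe_profile(scale=0.98),
                         agbe_reference_peaks=CalibrationSet.agbe_peaks(8.0))
    out = calibrate_q(base, cal)
    assert out.q[0] == pytest.approx(0.0)
    assert np.all(np.diff(out.q) > 0)
    # the map stretches the grid by ≈ 1/0.98
    assert out.q[-1] / base.q[-1] == pytest.approx(1 / 0.98, rel=0.01)
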