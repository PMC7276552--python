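import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coloptics.goniometry import (
    SpecularFit,
    detect_diffraction_peaks,
    extract_and_correct_streak,
    fit_grating,
    fit_specular,
    grating_angle,
    specular_shift,
    streak_overlay_rms,
)
from coloptics.synthdata import ColonyModel, TiltDistribution, synth_goniometer_map, synth_specular_trace
from coloptics.types import AngleResolvedMap, SpecularTrace


@pytest.mark.parametrize(
    "m, lam, d, theta_i, expected",
    [
        (0, 500.0, 395.0, -45.0, 45.0),
        (1, 336.0, 395.0, 0.0, np.degrees(np.arcsin(336 / 395))),
        (-1, 500.0, 395.0, -60.0, np.degrees(np.arcsin(-500 / 395 + np.sin(np.radians(60))))),
    ],
)
def test_grating_angle_values(m, lam, d, theta_i, expected):
    assert grating_angle(m, lam, d, theta_i) == pytest.approx(expected, abs=1e-9)


def test_grating_angle_evanescent_returns_none():
    assert grating_angle(1, 450.0, 395.0, 0.0) is None


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    m=st.sampled_from([-2, -1, 1, 2]),
    lam=st.floats(250, 700),
    d=st.floats(300, 500),
    theta_i=st.floats(-80, 80),
)
def test_grating_reciprocity(m, lam, d, theta_i):
    """If order m sends theta_i to theta_m, order -m sends -theta_m back to -theta_i."""
    theta_m = grating_angle(m, lam, d, theta_i)
    if theta_m is None:
        return
    back = grating_angle(-m, lam, d, -theta_m)
    assert back is not None
    assert back == pytest.approx(-theta_i, abs=1e-6)


def test_specular_shift_normal_incidence_and_values():
    assert specular_shift(480.0, 1.4, 0.0) == 480.0
    assert specular_shift(480.0, 1.4, 45.0) == pytest.approx(
        480 * np.cos(np.arcsin(np.sin(np.radians(45)) / 1.4)), rel=1e-12
    )
    assert specular_shift(480.0, 1.4, 45.0) == pytest.approx(414.3, abs=0.05)
    assert specular_shift(480.0, 1.4, 60.0) == pytest.approx(377.14, abs=0.05)


def test_specular_shift_strictly_decreasing_in_angle():
    th = np.arange(0.0, 80.0, 1.0)
    lam = specular_shift(480.0, 1.4, th)
    assert np.all(np.diff(lam) < 0)


def test_detect_peaks_noiseless_map_matches_grating_equation(day2_delta_maps):
    """Zero-tilt spots sit on the grating-equation loci to sub-grid accuracy."""
    found_any = False
    for amap in day2_delta_maps:
        for th, lam, _ in detect_diffraction_peaks(amap):
            d_closed = [
                m * lam / (np.sin(np.radians(th)) + np.sin(np.radians(amap.theta_in)))
                for m in (-2, -1, 1, 2)
            ]
            assert min(abs(d - 395.0) for d in d_closed) < 0.6
            found_any = True
    assert found_any


def test_detect_peaks_pure_noise_map_empty():
    rng = np.random.default_rng(0)
    amap = AngleResolvedMap(
        0.0,
        np.arange(-90.0, 90.5, 1.0),
        np.arange(300.0, 701.0, 4.0),
        rng.random((181, 101)),
    )
    with pytest.warns(UserWarning):
        assert detect_diffraction_peaks(amap) == []


def test_fit_grating_single_point_closed_form():
    th = float(np.degrees(np.arcsin(336.0 / 395.0)))
    inten = np.zeros((181, 201))
    thetas = np.arange(-90.0, 90.5, 1.0)
    lams = np.arange(300.0, 700.5, 2.0)
    i = np.argmin(np.abs(thetas - th))
    j = np.argmin(np.abs(lams - 336.0))
    # render an exact Gaussian spot so the log-parabola refinement is exact
    tt, ll = np.meshgrid(thetas, lams, indexing="ij")
    inten = np.exp(-0.5 * ((tt - th) / 1.5) ** 2 - 0.5 * ((ll - 336.0) / 5.0) ** 2)
    amap = AngleResolvedMap(0.0, thetas, lams, inten)
    fit = fit_grating([amap])
    assert fit.d_hat == pytest.approx(395.0, abs=1e-6)


def test_fit_grating_noiseless_maps_exact(day2_delta_maps):
    fit = fit_grating(day2_delta_maps)
    assert fit.d_hat == pytest.approx(395.0, abs=1e-3)
    assert fit.residual_rms < 1e-6


def test_fit_grating_day1_noiseless_exact():
    model = ColonyModel(d=425.0, tilt=TiltDistribution(0, 0, 0))
    maps = [synth_goniometer_map(model, t) for t in (0.0, -45.0, -60.0)]
    assert fit_grating(maps).d_hat == pytest.approx(425.0, abs=1e-3)


def test_fit_specular_noiseless_recovers_index():
    trace = synth_specular_trace(ColonyModel(d=395.0, lambda_p=480.0), n_avg=1.4)
    fit = fit_specular(trace)
    assert fit.lambda_p_hat == pytest.approx(480.0, abs=0.01)
    assert fit.n_avg_hat == pytest.approx(1.4, abs=1e-3)


def test_fit_specular_flat_trace_sets_lower_bound_flag():
    th = np.arange(-45.0, 46.0, 1.0)
    trace = SpecularTrace(theta_in=th, lambda_s=np.full_like(th, 480.0))
    fit = fit_specular(trace)
    assert fit.lower_bound_flag
    assert np.isinf(fit.n_avg_hat)


def test_fit_specular_requires_normal_incidence_coverage():
    th = np.arange(10.0, 46.0, 1.0)
    trace = SpecularTrace(th, specular_shift(480.0, 1.4, th))
    with pytest.raises(ValueError):
        fit_specular(trace)


def test_streak_delta_tilt_degenerates_to_spot(day2_delta_maps):
    """Without tilts there is no streak: the extraction window holds at most
    the flat-domain spot, so ridge points cluster at the spot wavelength."""
    tr = extract_and_correct_streak(day2_delta_maps[0])
    if tr.corrected_ridge.size:
        lam = tr.corrected_ridge[:, 1]
        assert lam.std() < 6.0


def test_streak_correction_overlays(day2_tilt_maps):
    traces = [extract_and_correct_streak(m) for m in day2_tilt_maps]
    assert streak_overlay_rms(traces) < 2.0


def test_streak_flipped_sign_fails_to_overlay(day2_tilt_maps):
    bad = [extract_and_correct_streak(m, correction_sign=-1.0) for m in day2_tilt_maps]
    with pytest.warns(UserWarning):
        assert streak_overlay_rms(bad) > 2.0
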