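import numpy as np
import pytest

from coloptics.tmm import (
    MultilayerStack,
    stack_from_lattice,
    tilted_stack_response,
    tmm_reflectance,
)

WL = np.arange(300.0, 700.0 + 1e-9, 2.0)


def test_fresnel_single_interface_closed_form():
    st = MultilayerStack([(1.34, 10.0)], ambient_index=1.0, substrate_index=1.34)
    sp = tmm_reflectance(st, 0.0, "TM", np.array([500.0]))
    assert sp.R[0] == pytest.approx((0.34 / 2.34) ** 2, abs=1e-12)


def test_index_matched_stack_reflects_nothing():
    st = MultilayerStack([(1.34, 123.0)] * 5, ambient_index=1.34, substrate_index=1.34)
    sp = tmm_reflectance(st, 25.0, "TE", WL)
    assert sp.R.max() < 1e-25


def test_energy_conservation_machine_precision():
    st = stack_from_lattice(395.0, 395.0, repetitions=41,
                            ambient_index=1.34, substrate_index=1.34)
    for pol in ("TE", "TM"):
        for th in (0.0, 30.0, 60.0):
            sp = tmm_reflectance(st, th, pol, WL)
            assert np.abs(sp.R + sp.T - 1).max() < 1e-10


def test_te_tm_coincide_at_normal_incidence():
    st = stack_from_lattice(395.0, 395.0, repetitions=11,
                            ambient_index=1.0, substrate_index=1.34)
    r_te = tmm_reflectance(st, 0.0, "TE", WL).R
    r_tm = tmm_reflectance(st, 0.0, "TM", WL).R
    assert np.abs(r_te - r_tm).max() < 1e-12


def test_stack_from_lattice_period_and_mean_index():
    st = stack_from_lattice(395.0, 395.0, direction="GK", n_layers_per_period=8)
    assert st.period_nm == pytest.approx(395.0 * np.sqrt(3) / 2, rel=1e-9)
    # area-weighted composite of touching disks: n^2 = f 1.38^2 + (1-f) 1.34^2
    f = np.pi / (2 * np.sqrt(3))
    n_bar = np.sqrt(f * 1.38**2 + (1 - f) * 1.34**2)
    assert st.mean_index == pytest.approx(n_bar, abs=2e-3)
    gm = stack_from_lattice(395.0, 395.0, direction="GM")
    assert gm.period_nm == pytest.approx(395.0 / 2, rel=1e-9)


def test_stack_empty_lattice_is_homogeneous():
    st = stack_from_lattice(395.0, 0.0, repetitions=3,
                            ambient_index=1.34, substrate_index=1.34)
    assert all(n == pytest.approx(1.34) for n, _ in st.layers)
    assert tmm_reflectance(st, 0.0, "TM", WL).R.max() < 1e-25


def test_bragg_peaks_of_41_period_stack():
    """Normal-incidence maxima sit at the m=2 and m=3 Bragg wavelengths
    2 n L / m of the effective stack, near 471 and 314 nm."""
    st = stack_from_lattice(395.0, 395.0, repetitions=41,
                            ambient_index=1.34, substrate_index=1.34)
    wl = np.arange(280.0, 700.0, 0.5)
    sp = tmm_reflectance(st, 0.0, "TM", wl)
    bragg = 2 * st.mean_index * st.period_nm
    for m in (2, 3):
        lam_b = bragg / m
        sel = np.abs(wl - lam_b) < 25
        peak = wl[sel][np.argmax(sp.R[sel])]
        assert abs(peak - lam_b) < 6.0  # within the peak FWHM


def test_peak_scales_linearly_with_index():
    base = stack_from_lattice(395.0, 395.0, repetitions=41,
                              ambient_index=1.34, substrate_index=1.34)
    wl = np.arange(380.0, 560.0, 0.25)

    def peak(stack):
        return wl[np.argmax(tmm_reflectance(stack, 0.0, "TM", wl).R)]

    p0 = peak(base)
    scaled = MultilayerStack([(n * 1.05, t) for n, t in base.layers],
                             ambient_index=1.34 * 1.05, substrate_index=1.34 * 1.05,
                             repetitions=41)
    assert peak(scaled) / p0 == pytest.approx(1.05, abs=0.005)


def test_tilted_stack_mirror_symmetry_and_identity():
    st = stack_from_lattice(395.0, 395.0, direction="GM", repetitions=21,
                            ambient_index=1.34, substrate_index=1.34)
    sp0 = tilted_stack_response(st, 0.0, np.array([10.0]), "TM", WL)[0]
    ref = tmm_reflectance(st, 10.0, "TM", WL)
    np.testing.assert_allclose(sp0.R, ref.R, atol=1e-14)
    plus = tilted_stack_response(st, 30.0, np.array([0.0]), "TM", WL)[0]
    minus = tilted_stack_response(st, -30.0, np.array([0.0]), "TM", WL)[0]
    np.testing.assert_allclose(plus.R, minus.R, atol=1e-12)
    grazing = tilted_stack_response(st, 30.0, np.array([-65.0]), "TM", WL)
    assert grazing[0] is None


def test_angle_sweep_follows_cosine_dispersion():
    """The specular Bragg ridge blue-shifts as lambda_p cos(arcsin(sin th/n))."""
    from coloptics.goniometry import specular_shift

    # measured from air, as in the goniometer: ambient index 1
    st = stack_from_lattice(395.0, 395.0, repetitions=41,
                            ambient_index=1.0, substrate_index=1.34)
    wl = np.arange(340.0, 520.0, 0.25)
    lam_p = wl[np.argmax(tmm_reflectance(st, 0.0, "TM", wl).R)]
    for th in (20.0, 35.0, 45.0):
        sp = tmm_reflectance(st, th, "TM", wl)
        expected = specular_shift(lam_p, st.mean_index, th)
        sel = np.abs(wl - expected) < 40
        ridge = wl[sel][np.argmax(sp.R[sel])]
        assert ridge == pytest.approx(expected, abs=2.0)
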