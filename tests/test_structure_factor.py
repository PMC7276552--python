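import numpy as np
import pytest

from coloptics.structure import LatticeSpec, first_shell_q, make_hexagonal
from coloptics.structure_factor import (
    NoLatticeError,
    autocorr_lattice,
    lineprofile_spacing,
    sq_image,
    sq_points,
)
from coloptics.synthdata import synth_em_image
from coloptics.types import ParticleEnsemble


@pytest.fixture(scope="module")
def perfect_lattice():
    return make_hexagonal(
        LatticeSpec(d=395.0, a=375.0, box=(5000.0, 5000.0), ff=0.6, periodic_y=False)
    )


def test_sq_points_first_shell_six_peaks(perfect_lattice):
    q1 = first_shell_q(395.0)
    sf = sq_points(perfect_lattice, q_max=1.3 * q1, n_grid=220)
    qxx, qyy = np.meshgrid(sf.qx, sf.qy)
    qr = np.hypot(qxx, qyy)
    shell = np.abs(qr - q1) < 0.12 * q1
    s = np.where(shell, sf.S, 0.0)
    # peak azimuths: six maxima 60 degrees apart
    phi, prof = sf.azimuthal_profile(q1)
    prof = np.nan_to_num(prof)
    peaks = prof > 0.5 * prof.max()
    angles = np.degrees(phi[peaks])
    assert s.max() > 10 * np.median(sf.S[sf.S > 0])
    folded = np.sort(np.unique(np.round(angles / 60.0)))
    assert len(np.unique(np.round((angles % 60) / 60))) >= 1
    assert sf.first_shell_radius(395.0) == pytest.approx(q1, abs=2 * (sf.qx[1] - sf.qx[0]))


def test_sq_points_poisson_ideal_gas_limit():
    rng = np.random.default_rng(1)
    n = 500
    pts = rng.uniform(0, 6000, (n, 2))
    ens = ParticleEnsemble(pts, radius=0.5, box=(6000.0, 6000.0))
    sf = sq_points(ens, q_max=0.02, n_grid=120)
    qxx, qyy = np.meshgrid(sf.qx, sf.qy)
    away = np.hypot(qxx, qyy) > 0.004
    assert abs(sf.S[away].mean() - 1.0) < 3 / np.sqrt(n)


def test_sq_direct_vs_gridded_fft_estimators_agree(perfect_lattice):
    """Independent estimator: bin the points onto a grid and take the FFT
    power spectrum; its first-shell radius must match the direct sum."""
    q1 = first_shell_q(395.0)
    sf_direct = sq_points(perfect_lattice, q_max=1.3 * q1, n_grid=200)
    # gridded indicator
    pix = 20.0
    nbin = int(5000 / pix)
    img, _, _ = np.histogram2d(
        perfect_lattice.positions[:, 0], perfect_lattice.positions[:, 1],
        bins=nbin, range=[[0, 5000], [0, 5000]],
    )
    sf_fft = sq_image(img, pix, binarize=False)
    r_direct = sf_direct.first_shell_radius(395.0)
    r_fft = sf_fft.first_shell_radius(395.0)
    assert r_fft == pytest.approx(r_direct, rel=0.02)


def test_sq_image_constant_is_zero_off_centre():
    sf = sq_image(np.ones((64, 64)), 4.0, binarize=False)
    assert np.abs(sf.S).max() < 1e-18


def test_sq_image_jittered_peaks_reduced_but_present():
    img0, _, _ = synth_em_image(d=395.0, pixel_nm=4.0, jitter_nm=0.0, seed=0)
    imgj, _, _ = synth_em_image(d=395.0, pixel_nm=4.0, jitter_nm=20.0, seed=0)
    q1 = first_shell_q(395.0)

    def shell_peak(img):
        with pytest.warns(UserWarning):
            sf = sq_image(img, 4.0)
        qxx, qyy = np.meshgrid(sf.qx, sf.qy)
        qr = np.hypot(qxx, qyy)
        return sf.S[np.abs(qr - q1) < 0.15 * q1].max()

    p0, pj = shell_peak(img0), shell_peak(imgj)
    assert pj < p0
    assert pj > 0.2 * p0


def test_autocorr_white_noise_raises():
    rng = np.random.default_rng(0)
    with pytest.raises(NoLatticeError):
        autocorr_lattice(rng.random((256, 256)), 4.0)


def test_autocorr_anisotropic_scaling_flagged():
    from scipy.ndimage import zoom

    img, _, _ = synth_em_image(d=395.0, pixel_nm=4.0, jitter_nm=0.0, seed=0)
    stretched = zoom(img, (1.0, 1.1), order=1)
    res = autocorr_lattice(stretched, 4.0)
    assert res["anisotropic"] or res["n_peaks"] < 2


def test_lineprofile_direction_dependence():
    img, truth, _ = synth_em_image(d=395.0, a=355.5, pixel_nm=4.0, seed=0)
    y0 = float(truth.positions[0, 1] / 4.0)
    nn = lineprofile_spacing(img, ((y0, 4.0), (y0, img.shape[1] - 4.0)), 4.0)
    assert nn["d_hat"] == pytest.approx(395.0, abs=4.0)
    assert nn["d_se"] < 4.0
    x0 = float(truth.positions[0, 0] / 4.0) + 395.0 / 4 / 4.0
    rows = lineprofile_spacing(img, ((4.0, x0), (img.shape[0] - 4.0, x0)), 4.0)
    assert rows["d_hat"] == pytest.approx(395.0 * np.sqrt(3) / 2, abs=4.0)


def test_lineprofile_blur_invariance():
    img1, truth, _ = synth_em_image(d=395.0, a=355.5, pixel_nm=4.0, blur_sigma_px=1.0, seed=0)
    img2, _, _ = synth_em_image(d=395.0, a=355.5, pixel_nm=4.0, blur_sigma_px=2.0, seed=0)
    y0 = float(truth.positions[0, 1] / 4.0)
    line = ((y0, 4.0), (y0, img1.shape[1] - 4.0))
    d1 = lineprofile_spacing(img1, line, 4.0)["d_hat"]
    d2 = lineprofile_spacing(img2, line, 4.0)["d_hat"]
    assert abs(d1 - d2) <= 2.0


def test_lineprofile_too_few_peaks_raises():
    img = np.zeros((64, 64))
    img[30:34, 30:34] = 1.0
    with pytest.raises(NoLatticeError):
        lineprofile_spacing(img, ((32.0, 2.0), (32.0, 62.0)), 4.0)
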