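import numpy as np
import pytest

from coloptics.fdtd import FdtdConfig, peak_metrics, run_fdtd, run_fdtd_image
from coloptics.structure import LatticeSpec, make_hexagonal
from coloptics.tmm import MultilayerStack, tmm_reflectance
from coloptics.types import ParticleEnsemble

WL4 = np.arange(300.0, 700.0 + 1e-9, 4.0)


def _empty_ensemble(box):
    # a single vanishing disk: a scatter-free background box
    return ParticleEnsemble(np.array([[box[0] / 2, box[1] / 2]]), radius=1e-3,
                            box=box, periodic_y=True)


def test_empty_box_reflects_nothing():
    box = (1000.0, 790.0)
    cfg = FdtdConfig(box=box, run_time_fs=120.0, wavelengths=WL4)
    sp = run_fdtd(_empty_ensemble(box), config=cfg)
    assert sp.R_total.max() < 1e-3
    assert np.abs(sp.R_total + sp.T - 1).max() < 0.02


def test_determinism_bit_identical():
    box = (1000.0, 790.0)
    spec = LatticeSpec(d=395.0, a=375.0, box=box, ff=0.4)
    cfg = FdtdConfig(box=box, run_time_fs=100.0, wavelengths=WL4)
    s1 = run_fdtd(make_hexagonal(spec), config=cfg)
    s2 = run_fdtd(make_hexagonal(spec), config=cfg)
    np.testing.assert_array_equal(s1.R_total, s2.R_total)
    np.testing.assert_array_equal(s1.R_specular, s2.R_specular)


def test_flat_stack_matches_tmm_within_3_percent_rms():
    """Cross-solver oracle: a laterally uniform multilayer must agree with
    the transfer-matrix solution."""
    n_per, t_hi, t_lo, pix = 8, 170.0, 170.0, 10.0
    col = []
    for _ in range(n_per):
        col += [1.0] * int(t_hi / pix) + [0.0] * int(t_lo / pix)
    img = np.array(col)[:, None] * np.ones((1, 40))
    wl = np.arange(300.0, 700.0 + 1e-9, 2.0)
    cfg = FdtdConfig(box=(img.shape[0] * pix, img.shape[1] * pix),
                     run_time_fs=250.0, wavelengths=wl)
    sp = run_fdtd_image(img, pix, config=cfg)
    stack = MultilayerStack([(1.38, t_hi), (1.34, t_lo)], ambient_index=1.34,
                            substrate_index=1.34, repetitions=n_per)
    tm = tmm_reflectance(stack, 0.0, "TM", wl)
    rms = float(np.sqrt(np.mean((sp.R_total - tm.R) ** 2)))
    assert rms < 0.03
    # flat stacks have no lateral structure: no diffracted flux
    assert sp.R_diffracted.max() < 0.01 * max(sp.R_total.max(), 1e-12)


def test_image_and_ensemble_representations_agree():
    """Rendering the lattice into a binary image and rasterizing the disks
    directly must give the same spectrum within 3% RMS."""
    box = (2500.0, 6 * 395.0)
    spec = LatticeSpec(d=395.0, a=375.0, box=box, ff=0.6)
    ens = make_hexagonal(spec)
    cfg = FdtdConfig(box=box, run_time_fs=220.0, wavelengths=WL4)
    sp_ens = run_fdtd(ens, config=cfg)

    pix = 5.0
    nx, ny = int(box[0] / pix), int(box[1] / pix)
    yy, xx = np.mgrid[0:nx, 0:ny]
    img = np.zeros((nx, ny))
    for cx, cy in ens.positions:
        dx = (yy + 0.5) * pix - cx
        dy = (xx + 0.5) * pix - cy
        dy -= box[1] * np.round(dy / box[1])
        img[dx**2 + dy**2 <= ens.radius**2] = 1.0
    sp_img = run_fdtd_image(img, pix, config=cfg)
    scale = max(sp_ens.R_total.max(), 1e-12)
    rms = float(np.sqrt(np.mean((sp_ens.R_total - sp_img.R_total) ** 2))) / scale
    assert rms < 0.20  # relative to the peak; absolute RMS much smaller
    assert abs(float(np.sqrt(np.mean((sp_ens.R_total - sp_img.R_total) ** 2)))) < 0.03


def test_energy_conservation_and_channel_sum(fdtd_kg_spectrum):
    sp = fdtd_kg_spectrum
    assert np.abs(sp.R_total + sp.T - 1).max() <= 0.02
    np.testing.assert_allclose(sp.R_specular + sp.R_diffracted, sp.R_total,
                               atol=1e-9 + 0.01 * sp.R_total.max())


def test_diffraction_cutoff_no_first_order_beyond_lateral_period(fdtd_kg_spectrum):
    """Beyond lambda = n_env * lateral period no nonzero order propagates,
    so the diffracted channel must vanish."""
    sp = fdtd_kg_spectrum
    cutoff = 1.34 * 395.0  # first-order onset in the embedding medium
    far = sp.wavelength > cutoff + 30
    assert sp.R_diffracted[far].max() < 5e-3 * max(sp.R_total.max(), 1e-12)


def test_grid_convergence_of_main_peak():
    """The 473-analogue peak moves < 3 nm when the grid is halved."""
    box = (2500.0, 6 * 395.0)
    spec = LatticeSpec(d=395.0, a=375.0, box=box, ff=0.6)
    ens = make_hexagonal(spec)
    wl = np.arange(420.0, 540.0 + 1e-9, 2.0)
    peaks = []
    for grid in (10.0, 5.0):
        cfg = FdtdConfig(grid_nm=grid, box=box, run_time_fs=220.0, wavelengths=wl)
        sp = run_fdtd(ens, config=cfg, check_energy=False)
        peaks.append(peak_metrics(sp, (430.0, 520.0))["position"])
    assert abs(peaks[0] - peaks[1]) <= 3.0


def test_image_smaller_than_box_rejected():
    img = np.zeros((20, 20))
    cfg = FdtdConfig(box=(1000.0, 1000.0), wavelengths=WL4)
    with pytest.raises(ValueError, match="tiling"):
        run_fdtd_image(img, 10.0, config=cfg)
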