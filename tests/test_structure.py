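import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coloptics.structure import (
    DisorderSpec,
    LatticeSpec,
    first_shell_q,
    generate_disordered,
    hex_fill_limit,
    jitter_lattice,
    make_hexagonal,
    psi6,
    target_sq,
)
from coloptics.types import ValidationError


def brute_force_psi6(pos, cutoff):
    """Independent O(N^2) loop oracle for the bond-orientational order."""
    acc = []
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            dx, dy = pos[j] - pos[i]
            if np.hypot(dx, dy) < cutoff:
                acc.append(np.exp(6j * np.arctan2(dy, dx)))
    return abs(np.mean(acc)) if acc else 0.0


def test_make_hexagonal_reference_particle_count():
    ens = make_hexagonal(LatticeSpec(d=395.0, a=375.0, box=(5000.0, 5000.0), ff=0.6,
                                     periodic_y=False))
    assert len(ens) == 136


def test_make_hexagonal_nearest_neighbour_exact():
    ens = make_hexagonal(LatticeSpec(d=395.0, a=375.0, box=(5000.0, 5000.0), ff=0.5,
                                     periodic_y=False))
    assert ens.pair_distances().min() == pytest.approx(395.0, abs=1e-9)


def test_orientations_related_by_rotation():
    s0 = LatticeSpec(d=395.0, a=375.0, box=(3000.0, 3000.0), ff=0.4, periodic_y=False)
    s30 = LatticeSpec(d=395.0, a=375.0, box=(3000.0, 3000.0), ff=0.4, orientation=30.0,
                      periodic_y=False)
    e0, e30 = make_hexagonal(s0), make_hexagonal(s30)
    # same minimal distances and counts; orientation of the psi6 phase differs
    assert len(e0) == len(e30)
    assert e30.pair_distances().min() == pytest.approx(e0.pair_distances().min(), rel=1e-9)


def test_ff_above_hexagonal_limit_rejected():
    with pytest.raises(ValidationError):
        LatticeSpec(d=395.0, a=300.0, box=(3000.0, 3000.0),
                    ff=hex_fill_limit(300.0, 395.0) + 0.05)


def test_psi6_perfect_vs_poisson_with_brute_force_oracle():
    ens = make_hexagonal(LatticeSpec(d=395.0, a=375.0, box=(4000.0, 4000.0), ff=0.5,
                                     periodic_y=False))
    assert psi6(ens) == pytest.approx(1.0, abs=1e-9)
    assert psi6(ens) == pytest.approx(
        brute_force_psi6(ens.positions, 1.4 * 2 * ens.radius), abs=1e-12
    )
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 4000, (300, 2))
    from coloptics.types import ParticleEnsemble

    poisson = ParticleEnsemble(pts, radius=1.0, box=(4000.0, 4000.0))
    assert psi6(poisson, cutoff_frac=200.0) < 0.1


def test_jitter_zero_is_identity():
    spec = LatticeSpec(d=395.0, a=375.0, box=(3000.0, 2370.0), ff=0.5)
    np.testing.assert_array_equal(jitter_lattice(spec, 0.0).positions,
                                  make_hexagonal(spec).positions)


@settings(max_examples=10, derandomize=True, deadline=None)
@given(sigma=st.floats(0.5, 8.0), seed=st.integers(0, 100))
def test_jitter_never_violates_hard_disks(sigma, seed):
    spec = LatticeSpec(d=395.0, a=375.0, box=(2500.0, 1580.0), ff=0.5)
    ens = jitter_lattice(spec, sigma, seed=seed)
    assert ens.pair_distances().min() >= 2 * ens.radius * (1 - 1e-9)


def test_jitter_debye_waller_peak_suppression():
    """First-shell peak height follows exp(-q1^2 sigma^2) within 15%."""
    from coloptics.structure_factor import sq_points

    spec = LatticeSpec(d=395.0, a=375.0, box=(5000.0, 5000.0), ff=0.6, periodic_y=False)
    q1 = first_shell_q(395.0)

    def shell_max(e):
        sf = sq_points(e, q_max=1.3 * q1, n_grid=160)
        qxx, qyy = np.meshgrid(sf.qx, sf.qy)
        qr = np.hypot(qxx, qyy)
        return sf.S[np.abs(qr - q1) < 0.15 * q1].max()

    h0 = shell_max(make_hexagonal(spec))
    sigma = 10.0
    hj = np.mean([shell_max(jitter_lattice(spec, sigma, seed=s)) for s in range(3)])
    assert hj / h0 == pytest.approx(np.exp(-(q1 * sigma) ** 2), abs=0.15)


def test_jitter_radial_width_monotone_in_sigma():
    """Displacement disorder moves first-shell weight into the diffuse
    background, so the second-moment radial width of the shell grows."""
    from coloptics.structure_factor import sq_points

    spec = LatticeSpec(d=395.0, a=375.0, box=(5000.0, 5000.0), ff=0.6, periodic_y=False)
    q1 = first_shell_q(395.0)
    widths = []
    for sigma in (0.0, 5.0, 10.0):
        per_seed = []
        for seed in (2, 3, 4):
            ens = jitter_lattice(spec, sigma, seed=seed)
            sf = sq_points(ens, q_max=1.4 * q1, n_grid=200)
            q, prof = sf.radial_profile(n_bins=80)
            sel = (q > 0.6 * q1) & (q < 1.4 * q1) & np.isfinite(prof)
            p = prof[sel]
            per_seed.append(np.sqrt(np.sum(p * (q[sel] - q1) ** 2) / np.sum(p)))
        widths.append(np.mean(per_seed))
    assert widths[0] < widths[1] < widths[2]


def test_jitter_rejection_rate_error():
    spec = LatticeSpec(d=395.0, a=375.0, box=(5000.0, 5000.0), ff=0.6, periodic_y=False)
    with pytest.raises(ValidationError, match="reduce sigma"):
        jitter_lattice(spec, 14.0, seed=2)


def test_target_sq_delta_limit_and_isotropic_ring():
    spec = LatticeSpec(d=395.0, a=375.0, box=(2500.0, 2370.0), ff=0.6)
    t0 = target_sq(spec, DisorderSpec(0.0, 0.0))
    q1 = first_shell_q(395.0)
    assert q1 == pytest.approx(0.018375, abs=2e-5)
    qr = np.hypot(t0.q[:, 0], t0.q[:, 1])
    assert qr[np.argmax(t0.S)] == pytest.approx(q1, rel=1e-3)
    iso = target_sq(spec, DisorderSpec(0.0, None))
    ring = np.abs(qr - q1) < 0.02 * q1
    assert np.std(iso.S[ring]) / np.mean(iso.S[ring]) < 0.01


def test_target_sq_radial_fwhm_scales_with_sigma_k():
    """Target peak width is the requested sigma_k convolved with the
    finite-size floor of the box."""
    from coloptics.structure import finite_size_sigma

    spec = LatticeSpec(d=395.0, a=375.0, box=(2500.0, 2370.0), ff=0.6)
    sigma_k = 0.15
    t = target_sq(spec, DisorderSpec(sigma_k, 0.0), n_radial=41)
    q1 = first_shell_q(395.0)
    qr = np.hypot(t.q[:, 0], t.q[:, 1])
    # radial cut through the 0-degree peak
    phi = np.degrees(np.arctan2(t.q[:, 1], t.q[:, 0]))
    cut = np.abs(phi) < 1e-6
    r, s = qr[cut], t.S[cut]
    order = np.argsort(r)
    r, s = r[order], s[order]
    above = r[s > 0.5 * s.max()]
    fwhm = above.max() - above.min()
    sig_eff = np.hypot(sigma_k, finite_size_sigma(spec))
    assert fwhm == pytest.approx(2.355 * sig_eff * q1, rel=0.25)


def test_generate_disordered_zero_target_stays_crystalline():
    spec = LatticeSpec(d=395.0, a=375.0, box=(2500.0, 2370.0), ff=0.6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ens = generate_disordered(spec, DisorderSpec(0.004, 0.0, seed=0), n_steps=8000)
    assert psi6(ens) > 0.7
    assert ens.pair_distances().min() >= 2 * ens.radius * (1 - 1e-9)


def test_generate_disordered_isotropic_melts():
    spec = LatticeSpec(d=395.0, a=375.0, box=(2500.0, 2370.0), ff=0.6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ens = generate_disordered(spec, DisorderSpec(0.0, None, seed=0), n_steps=15000)
    assert psi6(ens) < 0.3
    assert ens.pair_distances().min() >= 2 * ens.radius * (1 - 1e-9)
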