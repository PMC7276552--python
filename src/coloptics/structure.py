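"""Perfect and disorder-controlled 2D hard-disk packings.

The bacterial cross-section is modelled as hard disks on a hexagonal
lattice.  Disorder is introduced the way the optical analysis
parametrizes it: ``sigma_k`` broadens the Bragg peaks radially (positional
disorder of the lattice spacing) and ``sigma_phi`` azimuthally
(orientational disorder of the crystal axes).  Ensembles matching a
target structure factor are produced by simulated annealing of
single-particle moves with hard-disk rejection (inverse design); a fast
Gaussian-jitter generator covers the small-``sigma_k`` regime.

Orientation convention: ``orientation = 0`` places the close-packed rows
parallel to the lateral (y) axis, i.e. the stacking direction of the
colony layers along x — the geometry probed by normal incidence
("K-Gamma" in the band-structure labelling used throughout the package).
``orientation = 30`` is the 30-degree rotated ("M-Gamma") geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import ParticleEnsemble, ValidationError

__all__ = [
    "LatticeSpec",
    "DisorderSpec",
    "TargetStructureFactor",
    "make_hexagonal",
    "jitter_lattice",
    "target_sq",
    "generate_disordered",
    "psi6",
    "first_shell_q",
    "hex_fill_limit",
    "finite_size_sigma",
]


def first_shell_q(d: float) -> float:
    """Radius of the first Bragg shell of a hexagonal lattice, 4 pi / (sqrt(3) d)."""
    return 4 * np.pi / (np.sqrt(3) * d)


def hex_fill_limit(a: float, d: float) -> float:
    """Area fraction of a hexagonal lattice of disks (diameter a, spacing d)."""
    return float(np.pi / (2 * np.sqrt(3)) * (a / d) ** 2)


@dataclass
class LatticeSpec:
    d: float = 395.0
    a: float = 375.0
    orientation: float = 0.0
    box: tuple[float, float] = (5000.0, 5000.0)
    ff: float = 0.6
    periodic_y: bool = True

    def __post_init__(self) -> None:
        if self.a > self.d:
            raise ValidationError("disk diameter a must not exceed lattice constant d")
        if self.ff > hex_fill_limit(self.a, self.d) + 1e-12:
            raise ValidationError(
                f"requested ff={self.ff} exceeds the hexagonal limit "
                f"{hex_fill_limit(self.a, self.d):.4f} for a/d={self.a / self.d:.3f}"
            )

    @property
    def n_particles(self) -> int:
        return int(round(self.ff * self.box[0] * self.box[1] / (np.pi * self.a**2 / 4)))


@dataclass
class DisorderSpec:
    """Targets for the disordered generator.

    ``sigma_k`` is the relative standard deviation of the Bragg
    wavevector modulus (radial peak broadening), ``sigma_phi`` the
    standard deviation in degrees of the azimuth relative to the incident
    direction; ``sigma_phi = None`` requests the isotropic (uniform ring)
    limit.
    """

    sigma_k: float = 0.0
    sigma_phi: float | None = 0.0
    seed: int = 0
    n_realizations: int = 7

    def __post_init__(self) -> None:
        if self.sigma_k < 0:
            raise ValidationError("sigma_k must be nonnegative")
        if self.sigma_phi is not None and self.sigma_phi < 0:
            raise ValidationError("sigma_phi must be nonnegative")
        if self.n_realizations < 1:
            raise ValidationError("n_realizations must be >= 1")

    @property
    def isotropic(self) -> bool:
        return self.sigma_phi is None or self.sigma_phi >= 60.0


@dataclass
class TargetStructureFactor:
    q: np.ndarray  # (M, 2) wavevectors, 1/nm
    S: np.ndarray  # (M,) target values, arbitrary common scale
    weight: np.ndarray  # (M,) weights for the matching objective

    def __post_init__(self) -> None:
        if np.any(self.S < 0):
            raise ValidationError("target S must be nonnegative")


def _hex_sites(spec: LatticeSpec) -> np.ndarray:
    """All lattice sites of the oriented hexagonal lattice inside the box,
    with the lateral period snapped to the box height for periodicity."""
    bx, by = spec.box
    d = spec.d
    if np.isclose(spec.orientation % 60, 0.0, atol=1e-9):
        col_dx, y_period = np.sqrt(3) / 2 * d, d
    elif np.isclose(spec.orientation % 60, 30.0, atol=1e-9):
        col_dx, y_period = d / 2, np.sqrt(3) * d
    else:
        # arbitrary orientation: rotate an oversized 0-degree lattice (not y-periodic)
        big = LatticeSpec(spec.d, spec.a, 0.0, (2.2 * max(spec.box),) * 2, spec.ff, False)
        pts = _hex_sites(big) - np.array(big.box) / 2
        th = np.deg2rad(spec.orientation)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = pts @ rot.T + np.array(spec.box) / 2
        keep = (pts[:, 0] >= 0) & (pts[:, 0] <= bx) & (pts[:, 1] >= 0) & (pts[:, 1] <= by)
        return pts[keep]

    if spec.periodic_y:
        # snap the lateral period to the box so wrapped rows stay periodic;
        # choose commensurate boxes (box_y = k * period) to avoid strain
        m_y = max(int(round(by / y_period)), 1)
        y_eff = by / m_y
    else:
        m_y = int(np.floor(by / y_period))
        y_eff = y_period
    n_cols = int(np.floor(bx / col_dx))
    xs = (np.arange(n_cols) - (n_cols - 1) / 2) * col_dx + bx / 2
    sites = []
    for j, x in enumerate(xs):
        ys = (np.arange(m_y) + 0.5 * (j % 2)) * y_eff
        sites.extend((x, y % by) for y in ys)
    return np.array(sites)


def make_hexagonal(spec: LatticeSpec) -> ParticleEnsemble:
    """Hexagonal hard-disk packing filling a centred band of the box.

    The lattice spans the full lateral (periodic) extent; the particle
    count ``N = round(ff * box_area / disk_area)`` is reached by keeping
    the N sites closest to the box centre along the stacking direction, so
    ordered and disordered ensembles contain identical numbers of disks.
    """
    sites = _hex_sites(spec)
    n = spec.n_particles
    if n > len(sites):
        raise ValidationError(
            f"box holds only {len(sites)} lattice sites but ff={spec.ff} needs {n}"
        )
    cx = spec.box[0] / 2
    order = np.lexsort((np.abs(sites[:, 1] - spec.box[1] / 2), np.abs(sites[:, 0] - cx)))
    pos = sites[order[:n]]
    return ParticleEnsemble(pos, radius=spec.a / 2, box=spec.box, periodic_y=spec.periodic_y)


def jitter_lattice(
    spec: LatticeSpec,
    displacement_sigma: float,
    seed: int = 0,
    max_redraw_frac: float = 1.0,
) -> ParticleEnsemble:
    """Lattice sites plus i.i.d. Gaussian displacements, overlaps rejected.

    Fast approximate positional disorder: a displacement sigma maps onto a
    radial Bragg broadening through the measured S(q) (Debye-Waller-like
    peak suppression ``exp(-q^2 sigma^2)``).  More redraws than particles
    (a >50% rejection rate) raises, suggesting a smaller sigma.
    """
    base = make_hexagonal(spec)
    if displacement_sigma == 0:
        return base
    rng = np.random.default_rng(seed)
    pos = base.positions.copy()
    n = len(base)
    bx, by = spec.box
    a = spec.a

    def overlaps(p, idx):
        diff = p[idx][:, None, :] - p[None, :, :]
        if spec.periodic_y:
            diff[..., 1] -= by * np.round(diff[..., 1] / by)
        r2 = (diff**2).sum(-1)
        r2[np.arange(len(idx)), idx] = np.inf
        return (r2 < (a * (1 - 1e-9)) ** 2).any(axis=1)

    trial = pos + rng.normal(0, displacement_sigma, pos.shape)
    trial[:, 0] = np.clip(trial[:, 0], 0, bx)
    if spec.periodic_y:
        trial[:, 1] %= by
    else:
        trial[:, 1] = np.clip(trial[:, 1], 0, by)
    redraws = 0
    bad = np.where(overlaps(trial, np.arange(n)))[0]
    while bad.size:
        redraws += bad.size
        if redraws > max_redraw_frac * n:
            raise ValidationError(
                f"jitter sigma={displacement_sigma} nm rejects too often "
                f"({redraws} redraws for {n} disks); reduce sigma"
            )
        trial[bad] = pos[bad] + rng.normal(0, displacement_sigma, (bad.size, 2))
        trial[bad, 0] = np.clip(trial[bad, 0], 0, bx)
        trial[bad, 1] = trial[bad, 1] % by if spec.periodic_y else np.clip(trial[bad, 1], 0, by)
        bad = np.where(overlaps(trial, np.arange(n)))[0]
    return ParticleEnsemble(trial, radius=a / 2, box=spec.box, periodic_y=spec.periodic_y)


def _first_shell_vectors(spec: LatticeSpec) -> np.ndarray:
    """The six first-shell reciprocal vectors of the oriented lattice."""
    q1 = first_shell_q(spec.d)
    base = np.deg2rad(spec.orientation)
    ang = base + np.deg2rad(np.arange(6) * 60.0)
    return q1 * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def finite_size_sigma(spec: LatticeSpec) -> float:
    """Relative radial width of a Bragg peak imposed by the finite box.

    A crystal of linear size L has first-shell peaks of FWHM ~ 2 pi / L in
    q; expressed as a Gaussian sigma relative to |q1| this is the floor
    below which no generator can narrow the peaks, so disorder targets
    are convolved with it.
    """
    L = float(np.sqrt(spec.box[0] * spec.box[1]))
    return (2 * np.pi / L) / first_shell_q(spec.d) / 2.355


def target_sq(
    spec: LatticeSpec,
    disorder: DisorderSpec,
    n_radial: int = 9,
    n_azimuthal: int = 90,
) -> TargetStructureFactor:
    """Target S(q) on a polar grid around the first Bragg shell.

    Six Gaussian peaks at the reciprocal first shell, broadened radially
    by ``sigma_k * |q1|`` and azimuthally by ``sigma_phi``, both convolved
    with the finite-size width of the box (so the zero-disorder target is
    exactly what a perfect finite lattice can produce); the isotropic
    limit is a uniform ring.
    """
    q1 = first_shell_q(spec.d)
    sig_fs = finite_size_sigma(spec)
    sig_r = np.hypot(disorder.sigma_k, sig_fs) * q1
    radii = q1 + np.linspace(-3, 3, n_radial) * sig_r
    phis = np.linspace(0, 2 * np.pi, n_azimuthal, endpoint=False)
    rr, pp = np.meshgrid(radii, phis, indexing="ij")
    q = np.stack([rr * np.cos(pp), rr * np.sin(pp)], axis=-1).reshape(-1, 2)

    radial = np.exp(-0.5 * ((np.hypot(q[:, 0], q[:, 1]) - q1) / sig_r) ** 2)
    if disorder.isotropic:
        azi = np.ones(len(q))
    else:
        sig_p = np.hypot(np.deg2rad(disorder.sigma_phi), sig_fs)
        peak_angles = np.arctan2(*_first_shell_vectors(spec)[:, ::-1].T)
        dphi = np.angle(np.exp(1j * (np.arctan2(q[:, 1], q[:, 0])[:, None] - peak_angles[None, :])))
        azi = np.exp(-0.5 * (dphi / sig_p) ** 2).sum(axis=1)
    S = radial * azi
    S /= S.max()
    return TargetStructureFactor(q=q, S=S, weight=np.ones(len(q)))


def _rho(q: np.ndarray, pos: np.ndarray) -> np.ndarray:
    return np.exp(1j * (q @ pos.T)).sum(axis=1)


def _objective(rho: np.ndarray, target: TargetStructureFactor, n: int) -> float:
    s = (rho.real**2 + rho.imag**2) / n
    st, w = target.S, target.weight
    scale = max((w * s * st).sum() / max((w * st * st).sum(), 1e-30), 0.0)
    return float((w * (s - scale * st) ** 2).sum() / (w * (1 + scale * st) ** 2).sum())


def generate_disordered(
    spec: LatticeSpec,
    disorder: DisorderSpec,
    target: TargetStructureFactor | None = None,
    n_steps: int = 40_000,
    step_frac: float = 0.1,
    t_start: float = 1e-2,
    t_end: float = 1e-5,
    tol: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ParticleEnsemble:
    """Inverse design: anneal hard-disk positions toward a target S(q).

    Starting from the perfect lattice, particles are moved one at a time
    (Gaussian steps of ``step_frac * a``, hard-disk overlap rejection) and
    moves are accepted by a Metropolis rule on the weighted squared
    mismatch between the ensemble structure factor and the target, under a
    geometric temperature schedule.  If the objective stalls above ``tol``
    the best configuration found is returned with a warning.
    """
    rng = rng or np.random.default_rng(disorder.seed)
    if target is None:
        target = target_sq(spec, disorder)
    ens = make_hexagonal(spec)
    pos = ens.positions.copy()
    n = len(ens)
    a = spec.a
    bx, by = spec.box
    q = target.q
    rho = _rho(q, pos)
    obj = _objective(rho, target, n)
    best_pos, best_obj = pos.copy(), obj

    if disorder.isotropic:
        # melt first so the annealer does not fight the lattice memory
        pre = int(0.5 * n_steps)
    else:
        pre = 0

    step = step_frac * a
    temps = t_start * (t_end / t_start) ** (np.arange(n_steps) / max(n_steps - 1, 1))
    accepted = 0
    for it in range(n_steps):
        i = rng.integers(n)
        new = pos[i] + rng.normal(0, step if it >= pre else a / 2, 2)
        new[0] = min(max(new[0], 0.0), bx)
        new[1] = new[1] % by if spec.periodic_y else min(max(new[1], 0.0), by)
        diff = pos - new
        if spec.periodic_y:
            diff[:, 1] -= by * np.round(diff[:, 1] / by)
        r2 = (diff**2).sum(1)
        r2[i] = np.inf
        if r2.min() < (a * (1 - 1e-9)) ** 2:
            continue
        dr = np.exp(1j * (q @ new)) - np.exp(1j * (q @ pos[i]))
        rho_new = rho + dr
        if it < pre:
            # pure hard-disk shuffle toward the melt
            pos[i] = new
            rho = rho_new
            continue
        obj_new = _objective(rho_new, target, n)
        if obj_new < obj or rng.random() < np.exp((obj - obj_new) / max(temps[it], 1e-12)):
            pos[i] = new
            rho = rho_new
            obj = obj_new
            accepted += 1
            if obj < best_obj:
                best_obj = obj
                best_pos = pos.copy()
    if best_obj > tol:
        warnings.warn(
            f"annealing stalled at objective {best_obj:.3g} > tol {tol}; returning best-so-far"
        )
    return ParticleEnsemble(best_pos, radius=a / 2, box=spec.box, periodic_y=spec.periodic_y)


def psi6(ensemble: ParticleEnsemble, cutoff_frac: float = 1.4) -> float:
    """Global bond-orientational order parameter.

    Bonds are pairs closer than ``cutoff_frac * 2 * radius``;
    ``psi6 = |mean over bonds of exp(6 i theta)|`` is 1 for a perfect
    hexagonal lattice and near 0 for isotropic disorder.
    """
    p = ensemble.positions
    n = len(ensemble)
    if n < 3:
        raise ValueError("need at least 3 particles")
    diff = p[:, None, :] - p[None, :, :]
    if ensemble.periodic_y:
        by = ensemble.box[1]
        diff[..., 1] -= by * np.round(diff[..., 1] / by)
    r = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, 1)
    sel = r[iu] < cutoff_frac * 2 * ensemble.radius
    if not sel.any():
        return 0.0
    dx = diff[iu][sel][:, 0]
    dy = diff[iu][sel][:, 1]
    ang = np.arctan2(dy, dx)
    return float(np.abs(np.exp(6j * ang).mean()))
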