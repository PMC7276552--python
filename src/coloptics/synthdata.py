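"""Synthetic goniometer maps and EM-like cross-section images.

The goniometer forward model treats each crystalline domain as a 2D
hexagonal lattice tilted by an angle ``alpha``.  A domain scatters where
the elastic (Laue/Ewald) condition ``|k + G| = |k|`` is met by the
internally refracted beam, which reproduces every feature class of the
measurements from one rule:

* ``G = (-p, 0)`` rows give the specular family, i.e. the cosine
  dispersion law ``lambda_s = lambda_p cos(arcsin(sin(theta)/n_avg))``;
* laterally periodic ``G`` with ``n2 = +-1, +-2`` give diffraction spots
  whose exit angles satisfy the grating equation
  ``theta_m = arcsin(m lambda/d - sin theta_i)``;
* the tilt distribution sweeps these spots into the diagonal streaks seen
  in the maps, and the streaks overlay once corrected by the incidence
  angle because the corrected spot locus depends only on the effective
  incidence ``theta_in - alpha``.

For a lattice with nearest-neighbour distance ``d = 395`` nm and
``n_avg = 1.376`` the model puts the first-order spot at normal incidence
at (58.3 deg, 336 nm) and the specular Bragg orders at 471 / 314 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import AngleResolvedMap, ParticleEnsemble, SpecularTrace

__all__ = [
    "TiltDistribution",
    "ColonyModel",
    "diffraction_branches",
    "synth_goniometer_map",
    "synth_specular_trace",
    "synth_em_image",
    "DAY1_MODEL",
    "DAY2_MODEL",
]

_DEG = np.pi / 180.0


@dataclass
class TiltDistribution:
    """Domain-tilt density: a Gaussian core of flat-lying domains plus a
    uniform tail of strongly re-oriented domains.

    ``core_halfwidth`` is the +-halfwidth (deg) of the dominant flat
    population (Gaussian sigma = core_halfwidth / 2); ``tail_weight`` is
    the probability mass in the uniform tail over ``+-tail_range`` deg.
    """

    core_halfwidth: float = 10.0
    tail_weight: float = 0.1
    tail_range: float = 90.0

    def __post_init__(self) -> None:
        if not 0 <= self.tail_weight <= 1:
            raise ValueError("tail_weight must be in [0, 1]")
        if self.core_halfwidth < 0 or self.tail_range < 0:
            raise ValueError("widths must be nonnegative")

    @property
    def is_delta(self) -> bool:
        return self.core_halfwidth == 0 and self.tail_weight == 0

    def density(self, alpha: np.ndarray) -> np.ndarray:
        alpha = np.asarray(alpha, dtype=float)
        out = np.zeros_like(alpha)
        if self.core_halfwidth > 0:
            sig = self.core_halfwidth / 2.0
            out += (1 - self.tail_weight) * np.exp(-0.5 * (alpha / sig) ** 2) / (
                sig * np.sqrt(2 * np.pi)
            )
        elif self.tail_weight < 1:
            # degenerate core: delta at 0, handled by the sampler
            pass
        if self.tail_weight > 0 and self.tail_range > 0:
            out += self.tail_weight * (np.abs(alpha) <= self.tail_range) / (2 * self.tail_range)
        return out

    def samples(self, step: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature nodes and weights covering the distribution support."""
        if self.is_delta:
            return np.array([0.0]), np.array([1.0])
        span = max(self.tail_range if self.tail_weight > 0 else 0.0, 2.5 * self.core_halfwidth)
        alpha = np.arange(-span, span + step / 2, step)
        w = self.density(alpha) * step
        if self.core_halfwidth == 0 and self.tail_weight > 0:
            # delta core on top of the tail
            i0 = np.argmin(np.abs(alpha))
            w[i0] += 1 - self.tail_weight
        return alpha, w


@dataclass
class ColonyModel:
    """Ground-truth colony for the synthetic goniometer.

    ``d`` is the lattice constant (nm), ``a`` the cell diameter (nm,
    default 0.9 d), ``n_bac``/``n_env`` the cell and matrix indices; the
    volume-averaged index of the touching-disk composite sets the internal
    refraction.  ``lambda_p`` overrides the normal-incidence specular peak
    (default: the second-order Bragg wavelength ``n_avg * sqrt(3) d / 2``).
    """

    d: float = 395.0
    a: float | None = None
    n_bac: float = 1.38
    n_env: float = 1.34
    lambda_p: float | None = None
    tilt: TiltDistribution = field(default_factory=TiltDistribution)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a is None:
            self.a = 0.9 * self.d
        if not self.a <= self.d:
            raise ValueError("cell diameter a must not exceed lattice constant d")
        if not (self.n_bac > self.n_env > 1):
            raise ValueError("require n_bac > n_env > 1")
        if not 0.8 * self.d <= self.a <= self.d:
            raise ValueError("a/d outside the supported range [0.8, 1]")

    @property
    def fill_fraction(self) -> float:
        """Area fraction of the hexagonal disk lattice."""
        return float(np.pi / (2 * np.sqrt(3)) * (self.a / self.d) ** 2)

    @property
    def n_avg(self) -> float:
        f = self.fill_fraction
        return float(np.sqrt(f * self.n_bac**2 + (1 - f) * self.n_env**2))

    @property
    def row_spacing(self) -> float:
        return float(np.sqrt(3) / 2 * self.d)

    @property
    def lambda_p_effective(self) -> float:
        return self.lambda_p if self.lambda_p is not None else self.n_avg * self.row_spacing


DAY2_MODEL = ColonyModel(d=395.0)
DAY1_MODEL = ColonyModel(d=425.0)


def diffraction_branches(
    model: ColonyModel,
    theta_g: np.ndarray,
    n1_max: int = 4,
    n2_max: int = 2,
) -> list[dict]:
    """Spot loci of every scattering branch versus effective incidence.

    For each reciprocal vector ``G = n1 b1 + n2 b2`` of the row-oriented
    lattice the elastic condition fixes the resonant vacuum wavelength

        lambda(G, theta_g) = -4 pi n_avg (Gx cos(theta_2) + Gy sin(theta_2)) / |G|^2

    with ``sin(theta_2) = -sin(theta_g)/n_avg`` the internal beam
    direction, and the lateral order ``m = n2`` sets the exit angle through
    the grating equation.  Returns one dict per branch with arrays
    ``lambda_nm``, ``theta_out`` (crystal frame, NaN where evanescent) and
    scalar ``weight``.
    """
    d = model.d
    lam_row = model.row_spacing
    n_avg = model.n_avg
    theta_g = np.asarray(theta_g, dtype=float)
    s2 = -np.sin(theta_g * _DEG) / n_avg
    c2 = np.sqrt(1 - s2**2)
    spec_scale = model.lambda_p_effective / (n_avg * lam_row)

    branches = []
    for n1 in range(-2 * n1_max, 1):
        for n2 in range(-n2_max, n2_max + 1):
            if n1 == 0 and n2 == 0:
                continue
            gx = 2 * np.pi / lam_row * (n1 - n2 / 2.0)
            gy = 2 * np.pi / d * n2
            g2 = gx**2 + gy**2
            lam = -4 * np.pi * n_avg * (gx * c2 + gy * s2) / g2
            if n2 == 0:
                lam = lam * spec_scale
            ok = lam > 0
            if not ok.any():
                continue
            s_out = np.where(ok, n2 * lam / d - np.sin(theta_g * _DEG), np.nan)
            s_out = np.where(np.abs(s_out) <= 1, s_out, np.nan)
            theta_out = np.arcsin(s_out) / _DEG
            if not np.isfinite(theta_out).any():
                continue
            branches.append(
                {
                    "n1": n1,
                    "n2": n2,
                    "order": n2,
                    "lambda_nm": lam,
                    "theta_out": theta_out,
                    "weight": 1.0 / (n1**2 + n2**2),
                }
            )
    return branches


def synth_goniometer_map(
    model: ColonyModel,
    theta_in: float,
    theta_out_grid: np.ndarray | None = None,
    wavelength_grid: np.ndarray | None = None,
    kernel_theta_deg: float = 1.5,
    kernel_lambda_nm: float = 5.0,
    specular_weight: float = 4.0,
    blind_halfwidth: float = 5.0,
    angle_jitter_deg: float = 0.0,
    tilt_step_deg: float = 0.25,
    rng: np.random.Generator | None = None,
) -> AngleResolvedMap:
    """Forward-model an angle-resolved scattering map at one incidence angle.

    The map is the tilt-density-weighted superposition of Gaussian spot
    kernels at the branch loci of :func:`diffraction_branches`, evaluated
    in each domain's frame (effective incidence ``theta_in - alpha``) and
    rotated back to the lab frame by ``+alpha``.  ``angle_jitter_deg``
    perturbs each branch's spot angle once per map (instrumental pointing
    noise); ``model.noise_sigma`` adds relative Gaussian intensity noise
    clipped at zero; the blind region around the source arm is NaN.
    """
    if not -90 <= theta_in <= 90:
        raise ValueError("theta_in must be within [-90, 90] deg")
    if theta_out_grid is None:
        theta_out_grid = np.arange(-90.0, 90.0 + 1e-9, 0.5)
    if wavelength_grid is None:
        wavelength_grid = np.arange(300.0, 700.0 + 1e-9, 2.0)
    rng = rng or np.random.default_rng(model.seed)

    alpha, w_alpha = model.tilt.samples(step=tilt_step_deg)
    theta_g = theta_in - alpha
    branches = diffraction_branches(model, theta_g)

    intensity = np.zeros((theta_out_grid.size, wavelength_grid.size))
    dth = theta_out_grid[1] - theta_out_grid[0]
    dlam = wavelength_grid[1] - wavelength_grid[0]
    nwin_th = max(int(np.ceil(4 * kernel_theta_deg / dth)), 2)
    nwin_lam = max(int(np.ceil(4 * kernel_lambda_nm / dlam)), 2)

    for br in branches:
        jitter = rng.normal(0.0, angle_jitter_deg) if angle_jitter_deg > 0 else 0.0
        w_br = br["weight"] * (specular_weight if br["order"] == 0 else 1.0)
        th_lab = alpha + br["theta_out"] + jitter
        lam0 = br["lambda_nm"]
        ok = (
            np.isfinite(th_lab)
            & (w_alpha > 0)
            & (th_lab > theta_out_grid[0] - 4 * kernel_theta_deg)
            & (th_lab < theta_out_grid[-1] + 4 * kernel_theta_deg)
            & (lam0 > wavelength_grid[0] - 4 * kernel_lambda_nm)
            & (lam0 < wavelength_grid[-1] + 4 * kernel_lambda_nm)
        )
        for t0, l0, wa in zip(th_lab[ok], lam0[ok], w_alpha[ok]):
            i0 = int(round((t0 - theta_out_grid[0]) / dth))
            j0 = int(round((l0 - wavelength_grid[0]) / dlam))
            i_lo, i_hi = max(i0 - nwin_th, 0), min(i0 + nwin_th + 1, theta_out_grid.size)
            j_lo, j_hi = max(j0 - nwin_lam, 0), min(j0 + nwin_lam + 1, wavelength_grid.size)
            if i_lo >= i_hi or j_lo >= j_hi:
                continue
            gth = np.exp(-0.5 * ((theta_out_grid[i_lo:i_hi] - t0) / kernel_theta_deg) ** 2)
            glam = np.exp(-0.5 * ((wavelength_grid[j_lo:j_hi] - l0) / kernel_lambda_nm) ** 2)
            intensity[i_lo:i_hi, j_lo:j_hi] += (w_br * wa) * np.outer(gth, glam)

    if model.noise_sigma > 0:
        scale = model.noise_sigma * (intensity.max() if intensity.max() > 0 else 1.0)
        intensity = np.clip(intensity + rng.normal(0.0, scale, intensity.shape), 0.0, None)

    blind = np.abs(theta_out_grid - theta_in) <= blind_halfwidth
    intensity[blind, :] = np.nan
    return AngleResolvedMap(
        theta_in=theta_in,
        theta_out=theta_out_grid,
        wavelength=wavelength_grid,
        intensity=intensity,
        blind_halfwidth=blind_halfwidth,
    )


def synth_specular_trace(
    model: ColonyModel,
    theta_grid: np.ndarray | None = None,
    noise_sigma_nm: float = 0.0,
    n_avg: float | None = None,
    rng: np.random.Generator | None = None,
) -> SpecularTrace:
    """Specular ridge lambda_s(theta_in) from the cosine dispersion law.

    ``n_avg`` overrides the composite average index of the model (e.g. to
    emulate a measured in-vivo value rather than the tabulated composite).
    """
    if theta_grid is None:
        theta_grid = np.arange(-45.0, 45.0 + 1e-9, 1.0)
    rng = rng or np.random.default_rng(model.seed)
    n = model.n_avg if n_avg is None else n_avg
    s = np.sin(theta_grid * _DEG) / n
    lam = model.lambda_p_effective * np.sqrt(1 - s**2)
    if noise_sigma_nm > 0:
        lam = lam + rng.normal(0.0, noise_sigma_nm, lam.shape)
    return SpecularTrace(theta_in=theta_grid, lambda_s=lam)


def synth_em_image(
    d: float = 396.0,
    a: float | None = None,
    pixel_nm: float = 4.0,
    jitter_nm: float = 0.0,
    blur_sigma_px: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    max_regen: int = 20,
) -> tuple[np.ndarray, ParticleEnsemble, int]:
    """EM-like cross-section: bright disks on hexagonal sites, jittered,
    blurred and noised.

    Returns ``(image, ground_truth, n_rejected)`` where ``image`` is float
    in [0, 1] with shape ``shape`` and ``ground_truth`` the jittered disk
    centres actually rendered.  Jitter draws that would overlap disks are
    rejected and redrawn (hard-disk colony); the rejection count is
    reported.
    """
    if a is None:
        a = 0.9 * d
    if pixel_nm > a / 10:
        raise ValueError("pixel_nm must resolve the disks (<= a/10)")
    rng = np.random.default_rng(seed)
    h_nm = shape[0] * pixel_nm
    w_nm = shape[1] * pixel_nm

    row = np.sqrt(3) / 2 * d
    sites = []
    j = 0
    y0 = a / 2
    while y0 + j * row <= h_nm - a / 2:
        yrow = y0 + j * row
        x0 = a / 2 + (d / 2 if j % 2 else 0.0)
        xs = np.arange(x0, w_nm - a / 2 + 1e-9, d)
        sites.extend((x, yrow) for x in xs)
        j += 1
    sites = np.array(sites)

    pos = sites.copy()
    n_rejected = 0
    if jitter_nm > 0:
        trial = sites + rng.normal(0.0, jitter_nm, sites.shape)
        trial = np.clip(trial, a / 2, [w_nm - a / 2, h_nm - a / 2])
        budget = max_regen * len(sites)

        def overlapping(p):
            diff = p[:, None, :] - p[None, :, :]
            r2 = (diff**2).sum(-1)
            np.fill_diagonal(r2, np.inf)
            return np.where((r2 < (a * (1 - 1e-9)) ** 2).any(axis=1))[0]

        bad = overlapping(trial)
        while bad.size:
            n_rejected += bad.size
            if n_rejected > budget:
                raise ValueError(
                    f"jitter too large: {n_rejected} redraws exceeded the budget "
                    f"for {len(sites)} disks"
                )
            trial[bad] = sites[bad] + rng.normal(0.0, jitter_nm, (bad.size, 2))
            trial[bad] = np.clip(trial[bad], a / 2, [w_nm - a / 2, h_nm - a / 2])
            bad = overlapping(trial)
        pos = trial

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape, dtype=float)
    r_px = a / 2 / pixel_nm
    for x, y in pos:
        cx, cy = x / pixel_nm, y / pixel_nm
        ilo, ihi = int(max(cy - r_px - 2, 0)), int(min(cy + r_px + 3, shape[0]))
        jlo, jhi = int(max(cx - r_px - 2, 0)), int(min(cx + r_px + 3, shape[1]))
        rr = np.hypot(yy[ilo:ihi, jlo:jhi] - cy, xx[ilo:ihi, jlo:jhi] - cx)
        img[ilo:ihi, jlo:jhi] = np.maximum(img[ilo:ihi, jlo:jhi], np.clip(r_px + 0.5 - rr, 0, 1))

    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = ParticleEnsemble(positions=pos, radius=a / 2, box=(w_nm, h_nm))
    return img, truth, n_rejected
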