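"""1D transfer-matrix reflectance of layered effective-index stacks.

The hexagonal colony cross-section is approximated by a periodic
multilayer: each lattice row becomes a slab profile whose refractive
index is the row-resolved, area-weighted effective index of the disk
lattice.  The characteristic-matrix recursion then gives specular
reflectance and transmittance per wavelength, angle and polarization,
energy-conserving to machine precision for lossless stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultilayerStack",
    "ReflectanceSpectrum",
    "stack_from_lattice",
    "tmm_reflectance",
    "tilted_stack_response",
    "effective_index_profile",
]

_DEG = np.pi / 180.0


@dataclass
class MultilayerStack:
    """Ordered (index, thickness_nm) slabs between ambient and substrate,
    repeated ``repetitions`` times."""

    layers: list  # [(n, thickness_nm), ...] one period
    ambient_index: float = 1.0
    substrate_index: float = 1.34
    repetitions: int = 1

    def __post_init__(self) -> None:
        if any(t <= 0 for _, t in self.layers):
            raise ValueError("layer thicknesses must be positive")
        if any(n < 1 for n, _ in self.layers):
            raise ValueError("refractive indices must be >= 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @property
    def period_nm(self) -> float:
        return float(sum(t for _, t in self.layers))

    def expanded(self) -> list:
        return list(self.layers) * self.repetitions

    @property
    def mean_index(self) -> float:
        """Thickness-weighted RMS index of one period."""
        w = np.array([t for _, t in self.layers])
        n = np.array([n for n, _ in self.layers])
        return float(np.sqrt((w * n**2).sum() / w.sum()))


@dataclass
class ReflectanceSpectrum:
    wavelength: np.ndarray
    R: np.ndarray
    theta_in: float
    polarization: str
    T: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.R < -1e-12) or np.any(self.R > 1 + 1e-9):
            raise ValueError("reflectance must lie in [0, 1]")


def effective_index_profile(
    d: float, a: float, n_bac: float, n_env: float, direction: str, n_slabs: int
) -> tuple[np.ndarray, float]:
    """Row-resolved effective index across one stacking period.

    ``direction='GK'`` stacks the close-packed rows (period
    ``d * sqrt(3)/2``, disks spaced ``d`` within a row, adjacent rows
    offset by ``d/2``); ``'GM'`` stacks the 30-degree rotated rows (period
    ``d/2``, in-row spacing ``d * sqrt(3)``, offset by half).  Slab
    permittivity is the chord-length area fraction of the disks,
    volume-averaged with the surrounding matrix.
    """
    if direction == "GK":
        period, lateral = np.sqrt(3) / 2 * d, d
    elif direction == "GM":
        period, lateral = d / 2, np.sqrt(3) * d
    else:
        raise ValueError("direction must be 'GK' or 'GM'")

    edges = np.linspace(0, period, n_slabs + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    r = a / 2
    # rows at x = k * period contribute a chord 2*sqrt(r^2-u^2) per lateral cell
    f = np.zeros(n_slabs)
    for k in range(-2, 3):
        u = centers - k * period
        inside = np.abs(u) < r
        f[inside] += 2 * np.sqrt(r**2 - u[inside] ** 2) / lateral
    f = np.clip(f, 0.0, 1.0)
    n_eff = np.sqrt(f * n_bac**2 + (1 - f) * n_env**2)
    return n_eff, period


def stack_from_lattice(
    d: float = 395.0,
    a: float = 395.0,
    n_bac: float = 1.38,
    n_env: float = 1.34,
    direction: str = "GK",
    n_layers_per_period: int = 8,
    repetitions: int = 41,
    ambient_index: float = 1.0,
    substrate_index: float = 1.34,
) -> MultilayerStack:
    """Effective-medium multilayer for the disk lattice along GK or GM."""
    if a > d:
        raise ValueError("disk diameter a must not exceed d")
    if a == 0:
        n_eff = np.full(n_layers_per_period, n_env)
        period = (np.sqrt(3) / 2 if direction == "GK" else 0.5) * d
    else:
        n_eff, period = effective_index_profile(d, a, n_bac, n_env, direction, n_layers_per_period)
    dt = period / n_layers_per_period
    return MultilayerStack(
        layers=[(float(n), dt) for n in n_eff],
        ambient_index=ambient_index,
        substrate_index=substrate_index,
        repetitions=repetitions,
    )


def _char_matrix(n: np.ndarray, t: np.ndarray, lam: float, kx: float, pol: str):
    """Characteristic matrix product of the stack at one wavelength.

    ``kx`` is the conserved tangential wavevector (2 pi / lam * n0 sin
    theta); evanescent layers are handled through complex kz.
    """
    k0 = 2 * np.pi / lam
    kz = np.sqrt((k0 * n) ** 2 - kx**2 + 0j)
    if pol == "TE":
        eta = kz / k0
    else:  # TM
        eta = n**2 * k0 / kz
    delta = kz * t
    m = np.eye(2, dtype=complex)
    for dl, e in zip(delta, eta):
        c, s = np.cos(dl), np.sin(dl)
        m = m @ np.array([[c, 1j * s / e], [1j * e * s, c]])
    return m


def tmm_reflectance(
    stack: MultilayerStack,
    theta_in: float = 0.0,
    polarization: str = "TM",
    wavelengths: np.ndarray | None = None,
) -> ReflectanceSpectrum:
    """Specular reflectance/transmittance of the stack.

    Standard characteristic-matrix recursion (admittance form) per
    wavelength; ``R + T = 1`` for lossless stacks to machine precision.
    """
    if wavelengths is None:
        wavelengths = np.arange(300.0, 700.0 + 1e-9, 2.0)
    if polarization not in ("TE", "TM"):
        raise ValueError("polarization must be 'TE' or 'TM'")
    if abs(theta_in) >= 90:
        raise ValueError("evanescent ambient angle")
    layers = stack.expanded()
    n_arr = np.array([n for n, _ in layers])
    t_arr = np.array([t for _, t in layers])
    n0, ns = stack.ambient_index, stack.substrate_index

    R = np.empty_like(wavelengths, dtype=float)
    T = np.empty_like(wavelengths, dtype=float)
    s0 = np.sin(theta_in * _DEG)
    c0 = np.cos(theta_in * _DEG)
    for i, lam in enumerate(np.asarray(wavelengths, dtype=float)):
        k0 = 2 * np.pi / lam
        kx = k0 * n0 * s0
        kz_s = np.sqrt((k0 * ns) ** 2 - kx**2 + 0j)
        if polarization == "TE":
            eta0 = n0 * c0
            etas = kz_s / k0
        else:
            eta0 = n0 / c0
            etas = ns**2 * k0 / kz_s
        m = _char_matrix(n_arr, t_arr, lam, kx, polarization)
        b, c = m @ np.array([1.0, etas], dtype=complex)
        r = (eta0 * b - c) / (eta0 * b + c)
        R[i] = float(np.abs(r) ** 2)
        T[i] = float(4 * eta0 * np.real(etas) / np.abs(eta0 * b + c) ** 2)
    return ReflectanceSpectrum(np.asarray(wavelengths, float), R, theta_in, polarization, T)


def tilted_stack_response(
    stack: MultilayerStack,
    tilt: float,
    theta_in: np.ndarray,
    polarization: str = "TM",
    wavelengths: np.ndarray | None = None,
) -> list[ReflectanceSpectrum | None]:
    """Reflectance of a multilayer tilted by ``tilt`` degrees.

    Each incidence angle is evaluated at the effective incidence
    ``theta_in - tilt`` in the stack frame; grazing effective incidences
    are returned as None (marked missing).
    """
    out: list[ReflectanceSpectrum | None] = []
    for th in np.atleast_1d(theta_in):
        eff = th - tilt
        if abs(eff) >= 90:
            out.append(None)
            continue
        spec = tmm_reflectance(stack, eff, polarization, wavelengths)
        spec.theta_in = float(th)  # report in the lab frame
        out.append(spec)
    return out
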