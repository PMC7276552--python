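"""Core domain containers shared by every analysis stage.

Angle convention (used everywhere): angles are measured from the sample
normal.  The illumination arm sits on the negative side, so incidence
angles are signed and typically negative (``theta_in = -60`` pairs with
positive diffraction angles), while detector angles ``theta_out`` run over
[-90, 90].  Specular reflection satisfies ``theta_out = -theta_in``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AngleResolvedMap",
    "SpecularTrace",
    "ParticleEnsemble",
    "FormatError",
    "ValidationError",
]


class FormatError(ValueError):
    """Raised when an on-disk artefact violates its file format."""


class ValidationError(ValueError):
    """Raised when a container violates a physical invariant."""


def _strictly_increasing(x: np.ndarray) -> bool:
    return x.ndim == 1 and x.size > 0 and bool(np.all(np.diff(x) > 0))


@dataclass
class AngleResolvedMap:
    """Scattered intensity on a (theta_out, wavelength) grid for one incidence angle.

    ``intensity`` is a masked-by-NaN matrix of shape
    ``(len(theta_out), len(wavelength))``; cells inside the blind region
    (detector arm occluded by the source, ``|theta_out - theta_in| <=
    blind_halfwidth``) are NaN, never zero.
    """

    theta_in: float
    theta_out: np.ndarray
    wavelength: np.ndarray
    intensity: np.ndarray
    blind_halfwidth: float = 5.0

    def __post_init__(self) -> None:
        self.theta_out = np.asarray(self.theta_out, dtype=float)
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not _strictly_increasing(self.theta_out):
            raise FormatError("theta_out grid must be strictly increasing")
        if not _strictly_increasing(self.wavelength):
            raise FormatError("wavelength grid must be strictly increasing")
        if self.theta_out[0] < -90 or self.theta_out[-1] > 90:
            raise FormatError("theta_out grid must lie within [-90, 90]")
        if self.intensity.shape != (self.theta_out.size, self.wavelength.size):
            raise FormatError(
                f"intensity shape {self.intensity.shape} does not match grids "
                f"({self.theta_out.size}, {self.wavelength.size})"
            )
        if np.any(self.intensity[np.isfinite(self.intensity)] < 0):
            raise ValidationError("intensity must be nonnegative")

    @property
    def blind_mask(self) -> np.ndarray:
        """Boolean mask over theta_out: True inside the blind region."""
        return np.abs(self.theta_out - self.theta_in) <= self.blind_halfwidth

    def copy(self) -> "AngleResolvedMap":
        return AngleResolvedMap(
            self.theta_in,
            self.theta_out.copy(),
            self.wavelength.copy(),
            self.intensity.copy(),
            self.blind_halfwidth,
        )


@dataclass
class SpecularTrace:
    """Specular ridge wavelength lambda_s per incidence angle (mirror configuration)."""

    theta_in: np.ndarray
    lambda_s: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta_in = np.asarray(self.theta_in, dtype=float)
        self.lambda_s = np.asarray(self.lambda_s, dtype=float)
        if self.theta_in.shape != self.lambda_s.shape:
            raise FormatError("theta_in and lambda_s must have matching shapes")
        if not _strictly_increasing(self.theta_in):
            raise FormatError("theta_in grid must be strictly increasing")
        if self.intensity is None:
            self.intensity = np.ones_like(self.lambda_s)
        else:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if np.any(self.intensity < 0):
                raise ValidationError("intensity must be nonnegative")


@dataclass
class ParticleEnsemble:
    """Hard-disk cross-section model of the bacterial packing.

    ``positions`` holds disk centres (nm) inside ``box`` (nm); every disk
    has the same ``radius``.  ``periodic_y`` marks ensembles meant for the
    laterally periodic FDTD cell, in which case the hard-disk constraint is
    enforced with minimum-image distances along y.
    """

    positions: np.ndarray
    radius: float
    box: tuple[float, float]
    periodic_y: bool = False

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 2:
            raise FormatError("positions must be an (N, 2) array")
        if self.radius <= 0:
            raise ValidationError("radius must be positive")
        bx, by = self.box
        if np.any(self.positions[:, 0] < 0) or np.any(self.positions[:, 0] > bx) or np.any(
            self.positions[:, 1] < 0
        ) or np.any(self.positions[:, 1] > by):
            raise ValidationError("all centres must lie inside the box")
        self.validate_hard_disks()

    def __len__(self) -> int:
        return self.positions.shape[0]

    def pair_distances(self) -> np.ndarray:
        """Condensed pairwise centre distances (minimum image in y if periodic)."""
        p = self.positions
        d = p[:, None, :] - p[None, :, :]
        if self.periodic_y:
            by = self.box[1]
            d[..., 1] -= by * np.round(d[..., 1] / by)
        r = np.sqrt((d**2).sum(-1))
        iu = np.triu_indices(len(self), k=1)
        return r[iu]

    def validate_hard_disks(self, tol: float = 1e-9) -> None:
        """Raise unless all pairwise distances are >= 2*radius (touching allowed)."""
        n = len(self)
        if n < 2:
            return
        p = self.positions
        d = p[:, None, :] - p[None, :, :]
        if self.periodic_y:
            by = self.box[1]
            d[..., 1] -= by * np.round(d[..., 1] / by)
        r2 = (d**2).sum(-1)
        np.fill_diagonal(r2, np.inf)
        dmin2 = (2 * self.radius * (1 - tol)) ** 2
        bad = np.argwhere(r2 < dmin2)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"disks {i} and {j} overlap: centre distance "
                f"{np.sqrt(r2[i, j]):.3f} < diameter {2 * self.radius:.3f}"
            )


def as_float_array(x: Sequence[float] | np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=float)
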