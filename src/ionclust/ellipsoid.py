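"""Best-fitting ellipsoids of molecular ions and concentric ellipsoidal shells.

The reference ion's shape is summarised by the ellipsoid obtained from the
eigen-decomposition of the geometric (unweighted, population-normalised)
covariance matrix of its atomic coordinates; each eigenvalue lambda_i maps to
a semiaxis a_i = 2 * sqrt(lambda_i). Concentric shells grow the semiaxes
uniformly, a_i(n) = a_i + n * delta, with delta comparable to the size of one
solvent molecule, so successive shells probe successive solvation layers.

Degenerate ions (single atom, linear, planar) get their vanishing semiaxes
floored at a configurable value so the base ellipsoid always has positive
volume.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import Frame, SOLVENT_CODE, minimum_image

__all__ = [
    "Ellipsoid",
    "ShellSpec",
    "ShellOccupants",
    "fit_ellipsoid",
    "shell_semiaxes",
    "ellipsoid_contains",
    "shell_occupants",
    "shell_index_of_atoms",
    "resolve_n_max",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Centre (nm), orthonormal principal axes (columns) and descending semiaxes (nm)."""

    center: np.ndarray
    axes: np.ndarray  # (3, 3), column i is the direction of semiaxis i
    semiaxes: np.ndarray  # (3,), descending, floored

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        object.__setattr__(self, "axes", np.asarray(self.axes, float).reshape(3, 3))
        object.__setattr__(self, "semiaxes", np.asarray(self.semiaxes, float).reshape(3))


@dataclass(frozen=True)
class ShellSpec:
    """Geometry parameters of the shell scan.

    delta : shell increment in nm (0.4 by default, roughly one solvent molecule).
    contact_threshold : maximum nearest-atom distance (nm) for two ions to
        count as being in contact (0.3 by default).
    semiaxis_floor : lower bound (nm) applied to every fitted semiaxis.
    n_max : cap on the number of shells; ``None`` means auto,
        ceil((min box)/2 / delta), since shells beyond the half-box are not
        meaningful under the minimum-image convention.
    """

    delta: float = 0.4
    contact_threshold: float = 0.3
    semiaxis_floor: float = 0.1
    n_max: int | None = None

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.contact_threshold <= 0:
            raise ValueError(f"contact_threshold must be > 0, got {self.contact_threshold}")
        if self.n_max is not None and self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")


def resolve_n_max(spec: ShellSpec, box: np.ndarray) -> int:
    if spec.n_max is not None:
        return spec.n_max
    return max(1, math.ceil(float(np.min(box)) / 2.0 / spec.delta))


def fit_ellipsoid(coords, *, semiaxis_floor: float = 0.1) -> Ellipsoid:
    """Fit the best-fitting ellipsoid of a set of atomic coordinates.

    The covariance is the unweighted, centred second-moment matrix divided by
    the number of atoms (population normalisation, so a single atom yields
    zero and hence floor-sized semiaxes). Semiaxes are a_i = 2*sqrt(lambda_i),
    sorted descending and floored at ``semiaxis_floor``; axes columns follow
    the same order, each with its largest-magnitude component made positive.

    Coordinates must already be unwrapped (a contiguous molecule).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("fit_ellipsoid needs at least one coordinate")
    center = coords.mean(axis=0)
    dx = coords - center
    cov = dx.T @ dx / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for i in range(3):  # reproducible axis signs
        j = np.argmax(np.abs(evecs[:, i]))
        if evecs[j, i] < 0:
            evecs[:, i] = -evecs[:, i]
    semiaxes = np.maximum(2.0 * np.sqrt(evals), semiaxis_floor)
    return Ellipsoid(center=center, axes=evecs, semiaxes=semiaxes)


def shell_semiaxes(e: Ellipsoid, spec: ShellSpec, n: int) -> np.ndarray:
    """Semiaxes of shell boundary n: a_i + n * delta (n = 0 is the base ellipsoid)."""
    if n < 0:
        raise ValueError(f"shell index must be >= 0, got {n}")
    if spec.n_max is not None and n > spec.n_max:
        raise ValueError(f"shell index {n} exceeds n_max={spec.n_max}")
    return e.semiaxes + n * spec.delta


def ellipsoid_contains(e: Ellipsoid, semiaxes, point, box) -> bool:
    """Inclusive membership test under the minimum-image convention.

    The displacement point - center is wrapped into the primary image,
    rotated into the principal frame, and tested against
    sum_i (x_i / s_i)^2 <= 1 (boundary points count as inside).
    """
    s = np.asarray(semiaxes, dtype=float).reshape(3)
    if np.any(s <= 0):
        raise ValueError(f"semiaxes must be positive, got {s}")
    d = minimum_image(np.asarray(point, float).reshape(3) - e.center, box)
    y = d @ e.axes
    return bool(np.sum((y / s) ** 2) <= 1.0)


def shell_index_of_atoms(frame: Frame, e: Ellipsoid, spec: ShellSpec) -> tuple[np.ndarray, int]:
    """Shell index of every atom in ``frame`` relative to ellipsoid ``e``.

    Returns (idx, n_max) where idx[a] is the smallest n with atom a inside the
    boundary a(n) (boundary inclusive, so an atom on a boundary belongs to the
    inner shell), or n_max + 1 for atoms outside all shells. Shells therefore
    partition space: every atom has exactly one index.
    """
    n_max = resolve_n_max(spec, frame.box)
    d = minimum_image(frame.positions - e.center, frame.box)
    y = d @ e.axes  # principal-frame coordinates
    semis = e.semiaxes[None, :] + spec.delta * np.arange(n_max + 1)[:, None]
    q = ((y[None, :, :] / semis[:, None, :]) ** 2).sum(axis=-1)  # (n_max+1, n_atoms)
    inside = q <= 1.0
    idx = np.where(inside.any(axis=0), inside.argmax(axis=0), n_max + 1)
    return idx, n_max


@dataclass(frozen=True)
class ShellOccupants:
    """Atom indices inside one shell, grouped by role (reference ion excluded)."""

    ion_atoms: np.ndarray
    solvent_atoms: np.ndarray


def shell_occupants(
    e: Ellipsoid,
    spec: ShellSpec,
    n: int,
    frame: Frame,
    *,
    reference_molecule: int | None = None,
) -> ShellOccupants:
    """Atoms occupying shell ``n`` of ellipsoid ``e``, grouped into ion vs solvent.

    Shell n > 0 is the region inside boundary a(n) and outside a(n-1); shell 0
    is the base ellipsoid interior. Atoms of ``reference_molecule`` (normally
    the ion the ellipsoid was fitted to) are excluded.
    """
    if n < 0:
        raise ValueError(f"shell index must be >= 0, got {n}")
    idx, n_max = shell_index_of_atoms(frame, e, spec)
    if n > n_max:
        raise ValueError(f"shell index {n} exceeds n_max={n_max}")
    in_shell = idx == n
    if reference_molecule is not None:
        in_shell &= frame.molecule_ids != reference_molecule
    ions = np.flatnonzero(in_shell & (frame.roles != SOLVENT_CODE))
    solvent = np.flatnonzero(in_shell & (frame.roles == SOLVENT_CODE))
    return ShellOccupants(ion_atoms=ions, solvent_atoms=solvent)
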