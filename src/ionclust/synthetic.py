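"""Synthetic fixtures with exact ground truth.

Three generators cover the whole analysis chain:

* :func:`plant_frame` — a single frame containing molecular ions planted in
  clusters of prescribed sizes plus filler solvent. Ions are small rigid
  5-atom blobs; ions of one cluster form a contact chain (nearest-atom
  distance <= ``intra_contact``), distinct clusters are separated by at
  least ``inter_gap``, and solvent is kept outside a skin around every ion
  atom, with one solvent atom guaranteed on the closest-approach segment of
  every cluster pair. With gap >> contact threshold the planted partition is
  the unique answer both for the shell-expansion detector and for the
  contact-graph oracle.
* :func:`plant_series` — a state-vector time series built from a base
  composition plus planted orthogonal fluctuation modes (all orthogonal to
  the all-ones vector, so the populations stay normalised) and optional
  isotropic in-simplex noise; the analytic covariance is returned alongside
  for recovery tests.
* :func:`toy_trajectory` — a Markov chain over cluster-size partitions
  (single-ion detach/join moves at a given hop rate), re-planted
  geometrically every frame, exercising detection -> populations -> PCA end
  to end with known answers.

Every generated frame validates its own ground truth by direct distance
computation before being returned, and generation is bit-reproducible for a
given spec and seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cluster import ClusterPartition, _make_cluster
from .errors import GenerationError
from .populations import StateVector
from .trajectory_io import Frame, ROLE_CODE, Role, minimum_image, pairwise_min_image_dists

__all__ = [
    "PlantedSpec",
    "SeriesSpec",
    "plant_frame",
    "plant_series",
    "toy_trajectory",
    "ION_TEMPLATE",
]

# rigid ion blob, nm; first two entries are the chain-axis extremes
ION_TEMPLATE = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.1, 0.0, 0.0],
        [-0.1, 0.0, 0.0],
        [0.0, 0.1, 0.0],
        [0.0, 0.0, 0.1],
        [0.0, -0.1, 0.0],
        [0.0, 0.0, -0.1],
        [0.07, 0.07, 0.0],
    ]
)


@dataclass(frozen=True)
class PlantedSpec:
    """Recipe for one planted-cluster frame.

    Defaults mirror the simulated salt systems: 22 cations + 22 anions.
    ``box=None`` sizes the box automatically from the number of clusters and
    the separation constraint.
    """

    sizes: tuple[int, ...]
    n_cations: int = 22
    n_anions: int = 22
    atoms_per_ion: int = 5
    intra_contact: float = 0.25
    inter_gap: float = 1.2
    solvent_density: float = 0.5  # atoms per nm^3
    solvent_skin: float = 0.35
    box: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        if any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be >= 1")
        if sum(self.sizes) != self.n_cations + self.n_anions:
            raise ValueError(
                f"sum of sizes {sum(self.sizes)} != "
                f"n_cations + n_anions = {self.n_cations + self.n_anions}"
            )
        if not 1 <= self.atoms_per_ion <= ION_TEMPLATE.shape[0]:
            raise ValueError(
                f"atoms_per_ion must be 1..{ION_TEMPLATE.shape[0]}"
            )
        if self.intra_contact <= 0 or self.inter_gap <= 0:
            raise ValueError("contact and gap distances must be positive")

    @property
    def n_ions(self) -> int:
        return self.n_cations + self.n_anions


def _template(spec: PlantedSpec) -> np.ndarray:
    return ION_TEMPLATE[: spec.atoms_per_ion]


def _chain_geometry(spec: PlantedSpec) -> tuple[float, float, float]:
    """(extent towards +axis, extent towards -axis, centre spacing) of the chain."""
    t = _template(spec)
    ext_plus = float(t[:, 0].max())
    ext_minus = float(-t[:, 0].min())
    gap = 0.88 * spec.intra_contact  # nearest-atom distance between neighbours
    spacing = ext_plus + ext_minus + gap
    return ext_plus, ext_minus, spacing


def _cluster_radius(spec: PlantedSpec, size: int) -> float:
    """Circumscribing radius of a planted chain of ``size`` ions."""
    t = _template(spec)
    blob_r = float(np.linalg.norm(t, axis=1).max())
    _, _, spacing = _chain_geometry(spec)
    return 0.5 * spacing * (size - 1) + blob_r


def _rotation_onto(direction: np.ndarray, roll: float) -> np.ndarray:
    """Rotation taking x-hat to ``direction`` with a roll about it."""
    e = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0]) if abs(e[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(e, ref)
    u /= np.linalg.norm(u)
    v = np.cross(e, u)
    cu, su = math.cos(roll), math.sin(roll)
    return np.column_stack([e, cu * u + su * v, -su * u + cu * v])


def _assign_roles(groups: list[list[int]], n_cations: int, n_anions: int) -> dict[int, Role]:
    """Alternate cation/anion along each chain while honouring the exact totals."""
    remaining = {Role.CATION: n_cations, Role.ANION: n_anions}
    roles: dict[int, Role] = {}
    for group in groups:
        prev: Role | None = None
        for ion in group:
            if prev is None:
                pick = Role.CATION if remaining[Role.CATION] >= remaining[Role.ANION] else Role.ANION
            else:
                pick = Role.ANION if prev is Role.CATION else Role.CATION
            if remaining[pick] == 0:
                pick = Role.ANION if pick is Role.CATION else Role.CATION
            if remaining[pick] == 0:
                raise GenerationError("role totals inconsistent with ion count")
            roles[ion] = pick
            remaining[pick] -= 1
            prev = pick
    return roles


def _place_seeds(spec: PlantedSpec, n_clusters: int, max_radius: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    """Seed centres on a jittered periodic grid; returns (centres, box, jitter)."""
    spacing_min = spec.inter_gap + 2.0 * max_radius + 0.05
    if spec.box is None:
        k = max(1, math.ceil(n_clusters ** (1.0 / 3.0)))
        while k ** 3 < n_clusters:
            k += 1
        edge = k * spacing_min
        box = np.array([edge, edge, edge])
    else:
        box = np.asarray(spec.box, dtype=float)
        k = int(np.floor(np.min(box) / spacing_min))
        if k ** 3 < n_clusters:
            raise GenerationError(
                f"box {box} too small for {n_clusters} clusters needing "
                f">= {spacing_min:.2f} nm centre separation "
                f"(inter_gap={spec.inter_gap}, cluster radius {max_radius:.2f})"
            )
    cell = box / k
    jitter = 0.45 * (float(np.min(cell)) - spacing_min)
    jitter = max(0.0, jitter)
    cells = rng.choice(k ** 3, size=n_clusters, replace=False)
    centers = np.empty((n_clusters, 3))
    for i, c in enumerate(cells):
        ijk = np.array([c // (k * k), (c // k) % k, c % k], dtype=float)
        centers[i] = (ijk + 0.5) * cell + rng.uniform(-jitter, jitter, size=3)
    return centers, box, jitter


def _plant_geometry(groups: list[list[int]], roles: dict[int, Role],
                    spec: PlantedSpec, rng: np.random.Generator,
                    n_solvent: int | None = None):
    """Build (Frame, ClusterPartition) for explicit ion groups.

    ``n_solvent`` forces an exact solvent atom count (used by trajectories,
    where the composition must not drift between frames).
    """
    t = _template(spec)
    n_ions = sum(len(g) for g in groups)
    max_r = max(_cluster_radius(spec, len(g)) for g in groups)
    centers, box, _ = _place_seeds(spec, len(groups), max_r, rng)
    _, _, spacing = _chain_geometry(spec)

    pos_by_ion: dict[int, np.ndarray] = {}
    for g, center in zip(groups, centers):
        direction = rng.normal(size=3)
        while np.linalg.norm(direction) < 1e-8:  # pragma: no cover
            direction = rng.normal(size=3)
        R = _rotation_onto(direction, rng.uniform(0, 2 * math.pi))
        half = 0.5 * spacing * (len(g) - 1)
        for j, ion in enumerate(g):
            c = center + R[:, 0] * (j * spacing - half)
            pos_by_ion[ion] = c + t @ R.T

    ion_ids = sorted(pos_by_ion)
    positions = np.concatenate([pos_by_ion[i] for i in ion_ids])
    mol_ids = np.concatenate([[i] * t.shape[0] for i in ion_ids]).astype(int)
    codes = np.concatenate(
        [[ROLE_CODE[roles[i]]] * t.shape[0] for i in ion_ids]
    ).astype(int)
    names = []
    for i in ion_ids:
        names.extend(f"C{a + 1}" if roles[i] is Role.CATION else f"S{a + 1}"
                     for a in range(t.shape[0]))

    solvent = _place_solvent(positions, centers, groups, pos_by_ion, box, spec, rng,
                             n_solvent)
    if solvent.shape[0]:
        positions = np.concatenate([positions, solvent])
        start = n_ions + 1
        mol_ids = np.concatenate(
            [mol_ids, np.arange(start, start + solvent.shape[0])]
        )
        codes = np.concatenate(
            [codes, np.full(solvent.shape[0], ROLE_CODE[Role.SOLVENT])]
        )
        names.extend("OW" for _ in range(solvent.shape[0]))

    frame = Frame(positions, mol_ids, codes, box, names=names)
    clusters = [_make_cluster(frame, g) for g in groups]
    partition = ClusterPartition(frame_index=0, clusters=clusters)
    _validate_plant(frame, groups, pos_by_ion, spec)
    return frame, partition


def _place_solvent(ion_pos, centers, groups, pos_by_ion, box, spec, rng,
                   n_solvent: int | None = None):
    points: list[np.ndarray] = []
    if spec.solvent_density > 0 or (n_solvent or 0) > 0:
        # guaranteed obstruction between every pair of clusters: one solvent
        # atom at the midpoint of the closest approach (when outside every skin)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pi = np.concatenate([pos_by_ion[m] for m in groups[i]])
                pj = np.concatenate([pos_by_ion[m] for m in groups[j]])
                D = pairwise_min_image_dists(pi, pj, box)
                a, b = np.unravel_index(np.argmin(D), D.shape)
                q = pi[a] + minimum_image(pj[b] - pi[a], box)
                mid = 0.5 * (pi[a] + q)
                if pairwise_min_image_dists(mid[None, :], ion_pos, box).min() > spec.solvent_skin:
                    points.append(mid)
    n_target = int(round(spec.solvent_density * float(np.prod(box))))
    if n_solvent is not None:
        if len(points) > n_solvent:
            raise GenerationError(
                f"solvent budget {n_solvent} below the {len(points)} obstruction "
                "atoms required between cluster pairs"
            )
        n_target = n_solvent
    attempts = 0
    while len(points) < n_target and attempts < 50 * max(1, n_target):
        attempts += 1
        p = rng.uniform(0, 1, size=3) * box
        if pairwise_min_image_dists(p[None, :], ion_pos, box).min() > spec.solvent_skin:
            points.append(p)
    if len(points) < n_target:
        raise GenerationError(
            f"could not place {n_target} solvent atoms outside the "
            f"{spec.solvent_skin} nm skin after {attempts} attempts"
        )
    return np.array(points).reshape(-1, 3)


def _validate_plant(frame: Frame, groups, pos_by_ion, spec: PlantedSpec) -> None:
    """Verify the emitted geometry honours the planted constraints."""
    box = frame.box
    for g in groups:
        for a, b in zip(g[:-1], g[1:]):
            d = pairwise_min_image_dists(pos_by_ion[a], pos_by_ion[b], box).min()
            if d > spec.intra_contact + 1e-9:
                raise GenerationError(
                    f"chain contact {a}-{b} is {d:.3f} nm > intra_contact"
                )
    for i in range(len(groups)):
        pi = np.concatenate([pos_by_ion[m] for m in groups[i]])
        for j in range(i + 1, len(groups)):
            pj = np.concatenate([pos_by_ion[m] for m in groups[j]])
            d = pairwise_min_image_dists(pi, pj, box).min()
            if d < spec.inter_gap - 1e-9:
                raise GenerationError(
                    f"clusters {i} and {j} are {d:.3f} nm apart < inter_gap"
                )
    solv = frame.positions[frame.roles == ROLE_CODE[Role.SOLVENT]]
    ions = frame.positions[frame.roles != ROLE_CODE[Role.SOLVENT]]
    if solv.shape[0]:
        d = pairwise_min_image_dists(solv, ions, box).min()
        if d < spec.solvent_skin - 1e-9:
            raise GenerationError(f"solvent atom inside the {spec.solvent_skin} nm skin")


def plant_frame(spec: PlantedSpec) -> tuple[Frame, ClusterPartition]:
    """Generate one frame with a planted ground-truth cluster partition."""
    rng = np.random.default_rng(spec.seed)
    groups: list[list[int]] = []
    next_id = 1
    for s in spec.sizes:
        groups.append(list(range(next_id, next_id + s)))
        next_id += s
    roles = _assign_roles(groups, spec.n_cations, spec.n_anions)
    return _plant_geometry(groups, roles, spec, rng)


# ---------------------------------------------------------------------------
# population time series with planted covariance


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for a state-vector series with known covariance.

    ``modes`` are fluctuation directions (each orthogonal to the all-ones
    vector so the normalisation survives; normalised internally); ``base``
    must sum to 1. Isotropic noise is projected into the zero-sum subspace.
    Frames whose perturbed components would go negative are resampled, which
    with the small default amplitudes essentially never triggers.
    """

    n_frames: int
    s_max: int = 4
    base: tuple[float, ...] = (0.5, 0.3, 0.12, 0.08)
    modes: tuple[tuple[float, ...], ...] = ()
    amplitudes: tuple[float, ...] = ()
    noise: float = 0.0
    seed: int = 0
    max_resamples: int = 1000

    def __post_init__(self):
        base = np.asarray(self.base, dtype=float)
        if base.shape != (self.s_max,):
            raise ValueError(f"base must have length s_max={self.s_max}")
        if abs(base.sum() - 1.0) > 1e-10:
            raise ValueError(f"base must sum to 1, sums to {base.sum()}")
        if len(self.modes) != len(self.amplitudes):
            raise ValueError("modes and amplitudes must pair up")
        for m in self.modes:
            v = np.asarray(m, dtype=float)
            if v.shape != (self.s_max,):
                raise ValueError("every mode must have length s_max")
            if abs(v.sum()) > 1e-8 * max(1.0, np.linalg.norm(v)):
                raise ValueError(
                    "modes must be orthogonal to the all-ones vector "
                    "(they would break the population normalisation)"
                )


def plant_series(spec: SeriesSpec) -> tuple[list[StateVector], np.ndarray]:
    """Generate the series and return it with its analytic covariance."""
    rng = np.random.default_rng(spec.seed)
    base = np.asarray(spec.base, dtype=float)
    S = spec.s_max
    M = np.array([np.asarray(m, float) / np.linalg.norm(m) for m in spec.modes]).reshape(
        len(spec.modes), S
    )
    amps = np.asarray(spec.amplitudes, dtype=float)
    P = np.eye(S) - np.ones((S, S)) / S  # projector onto the zero-sum subspace

    true_cov = np.zeros((S, S))
    for a, m in zip(amps, M):
        true_cov += a * a * np.outer(m, m)
    true_cov += spec.noise ** 2 * P

    out: list[StateVector] = []
    for k in range(spec.n_frames):
        for attempt in range(spec.max_resamples):
            v = base.copy()
            if len(amps):
                v = v + (rng.normal(size=len(amps)) * amps) @ M
            if spec.noise > 0:
                v = v + spec.noise * (P @ rng.normal(size=S))
            if np.all(v >= 0):
                break
        else:
            raise GenerationError(
                f"frame {k}: could not draw non-negative populations in "
                f"{spec.max_resamples} attempts; reduce amplitudes or noise"
            )
        out.append(StateVector(frame_index=k, components=v))
    return out, true_cov


# ---------------------------------------------------------------------------
# toy trajectory: Markov re-planting of evolving partitions


def _feasible_moves(groups: list[list[int]], size_cap: int):
    moves = []
    for gi, g in enumerate(groups):
        if len(g) >= 2:
            moves.append(("split", gi))
    monomers = [gi for gi, g in enumerate(groups) if len(g) == 1]
    for gi in monomers:
        for gj, g in enumerate(groups):
            if gj != gi and len(g) < size_cap:
                moves.append(("join", gi, gj))
    return moves


def toy_trajectory(
    spec: PlantedSpec,
    n_frames: int,
    hop_rate: float,
    seed: int,
    *,
    size_cap: int = 4,
) -> tuple[list[Frame], list[ClusterPartition]]:
    """Frames of an evolving cluster population with exact per-frame truth.

    At each step, with probability ``hop_rate`` one randomly chosen feasible
    move is applied: an end ion detaches from a multi-ion cluster, or a free
    monomer joins another cluster (capped at ``size_cap``). The geometry is
    re-planted every frame, so consecutive frames share the partition
    topology, not atomic positions — this emulates interconversion of the
    populations, which is all the downstream statistics consume.
    """
    if not 0.0 <= hop_rate <= 1.0:
        raise ValueError(f"hop_rate must be in [0, 1], got {hop_rate}")
    rng = np.random.default_rng(seed)
    groups: list[list[int]] = []
    next_id = 1
    for s in spec.sizes:
        groups.append(list(range(next_id, next_id + s)))
        next_id += s
    roles = _assign_roles(groups, spec.n_cations, spec.n_anions)

    # freeze box and solvent count for the whole trajectory: size the box for
    # the worst case (every ion free), budget enough solvent for the largest
    # possible number of obstruction midpoints
    if spec.box is None:
        worst_spacing = spec.inter_gap + 2.0 * _cluster_radius(spec, size_cap) + 0.05
        k_cells = 1
        while k_cells ** 3 < spec.n_ions:
            k_cells += 1
        edge = k_cells * worst_spacing
        spec = replace(spec, box=(edge, edge, edge))
    n_solvent = None
    if spec.solvent_density > 0:
        n_solvent = max(
            int(round(spec.solvent_density * float(np.prod(spec.box)))),
            spec.n_ions * (spec.n_ions - 1) // 2,
        )

    frames: list[Frame] = []
    truths: list[ClusterPartition] = []
    for k in range(n_frames):
        geo_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        frame, part = _plant_geometry([list(g) for g in groups], roles, spec, geo_rng,
                                      n_solvent=n_solvent)
        part = ClusterPartition(frame_index=k, clusters=part.clusters)
        frames.append(frame)
        truths.append(part)
        if rng.random() < hop_rate:
            moves = _feasible_moves(groups, size_cap)
            if moves:
                mv = moves[rng.integers(0, len(moves))]
                if mv[0] == "split":
                    g = groups[mv[1]]
                    groups.append([g.pop()])  # detach the chain-end ion
                else:
                    _, gi, gj = mv
                    groups[gj].append(groups[gi][0])
                    groups.pop(gi)
                groups = [g for g in groups if g]
    return frames, truths
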