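"""Frame-wise detection of transient ionic clusters by iterative shell expansion.

Around a reference ion, concentric ellipsoidal shells are scanned outwards.
Any non-assigned ion with an atom in the current shell is a candidate; it is
accepted into the cluster when its nearest-atom distance to any atom of the
already-accepted members (reference included) does not exceed the contact
threshold (0.3 nm by default). The scan stops when a shell holds no ion atoms
beyond the reference's own (solvent-only or empty, condition a), or holds ion
atoms but accepts no new candidate (condition b), or the shell cap is hit.
Repeating the procedure over reference ions, skipping those already assigned,
partitions every ion of the frame into exactly one cluster.

A brute-force contact-graph oracle (single-linkage over the nearest-atom
distance with an explicit solvent-obstruction test on the closest-approach
segment) is provided for testing; it shares no code path with the shell scan.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .ellipsoid import ShellSpec, fit_ellipsoid, resolve_n_max, shell_index_of_atoms
from .errors import IntegrityError
from .trajectory_io import Frame, SOLVENT_CODE, minimum_image, pairwise_min_image_dists

__all__ = [
    "Cluster",
    "ClusterPartition",
    "grow_cluster",
    "partition_frame",
    "contact_graph_oracle",
    "random_order",
]


@dataclass(frozen=True)
class Cluster:
    """A set of ion molecules detected as one transient cluster."""

    member_ids: frozenset[int]
    n_cations: int
    n_anions: int

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def charge_composition(self) -> tuple[int, int]:
        """(number of cations, number of anions)."""
        return (self.n_cations, self.n_anions)

    def __post_init__(self):
        if self.size < 1:
            raise IntegrityError("a cluster must have at least one member")
        if self.n_cations + self.n_anions != self.size:
            raise IntegrityError(
                f"charge composition {self.n_cations}+{self.n_anions} "
                f"does not match size {self.size}"
            )


@dataclass
class ClusterPartition:
    """Disjoint assignment of all ion molecules of one frame to clusters."""

    frame_index: int
    clusters: list[Cluster]

    def __post_init__(self):
        seen: set[int] = set()
        for c in self.clusters:
            overlap = seen & c.member_ids
            if overlap:
                raise IntegrityError(f"ions {sorted(overlap)} appear in two clusters")
            seen |= c.member_ids

    @property
    def n_ions(self) -> int:
        return sum(c.size for c in self.clusters)

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def size_counts(self) -> Counter:
        """Multiset of cluster sizes: size -> number of clusters."""
        return Counter(c.size for c in self.clusters)

    def cluster_of(self, molecule_id: int) -> Cluster:
        for c in self.clusters:
            if molecule_id in c.member_ids:
                return c
        raise LookupError(f"ion {molecule_id} not in partition")


def _make_cluster(frame: Frame, member_ids) -> Cluster:
    n_cat = n_an = 0
    for m in member_ids:
        code = int(frame.roles[frame.molecule_ids == m][0])
        if code == 0:
            n_cat += 1
        elif code == 1:
            n_an += 1
        else:
            raise ValueError(f"molecule {m} is solvent, cannot join a cluster")
    return Cluster(member_ids=frozenset(int(m) for m in member_ids),
                   n_cations=n_cat, n_anions=n_an)


def grow_cluster(
    reference_id: int,
    frame: Frame,
    spec: ShellSpec = ShellSpec(),
    excluded: frozenset[int] | set[int] = frozenset(),
) -> Cluster:
    """Grow the cluster of ``reference_id`` by iterative shell expansion.

    ``excluded`` holds ions already assigned to earlier clusters; their atoms
    still count as ion atoms for the termination logic but they can never be
    accepted again.
    """
    ref_mask = frame.molecule_ids == reference_id
    if not ref_mask.any():
        raise ValueError(f"unknown molecule id {reference_id}")
    if int(frame.roles[ref_mask][0]) == SOLVENT_CODE:
        raise ValueError(f"molecule {reference_id} is solvent, not an ion")
    if reference_id in excluded:
        raise ValueError(f"reference ion {reference_id} is already assigned")

    ell = fit_ellipsoid(frame.positions[ref_mask], semiaxis_floor=spec.semiaxis_floor)
    shell_idx, n_max = shell_index_of_atoms(frame, ell, spec)

    ion_atom = frame.roles != SOLVENT_CODE
    member_mask = ref_mask.copy()
    members = [int(reference_id)]
    # ions eligible for acceptance: not solvent, not excluded, not yet a member
    eligible = {
        int(m)
        for m in np.unique(frame.molecule_ids[ion_atom])
        if int(m) not in excluded and int(m) != reference_id
    }

    for n in range(n_max + 1):
        occ = (shell_idx == n) & ~ref_mask
        ion_occ = occ & ion_atom
        # candidates nominated by any atom in this shell
        candidates = sorted(
            {int(m) for m in np.unique(frame.molecule_ids[ion_occ])} & eligible
        )
        accepted_any = False
        changed = True
        while changed and candidates:  # chase within-shell contact chains
            changed = False
            member_pos = frame.positions[member_mask]
            for m in list(candidates):
                cand_pos = frame.positions[frame.molecule_ids == m]
                dmin = pairwise_min_image_dists(cand_pos, member_pos, frame.box).min()
                if dmin <= spec.contact_threshold:
                    members.append(m)
                    member_mask |= frame.molecule_ids == m
                    eligible.discard(m)
                    candidates.remove(m)
                    accepted_any = True
                    changed = True
        if n == 0:
            continue  # the base ellipsoid is the reference's own region
        if not ion_occ.any():
            break  # (a) shell holds solvent only (or nothing): the cluster is bounded
        if not accepted_any and (ion_occ & ~member_mask).any():
            break  # (b) foreign ion atoms present but none in contact
        # otherwise the shell holds member atoms (or just-accepted ions): keep scanning
    return _make_cluster(frame, members)


def partition_frame(
    frame: Frame,
    spec: ShellSpec = ShellSpec(),
    order=None,
    *,
    frame_index: int = 0,
) -> ClusterPartition:
    """Partition every ion of ``frame`` into clusters.

    ``order`` is the sequence of reference ions to try (default: ascending
    molecule id); ions already swallowed by an earlier cluster are skipped.
    The resulting size distribution is insensitive to this order for
    well-separated clusters, which is asserted in the test suite.
    """
    ion_ids = [int(m) for m in frame.ion_molecule_ids]
    if not ion_ids:
        raise ValueError("frame contains no ion molecules")
    if order is None:
        order = ion_ids
    else:
        order = [int(m) for m in order]
        if set(order) != set(ion_ids):
            raise ValueError("order must be a permutation of the frame's ion ids")
    assigned: set[int] = set()
    clusters: list[Cluster] = []
    for ref in order:
        if ref in assigned:
            continue
        c = grow_cluster(ref, frame, spec, excluded=frozenset(assigned))
        clusters.append(c)
        assigned |= c.member_ids
    part = ClusterPartition(frame_index=frame_index, clusters=clusters)
    if part.n_ions != len(ion_ids):
        raise IntegrityError(
            f"partition covers {part.n_ions} ions, frame has {len(ion_ids)}"
        )
    return part


def random_order(frame: Frame, seed: int) -> list[int]:
    """A seeded random permutation of the frame's ion molecule ids."""
    rng = np.random.default_rng(seed)
    ids = [int(m) for m in frame.ion_molecule_ids]
    return [ids[i] for i in rng.permutation(len(ids))]


def _segment_blocked(p, q, solvent_pos, box, blocking_radius: float) -> bool:
    """True if any solvent atom lies within blocking_radius of segment p-q.

    q must already be the minimum image of its atom relative to p. Solvent
    atoms are wrapped relative to the segment midpoint before the test.
    """
    if solvent_pos.shape[0] == 0:
        return False
    mid = 0.5 * (p + q)
    s = mid + minimum_image(solvent_pos - mid, box)
    seg = q - p
    L2 = float(seg @ seg)
    if L2 == 0.0:
        d = np.linalg.norm(s - p, axis=1)
    else:
        t = np.clip((s - p) @ seg / L2, 0.0, 1.0)
        d = np.linalg.norm(s - (p + t[:, None] * seg), axis=1)
    return bool(np.any(d <= blocking_radius))


def contact_graph_oracle(
    frame: Frame,
    contact_threshold: float = 0.3,
    blocking_radius: float = 0.15,
    *,
    frame_index: int = 0,
) -> ClusterPartition:
    """Brute-force reference partition, independent of the shell scan.

    Two ions are joined by an edge when their nearest-atom minimum-image
    distance is <= ``contact_threshold`` and no solvent atom lies within
    ``blocking_radius`` of the segment between the two closest atoms;
    clusters are the connected components. Intended for tests.
    """
    ion_ids = [int(m) for m in frame.ion_molecule_ids]
    n = len(ion_ids)
    solvent_pos = frame.positions[frame.roles == SOLVENT_CODE]
    atom_pos = [frame.positions[frame.molecule_ids == m] for m in ion_ids]
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            D = pairwise_min_image_dists(atom_pos[i], atom_pos[j], frame.box)
            a, b = np.unravel_index(np.argmin(D), D.shape)
            if D[a, b] > contact_threshold:
                continue
            p = atom_pos[i][a]
            q = p + minimum_image(atom_pos[j][b] - p, frame.box)
            if _segment_blocked(p, q, solvent_pos, frame.box, blocking_radius):
                continue
            rows.append(i)
            cols.append(j)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters = []
    for k in range(n_comp):
        members = [ion_ids[i] for i in np.flatnonzero(labels == k)]
        clusters.append(_make_cluster(frame, members))
    return ClusterPartition(frame_index=frame_index, clusters=clusters)
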