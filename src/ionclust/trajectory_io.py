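"""Reading and writing coordinate frames with molecule roles.

A :class:`Frame` holds one MD snapshot as flat numpy arrays (positions in nm,
per-atom molecule id and role) plus the orthorhombic box. Roles distinguish
cation / anion / solvent and normally come from a separate role-map file
(CSV or YAML) rather than from residue names, which are unreliable across
tools.

Supported formats:

* GRO — read through MDAnalysis; concatenated multi-frame GRO files are
  split on the atom-count header and each block parsed individually.
  Written natively (fixed-column, positions in nm at 1e-3 precision).
* PDB — read through MDAnalysis (ATOM/HETATM, CRYST1 box, MODEL/ENDMDL for
  multiple frames); Angstrom converted to nm on read.
* Extended-XYZ internal dialect — comment line carries ``box="lx ly lz"``
  (and optionally ``time=...``); per-atom columns are
  ``element x y z molecule_id role``. Both directions native.

All geometry downstream assumes orthorhombic boxes; triclinic input is
rejected. Molecules are made whole (unwrapped across periodic faces) once
per frame on read.
"""
from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, RoleMapError, StructureError

__all__ = [
    "Role",
    "AtomRecord",
    "Frame",
    "RoleMap",
    "read_frames",
    "write_frames",
    "write_gro",
    "write_xyz",
    "write_role_map",
    "load_role_map",
    "minimum_image",
    "molecule_atoms",
    "make_whole",
]

_ANGLE_TOL = 1e-3  # degrees away from 90 tolerated before a box counts as triclinic


class Role(str, Enum):
    CATION = "cation"
    ANION = "anion"
    SOLVENT = "solvent"


ROLE_CODE = {Role.CATION: 0, Role.ANION: 1, Role.SOLVENT: 2}
CODE_ROLE = {v: k for k, v in ROLE_CODE.items()}
SOLVENT_CODE = ROLE_CODE[Role.SOLVENT]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: index in file order (0-based), owning molecule, role, position in nm."""

    atom_id: int
    molecule_id: int
    role: Role
    position: np.ndarray


@dataclass
class Frame:
    """One snapshot: positions (nm), per-atom molecule ids and role codes, box (nm).

    ``roles`` stores the integer codes from :data:`ROLE_CODE`; use
    :meth:`role_of` for the enum view. ``names`` (optional) preserves atom
    names for writers.
    """

    positions: np.ndarray
    molecule_ids: np.ndarray
    roles: np.ndarray
    box: np.ndarray
    time: float | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int).reshape(-1)
        self.roles = np.asarray(self.roles, dtype=int).reshape(-1)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        n = self.positions.shape[0]
        if self.molecule_ids.shape[0] != n or self.roles.shape[0] != n:
            raise StructureError(
                f"inconsistent per-atom arrays: {n} positions, "
                f"{self.molecule_ids.shape[0]} molecule ids, {self.roles.shape[0]} roles"
            )
        if not np.all(np.isfinite(self.positions)):
            raise StructureError("non-finite coordinates in frame")
        if np.any(self.box <= 0):
            raise StructureError(f"box lengths must be positive, got {self.box}")
        # all atoms of one molecule must share a role
        for mol in np.unique(self.molecule_ids):
            r = np.unique(self.roles[self.molecule_ids == mol])
            if r.size != 1:
                raise RoleMapError(f"molecule {mol} carries {r.size} distinct roles")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def is_ion(self) -> np.ndarray:
        return self.roles != SOLVENT_CODE

    @property
    def ion_molecule_ids(self) -> np.ndarray:
        """Sorted unique molecule ids of cations and anions."""
        return np.unique(self.molecule_ids[self.is_ion])

    def role_of(self, molecule_id: int) -> Role:
        mask = self.molecule_ids == molecule_id
        if not mask.any():
            raise LookupError(f"unknown molecule id {molecule_id}")
        return CODE_ROLE[int(self.roles[mask][0])]

    def molecule_mask(self, molecule_id: int) -> np.ndarray:
        return self.molecule_ids == molecule_id


def minimum_image(delta, box):
    """Wrap displacement vector(s) into the primary image of an orthorhombic box.

    Each component of the result lies in [-box/2, box/2). Broadcasts over
    leading axes of ``delta``.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.floor(delta / box + 0.5)


def pairwise_min_image_dists(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(n, m) matrix of minimum-image distances between two point sets (nm)."""
    d = minimum_image(a[:, None, :] - b[None, :, :], box)
    return np.sqrt((d * d).sum(axis=-1))


def make_whole(frame: Frame) -> Frame:
    """Return a copy of ``frame`` with every molecule contiguous.

    Atoms are unwrapped to the periodic image nearest the molecule's first
    atom; valid for molecules smaller than half the box in every dimension,
    which holds for the molecular ions and single-atom solvent handled here.
    """
    pos = frame.positions.copy()
    for mol in np.unique(frame.molecule_ids):
        idx = np.flatnonzero(frame.molecule_ids == mol)
        if idx.size < 2:
            continue
        anchor = pos[idx[0]]
        pos[idx] = anchor + minimum_image(pos[idx] - anchor, frame.box)
    return replace(frame, positions=pos)


def molecule_atoms(frame: Frame, molecule_id: int) -> list[AtomRecord]:
    """All atoms of one molecule, unwrapped to be mutually contiguous."""
    idx = np.flatnonzero(frame.molecule_ids == molecule_id)
    if idx.size == 0:
        raise LookupError(f"unknown molecule id {molecule_id}")
    pos = frame.positions[idx]
    anchor = pos[0]
    pos = anchor + minimum_image(pos - anchor, frame.box)
    role = CODE_ROLE[int(frame.roles[idx[0]])]
    return [
        AtomRecord(atom_id=int(i), molecule_id=int(molecule_id), role=role, position=p)
        for i, p in zip(idx, pos)
    ]


# ---------------------------------------------------------------------------
# role maps


@dataclass(frozen=True)
class RoleMap:
    """Mapping from molecules (or individual atoms) to roles.

    ``by_molecule`` maps molecule_id -> Role. ``by_atom`` (optional) maps
    1-based file-order atom index -> (molecule_id, Role) and, when present,
    overrides molecule ids found in the coordinate file.
    """

    by_molecule: dict[int, Role] = field(default_factory=dict)
    by_atom: dict[int, tuple[int, Role]] | None = None

    def role_for(self, atom_id: int, molecule_id: int) -> tuple[int, Role]:
        """Resolve (molecule_id, role) for a 1-based atom index."""
        if self.by_atom is not None:
            try:
                return self.by_atom[atom_id]
            except KeyError:
                raise RoleMapError(f"role map has no entry for atom {atom_id}") from None
        try:
            return molecule_id, self.by_molecule[molecule_id]
        except KeyError:
            raise RoleMapError(
                f"role map has no entry for molecule {molecule_id} (atom {atom_id})"
            ) from None


def _parse_role(value) -> Role:
    try:
        return Role(str(value).strip().lower())
    except ValueError:
        raise RoleMapError(
            f"unknown role {value!r}; expected one of cation/anion/solvent"
        ) from None


def load_role_map(path) -> RoleMap:
    """Load a role map from CSV (columns molecule_id,role or atom_id,molecule_id,role)
    or YAML (mapping molecule_id -> role, or a list of records under ``roles``)."""
    path = Path(path)
    if not path.exists():
        raise RoleMapError(f"role map file not found: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if isinstance(data, dict) and "roles" in data:
            data = data["roles"]
        if isinstance(data, dict):
            return RoleMap(by_molecule={int(k): _parse_role(v) for k, v in data.items()})
        if isinstance(data, list):
            df = pd.DataFrame(data)
        else:
            raise RoleMapError(f"unsupported YAML role-map structure in {path}")
    else:
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise RoleMapError(f"cannot parse role map {path}: {exc}") from exc
    cols = {c.strip().lower() for c in df.columns}
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"molecule_id", "role"} <= cols:
        raise RoleMapError(
            f"role map {path} must have columns (molecule_id, role) "
            f"or (atom_id, molecule_id, role); found {sorted(cols)}"
        )
    if "atom_id" in cols:
        by_atom = {
            int(r.atom_id): (int(r.molecule_id), _parse_role(r.role))
            for r in df.itertuples()
        }
        return RoleMap(by_atom=by_atom)
    return RoleMap(
        by_molecule={int(r.molecule_id): _parse_role(r.role) for r in df.itertuples()}
    )


def write_role_map(frame: Frame, path) -> None:
    """Write a molecule-level CSV role map for ``frame``."""
    mols = np.unique(frame.molecule_ids)
    rows = [(int(m), frame.role_of(int(m)).value) for m in mols]
    pd.DataFrame(rows, columns=["molecule_id", "role"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# readers


def read_frames(path, topology=None, stride: int = 1) -> list[Frame]:
    """Read coordinate frames plus roles.

    Parameters
    ----------
    path
        GRO, PDB or extended-XYZ file (format chosen by suffix).
    topology
        Role-map file (CSV/YAML) or a :class:`RoleMap`. Required for GRO/PDB;
        optional for the XYZ dialect, whose per-atom columns already carry
        molecule ids and roles.
    stride
        Keep every ``stride``-th frame (the first frame is always kept).

    Positions are returned in nm and molecules are made whole.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"coordinate file not found: {path}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    suffix = path.suffix.lower()
    if isinstance(topology, (str, Path)):
        topology = load_role_map(topology)
    if suffix == ".gro":
        frames = _read_gro(path, _require_map(topology, path))
    elif suffix == ".pdb":
        frames = _read_pdb(path, _require_map(topology, path))
    elif suffix in (".xyz", ".exyz", ".extxyz"):
        frames = _read_xyz(path, topology)
    else:
        raise FormatError(f"unsupported coordinate format {suffix!r} for {path}")
    if not frames:
        raise FormatError(f"no frames found in {path}")
    n0 = frames[0].n_atoms
    for k, fr in enumerate(frames):
        if fr.n_atoms != n0:
            raise StructureError(
                f"{path}: frame {k} has {fr.n_atoms} atoms, frame 0 has {n0}"
            )
    return [make_whole(fr) for fr in frames[::stride]]


def _require_map(topology, path) -> RoleMap:
    if topology is None:
        raise RoleMapError(f"a role map is required to read {path}")
    return topology


def _check_orthorhombic(dimensions, where: str) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise FormatError(f"{where}: missing or zero box vectors")
    lengths = np.asarray(dimensions[:3], dtype=float)
    angles = np.asarray(dimensions[3:6], dtype=float)
    if np.any(np.abs(angles - 90.0) > _ANGLE_TOL):
        raise FormatError(
            f"{where}: triclinic box (angles {angles}) not supported; "
            "only orthorhombic boxes are handled"
        )
    return lengths


def _frame_from_universe(u, rmap: RoleMap, where: str, time: float | None) -> Frame:
    ts = u.trajectory.ts
    lengths_A = _check_orthorhombic(ts.dimensions, where)
    pos_nm = np.asarray(u.atoms.positions, dtype=float) / 10.0  # MDAnalysis works in A
    box_nm = lengths_A / 10.0
    resids = np.asarray(u.atoms.resids, dtype=int)
    mol_ids = np.empty(len(resids), dtype=int)
    role_codes = np.empty(len(resids), dtype=int)
    for i, resid in enumerate(resids):
        mol, role = rmap.role_for(i + 1, int(resid))
        mol_ids[i] = mol
        role_codes[i] = ROLE_CODE[role]
    names = [str(n) for n in u.atoms.names] if hasattr(u.atoms, "names") else None
    return Frame(pos_nm, mol_ids, role_codes, box_nm, time=time, names=names)


def _read_gro(path: Path, rmap: RoleMap) -> list[Frame]:
    import MDAnalysis as mda
    from MDAnalysis.lib.util import NamedStream

    text = path.read_text()
    lines = text.splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip() and all(not l.strip() for l in lines[i:]):
            break
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: truncated frame header at line {i + 1}")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError:
            raise FormatError(
                f"{path}: line {i + 2}: expected atom count, got {lines[i + 1]!r}"
            ) from None
        end = i + 2 + natoms + 1
        if end > len(lines):
            raise FormatError(
                f"{path}: frame starting at line {i + 1} declares {natoms} atoms "
                "but the file ends early"
            )
        block = "\n".join(lines[i:end]) + "\n"
        time = _gro_title_time(lines[i])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                u = mda.Universe(NamedStream(io.StringIO(block), "frame.gro"))
            except Exception as exc:
                raise FormatError(
                    f"{path}: cannot parse frame starting at line {i + 1}: {exc}"
                ) from exc
        frames.append(_frame_from_universe(u, rmap, f"{path} (line {i + 1})", time))
        i = end
    return frames


def _gro_title_time(title: str) -> float | None:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (IndexError, ValueError):
            return None
    return None


def _read_pdb(path: Path, rmap: RoleMap) -> list[Frame]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse PDB: {exc}") from exc
        frames = []
        for k, _ts in enumerate(u.trajectory):
            frames.append(_frame_from_universe(u, rmap, f"{path} (model {k + 1})", None))
    return frames


def _read_xyz(path: Path, topology: RoleMap | None) -> list[Frame]:
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from None
        if i + 1 >= len(lines) or i + 2 + natoms > len(lines):
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        comment = lines[i + 1]
        box, time = _parse_xyz_comment(comment, path, i + 2)
        pos = np.empty((natoms, 3))
        mols = np.empty(natoms, dtype=int)
        codes = np.empty(natoms, dtype=int)
        names = []
        for a in range(natoms):
            ln = i + 2 + a
            parts = lines[ln].split()
            if len(parts) < 6:
                raise FormatError(
                    f"{path}: line {ln + 1}: expected "
                    "'element x y z molecule_id role', got {lines[ln]!r}"
                )
            try:
                pos[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
                mol = int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln + 1}: {exc}") from None
            role = _parse_role(parts[5])
            if topology is not None:
                mol, role = topology.role_for(a + 1, mol)
            names.append(parts[0])
            mols[a] = mol
            codes[a] = ROLE_CODE[role]
        frames.append(Frame(pos, mols, codes, box, time=time, names=names))
        i += 2 + natoms
    return frames


def _parse_xyz_comment(comment: str, path: Path, lineno: int):
    box = None
    time = None
    if 'box="' in comment:
        payload = comment.split('box="', 1)[1].split('"', 1)[0]
        try:
            box = np.array([float(x) for x in payload.split()], dtype=float)
        except ValueError:
            box = None
    if box is None or box.size != 3:
        raise FormatError(f'{path}: line {lineno}: comment must carry box="lx ly lz"')
    if "time=" in comment:
        try:
            time = float(comment.split("time=", 1)[1].split()[0])
        except (IndexError, ValueError):
            time = None
    return box, time


# ---------------------------------------------------------------------------
# writers

_RESNAME = {0: "CAT", 1: "ANI", 2: "SOL"}


def write_gro(frames, path) -> None:
    """Write frame(s) as (concatenated) GRO, positions in nm at 1e-3 precision."""
    frames = _as_frames(frames)
    with open(path, "w") as fh:
        for fr in frames:
            title = "ionclust frame"
            if fr.time is not None:
                title += f" t= {fr.time:.4f}"
            fh.write(title + "\n")
            fh.write(f"{fr.n_atoms:5d}\n")
            for i in range(fr.n_atoms):
                resid = int(fr.molecule_ids[i]) % 100000
                resname = _RESNAME[int(fr.roles[i])]
                name = (fr.names[i] if fr.names else f"A{i % 100}")[:5]
                x, y, z = fr.positions[i]
                fh.write(
                    f"{resid:5d}{resname:<5s}{name:>5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")


def write_xyz(frames, path) -> None:
    """Write frame(s) in the extended-XYZ internal dialect (full float precision)."""
    frames = _as_frames(frames)
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            comment = f'box="{fr.box[0]:.9g} {fr.box[1]:.9g} {fr.box[2]:.9g}"'
            if fr.time is not None:
                comment += f" time={fr.time:.9g}"
            fh.write(comment + "\n")
            for i in range(fr.n_atoms):
                el = (fr.names[i] if fr.names else "X").split()[0]
                x, y, z = fr.positions[i]
                role = CODE_ROLE[int(fr.roles[i])].value
                fh.write(
                    f"{el} {x:.9f} {y:.9f} {z:.9f} {int(fr.molecule_ids[i])} {role}\n"
                )


def write_frames(frames, path) -> None:
    """Dispatch on suffix: .gro or .xyz/.exyz/.extxyz."""
    suffix = Path(path).suffix.lower()
    if suffix == ".gro":
        write_gro(frames, path)
    elif suffix in (".xyz", ".exyz", ".extxyz"):
        write_xyz(frames, path)
    else:
        raise FormatError(f"unsupported output format {suffix!r}")


def _as_frames(frames) -> list[Frame]:
    if isinstance(frames, Frame):
        return [frames]
    return list(frames)
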