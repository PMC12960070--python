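"""Frame parsing, role maps, periodic geometry helpers."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ionclust as ic
from ionclust.errors import FormatError, RoleMapError, StructureError
from ionclust.trajectory_io import (
    make_whole,
    minimum_image,
    molecule_atoms,
    write_gro,
    write_role_map,
    write_xyz,
)

finite_floats = st.floats(-50, 50, allow_nan=False)


def gro_line(resid, resname, name, serial, x, y, z):
    return f"{resid:5d}{resname:<5s}{name:>5s}{serial:5d}{x:8.3f}{y:8.3f}{z:8.3f}"


class TestMinimumImage:
    def test_zero_delta_maps_to_zero(self):
        assert np.allclose(minimum_image([0, 0, 0], [1, 2, 3]), 0)

    def test_wraps_past_half_box(self):
        assert np.allclose(minimum_image([0.9, 0, 0], [1, 1, 1]), [-0.1, 0, 0])

    def test_half_box_lands_on_negative_edge(self):
        # components live in [-box/2, box/2)
        assert np.allclose(minimum_image([0.5, -0.5, 1.5], [1, 1, 1]), [-0.5] * 3)

    @given(st.lists(finite_floats, min_size=3, max_size=3),
           st.lists(st.floats(0.5, 20), min_size=3, max_size=3),
           st.lists(st.integers(-4, 4), min_size=3, max_size=3))
    def test_invariant_under_box_translations(self, delta, box, shifts):
        delta = np.array(delta)
        box = np.array(box)
        shifted = delta + np.array(shifts) * box
        assert np.allclose(minimum_image(delta, box), minimum_image(shifted, box),
                           atol=1e-9)

    @given(st.lists(finite_floats, min_size=3, max_size=3),
           st.lists(st.floats(0.5, 20), min_size=3, max_size=3))
    def test_idempotent_and_norm_minimising_over_27_images(self, delta, box):
        delta = np.array(delta)
        box = np.array(box)
        w = minimum_image(delta, box)
        assert np.allclose(minimum_image(w, box), w)
        images = [
            w + np.array([i, j, k]) * box
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        ]
        assert np.linalg.norm(w) <= min(np.linalg.norm(v) for v in images) + 1e-9
        assert np.all(w >= -box / 2) and np.all(w < box / 2)


class TestFrameContracts:
    def test_molecule_roles_must_agree(self):
        with pytest.raises(RoleMapError):
            ic.Frame(np.zeros((2, 3)), [1, 1], [0, 1], [1, 1, 1])

    def test_box_must_be_positive(self):
        with pytest.raises(StructureError):
            ic.Frame(np.zeros((1, 3)), [1], [0], [1, -1, 1])

    def test_positions_must_be_finite(self):
        with pytest.raises(StructureError):
            ic.Frame([[np.nan, 0, 0]], [1], [0], [1, 1, 1])

    def test_make_whole_reunites_split_molecule(self):
        frame = ic.Frame([[0.02, 0.5, 0.5], [0.98, 0.5, 0.5]], [1, 1], [0, 0],
                         [1.0, 1.0, 1.0])
        whole = make_whole(frame)
        d = np.linalg.norm(whole.positions[0] - whole.positions[1])
        assert d < 0.1

    def test_molecule_atoms_returns_contiguous_records(self):
        frame = ic.Frame([[0.02, 0.5, 0.5], [0.98, 0.5, 0.5], [0.4, 0.4, 0.4]],
                         [1, 1, 2], [0, 0, 2], [1.0, 1.0, 1.0])
        records = molecule_atoms(frame, 1)
        assert len(records) == 2
        assert np.linalg.norm(records[0].position - records[1].position) < 0.1
        assert all(r.role is ic.Role.CATION for r in records)
        (solo,) = molecule_atoms(frame, 2)
        assert solo.role is ic.Role.SOLVENT

    def test_molecule_atoms_unknown_id(self):
        frame = ic.Frame(np.zeros((1, 3)), [1], [0], [1, 1, 1])
        with pytest.raises(LookupError):
            molecule_atoms(frame, 99)


class TestReaders:
    def test_minimal_gro_parse(self, tmp_path):
        gro = tmp_path / "mini.gro"
        gro.write_text(
            "two molecules\n"
            "    3\n"
            + gro_line(1, "CAT", "C1", 1, 0.1, 0.2, 0.3) + "\n"
            + gro_line(1, "CAT", "C2", 2, 0.15, 0.2, 0.3) + "\n"
            + gro_line(2, "SOL", "OW", 3, 0.5, 0.5, 0.5) + "\n"
            "   1.00000   1.00000   1.00000\n"
        )
        roles = tmp_path / "roles.csv"
        roles.write_text("molecule_id,role\n1,cation\n2,solvent\n")
        (frame,) = ic.read_frames(gro, roles)
        assert frame.n_atoms == 3
        assert len(np.unique(frame.molecule_ids)) == 2
        assert np.allclose(frame.positions[0], [0.1, 0.2, 0.3])
        assert frame.box.tolist() == [1.0, 1.0, 1.0]

    def test_pdb_angstrom_converted_to_nm(self, tmp_path):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(
            "CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1\n"
            "ATOM      1  C1  CAT A   1      10.000   2.000   3.000  1.00  0.00\n"
            "END\n"
        )
        roles = tmp_path / "roles.csv"
        roles.write_text("molecule_id,role\n1,cation\n")
        (frame,) = ic.read_frames(pdb, roles)
        assert np.allclose(frame.positions[0], [1.0, 0.2, 0.3], atol=1e-6)
        assert np.allclose(frame.box, [2.0, 2.0, 2.0])

    def test_triclinic_pdb_rejected(self, tmp_path):
        pdb = tmp_path / "tri.pdb"
        pdb.write_text(
            "CRYST1   20.000   20.000   20.000  90.00  90.00  60.00 P 1\n"
            "ATOM      1  C1  CAT A   1      10.000   2.000   3.000  1.00  0.00\n"
            "END\n"
        )
        roles = tmp_path / "roles.csv"
        roles.write_text("molecule_id,role\n1,cation\n")
        with pytest.raises(FormatError, match="triclinic"):
            ic.read_frames(pdb, roles)

    def test_gro_bad_atom_count_names_line(self, tmp_path):
        gro = tmp_path / "bad.gro"
        gro.write_text("title\nnot-a-number\n")
        roles = tmp_path / "roles.csv"
        roles.write_text("molecule_id,role\n1,cation\n")
        with pytest.raises(FormatError, match="line 2"):
            ic.read_frames(gro, roles)

    def test_missing_role_is_a_mapping_error(self, tmp_path):
        gro = tmp_path / "mini.gro"
        gro.write_text(
            "title\n    1\n"
            + gro_line(7, "CAT", "C1", 1, 0.1, 0.2, 0.3) + "\n"
            "   1.00000   1.00000   1.00000\n"
        )
        roles = tmp_path / "roles.csv"
        roles.write_text("molecule_id,role\n1,cation\n")
        with pytest.raises(RoleMapError, match="molecule 7"):
            ic.read_frames(gro, roles)

    def test_atom_count_mismatch_between_frames(self, tmp_path):
        xyz = tmp_path / "t.xyz"
        xyz.write_text(
            '1\nbox="1 1 1"\nC 0.1 0.1 0.1 1 cation\n'
            '2\nbox="1 1 1"\nC 0.1 0.1 0.1 1 cation\nO 0.5 0.5 0.5 2 solvent\n'
        )
        with pytest.raises(StructureError):
            ic.read_frames(xyz)

    def test_xyz_without_box_rejected(self, tmp_path):
        xyz = tmp_path / "nobox.xyz"
        xyz.write_text("1\nno box here\nC 0.1 0.1 0.1 1 cation\n")
        with pytest.raises(FormatError, match="box"):
            ic.read_frames(xyz)

    def test_yaml_role_map(self, tmp_path):
        yml = tmp_path / "roles.yaml"
        yml.write_text("1: cation\n2: anion\n3: solvent\n")
        rmap = ic.load_role_map(yml)
        assert rmap.role_for(1, 2) == (2, ic.Role.ANION)


class TestRoundTrip:
    @pytest.mark.parametrize("writer,ext,tol", [
        (write_gro, "gro", 1e-3),   # GRO stores 3 decimals
        (write_xyz, "xyz", 1e-8),
    ])
    def test_synthetic_frame_round_trip(self, tmp_path, writer, ext, tol):
        spec = ic.PlantedSpec(sizes=(2, 2, 1, 1), n_cations=3, n_anions=3, seed=21)
        frame, _ = ic.plant_frame(spec)
        path = tmp_path / f"rt.{ext}"
        writer([frame], path)
        roles = tmp_path / "roles.csv"
        write_role_map(frame, roles)
        (back,) = ic.read_frames(path, roles)
        ref = make_whole(frame)
        assert back.n_atoms == frame.n_atoms
        assert np.array_equal(back.molecule_ids, frame.molecule_ids)
        assert np.array_equal(back.roles, frame.roles)
        assert np.abs(back.positions - ref.positions).max() <= tol
        assert np.allclose(back.box, frame.box, atol=tol)

    def test_multi_frame_gro_and_stride(self, tmp_path):
        spec = ic.PlantedSpec(sizes=(2, 1, 1), n_cations=2, n_anions=2, seed=8)
        frames, _ = ic.toy_trajectory(spec, 6, hop_rate=0.0, seed=8)
        path = tmp_path / "traj.gro"
        write_gro(frames, path)
        roles = tmp_path / "roles.csv"
        write_role_map(frames[0], roles)
        assert len(ic.read_frames(path, roles)) == 6
        assert len(ic.read_frames(path, roles, stride=2)) == 3
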