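"""Ellipsoid fitting and shell geometry, checked against explicit linear algebra."""
import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ionclust as ic
from ionclust.ellipsoid import (
    ShellSpec,
    ellipsoid_contains,
    fit_ellipsoid,
    resolve_n_max,
    shell_occupants,
    shell_semiaxes,
)

BIG_BOX = np.array([100.0, 100.0, 100.0])


def cube_points():
    return np.array(list(itertools.product([1, -1], [2, -2], [3, -3])), dtype=float)


class TestFit:
    def test_signed_cube_gives_exact_semiaxes(self):
        # variance of {+c, -c} is c^2, so eigenvalues are (9, 4, 1) and
        # a_i = 2 sqrt(lambda_i) = (6, 4, 2) exactly
        e = fit_ellipsoid(cube_points())
        assert np.allclose(e.center, 0, atol=1e-12)
        assert np.array_equal(e.semiaxes, [6.0, 4.0, 2.0])

    def test_single_atom_gets_floor_semiaxes(self):
        e = fit_ellipsoid([[5.0, 5.0, 5.0]], semiaxis_floor=0.1)
        assert np.allclose(e.center, [5, 5, 5])
        assert np.allclose(e.semiaxes, 0.1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipsoid(np.empty((0, 3)))

    def test_random_cloud_matches_explicit_eigensolve(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            pts = rng.normal(scale=2.0, size=(20, 3))
            e = fit_ellipsoid(pts, semiaxis_floor=0.0)
            # independent route: assemble the second-moment matrix entry by entry
            c = pts.mean(axis=0)
            M = np.zeros((3, 3))
            for p in pts:
                for i in range(3):
                    for j in range(3):
                        M[i, j] += (p[i] - c[i]) * (p[j] - c[j])
            M /= len(pts)
            lam = np.sort(np.linalg.eigvalsh(M))[::-1]
            assert np.allclose(e.semiaxes, 2 * np.sqrt(lam), atol=1e-10)
            # axes orthonormal and actually diagonalise M
            assert np.allclose(e.axes.T @ e.axes, np.eye(3), atol=1e-10)
            D = e.axes.T @ M @ e.axes
            assert np.allclose(D, np.diag(np.diag(D)), atol=1e-10)

    def test_translation_and_rotation_equivariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(15, 3))
        base = fit_ellipsoid(pts, semiaxis_floor=0.0)
        shift = np.array([3.0, -2.0, 9.0])
        moved = fit_ellipsoid(pts + shift, semiaxis_floor=0.0)
        assert np.allclose(moved.center, base.center + shift, atol=1e-10)
        assert np.allclose(moved.semiaxes, base.semiaxes, atol=1e-8)
        # random rotation via QR
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = fit_ellipsoid(pts @ Q.T, semiaxis_floor=0.0)
        assert np.allclose(rotated.semiaxes, base.semiaxes, atol=1e-8)

    @given(st.permutations(range(8)))
    def test_semiaxes_invariant_under_atom_relabeling(self, perm):
        pts = cube_points()[:8]
        e1 = fit_ellipsoid(pts)
        e2 = fit_ellipsoid(pts[list(perm)])
        assert np.allclose(e1.semiaxes, e2.semiaxes, atol=1e-12)


class TestShells:
    def test_shell_semiaxes_formula(self):
        e = fit_ellipsoid(cube_points())
        spec = ShellSpec(delta=0.4)
        assert np.allclose(shell_semiaxes(e, spec, 0), [6, 4, 2])
        assert np.allclose(shell_semiaxes(e, spec, 1), [6.4, 4.4, 2.4])
        assert np.allclose(shell_semiaxes(e, spec, 5), [8, 6, 4])

    def test_negative_shell_rejected(self):
        e = fit_ellipsoid(cube_points())
        with pytest.raises(ValueError):
            shell_semiaxes(e, ShellSpec(), -1)

    def test_contains_center_and_inclusive_boundary(self):
        e = fit_ellipsoid(cube_points())
        assert ellipsoid_contains(e, e.semiaxes, e.center, BIG_BOX)
        boundary = e.center + e.semiaxes[0] * e.axes[:, 0]
        assert ellipsoid_contains(e, e.semiaxes, boundary, BIG_BOX)
        outside = e.center + (e.semiaxes[0] + 1e-6) * e.axes[:, 0]
        assert not ellipsoid_contains(e, e.semiaxes, outside, BIG_BOX)

    def test_contains_matches_unrotated_oracle(self):
        # an axis-aligned ellipsoid: membership must equal the direct formula
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 3)) * [3.0, 2.0, 1.0]
        e = fit_ellipsoid(pts, semiaxis_floor=0.0)
        s = e.semiaxes
        for p in rng.uniform(-8, 8, size=(200, 3)):
            y = (p - e.center) @ e.axes
            expected = (y[0] / s[0]) ** 2 + (y[1] / s[1]) ** 2 + (y[2] / s[2]) ** 2 <= 1
            assert ellipsoid_contains(e, s, p, BIG_BOX) == expected

    def test_contains_respects_periodicity(self):
        e = ic.Ellipsoid(center=[0.1, 0.1, 0.1], axes=np.eye(3),
                         semiaxes=[0.3, 0.3, 0.3])
        # the image of a point near the far box face is close to the centre
        assert ellipsoid_contains(e, e.semiaxes, [0.95, 0.1, 0.1], [1.0, 1.0, 1.0])

    def test_shells_partition_space(self, small_planted):
        _, frame, _ = small_planted
        ref = int(frame.ion_molecule_ids[0])
        e = fit_ellipsoid(frame.positions[frame.molecule_mask(ref)])
        spec = ShellSpec()
        n_max = resolve_n_max(spec, frame.box)
        seen = np.zeros(frame.n_atoms, dtype=int)
        for n in range(n_max + 1):
            occ = shell_occupants(e, spec, n, frame)
            seen[occ.ion_atoms] += 1
            seen[occ.solvent_atoms] += 1
        assert np.max(seen) <= 1  # no atom in two shells

    def test_occupant_grouping_and_reference_exclusion(self, small_planted):
        _, frame, _ = small_planted
        ref = int(frame.ion_molecule_ids[0])
        e = fit_ellipsoid(frame.positions[frame.molecule_mask(ref)])
        spec = ShellSpec()
        n_max = resolve_n_max(spec, frame.box)
        for n in range(n_max + 1):
            occ = shell_occupants(e, spec, n, frame, reference_molecule=ref)
            assert not np.isin(occ.ion_atoms, np.flatnonzero(frame.molecule_mask(ref))).any()
            assert np.all(frame.roles[occ.solvent_atoms] == 2)
            assert np.all(frame.roles[occ.ion_atoms] != 2)

    def test_planted_solvent_atom_lands_in_predicted_shell(self):
        e = fit_ellipsoid(cube_points())
        spec = ShellSpec(delta=0.4)
        # a point half a delta beyond the base surface sits in shell 1
        p = e.center + (e.semiaxes[0] + 0.5 * spec.delta) * e.axes[:, 0]
        frame = ic.Frame([p], [99], [2], BIG_BOX)
        assert len(shell_occupants(e, spec, 1, frame).solvent_atoms) == 1
        assert len(shell_occupants(e, spec, 0, frame).solvent_atoms) == 0
        assert len(shell_occupants(e, spec, 2, frame).solvent_atoms) == 0

    def test_occupants_match_per_atom_brute_force(self, small_planted):
        _, frame, _ = small_planted
        ref = int(frame.ion_molecule_ids[2])
        e = fit_ellipsoid(frame.positions[frame.molecule_mask(ref)])
        spec = ShellSpec()
        n_max = resolve_n_max(spec, frame.box)
        for n in range(n_max + 1):
            occ = shell_occupants(e, spec, n, frame, reference_molecule=ref)
            got = set(occ.ion_atoms) | set(occ.solvent_atoms)
            expected = set()
            for a in range(frame.n_atoms):
                if frame.molecule_ids[a] == ref:
                    continue
                inside_n = ellipsoid_contains(
                    e, shell_semiaxes(e, spec, n), frame.positions[a], frame.box)
                inside_prev = n > 0 and ellipsoid_contains(
                    e, shell_semiaxes(e, spec, n - 1), frame.positions[a], frame.box)
                if inside_n and not inside_prev:
                    expected.add(a)
            assert got == expected

    def test_auto_n_max_covers_half_box(self):
        spec = ShellSpec(delta=0.4)
        assert resolve_n_max(spec, np.array([4.0, 6.0, 8.0])) == 5  # ceil(2/0.4)
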