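"""SASA, relative exposure, burial and solvation classes."""

import numpy as np
import pytest

from unfoldkit import surface as sf
from unfoldkit.errors import ParameterError
from unfoldkit.structure_io import Atom, DomainPartition, ResidueID, Structure, Trajectory


def fibonacci_sphere(n):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def quadrature_sasa_oracle(structure, probe=1.4, n_points=2000):
    """Independent numpy Shrake-Rupley (same radii, own point set)."""
    X = structure.coords
    radii = structure.radii + probe
    pts = fibonacci_sphere(n_points)
    areas = np.zeros(len(X))
    for i in range(len(X)):
        p = X[i] + radii[i] * pts
        free = np.ones(n_points, dtype=bool)
        for j in range(len(X)):
            if j == i:
                continue
            free &= np.linalg.norm(p - X[j], axis=1) >= radii[j]
        areas[i] = 4 * np.pi * radii[i] ** 2 * free.mean()
    return areas


def _c_atom(name, rid):
    return Atom(name=name, element="C", residue=rid)


def _cage(center, radius, rid_start, n_shell=40):
    """Shell of single-C residues enclosing `center`."""
    atoms, coords = [], []
    pts = fibonacci_sphere(n_shell) * radius + np.asarray(center)
    for k in range(n_shell):
        atoms.append(_c_atom("C", ResidueID("A", rid_start + k)))
        coords.append(pts[k])
    return atoms, coords


class TestShrakeRupley:
    def test_isolated_atom_matches_analytic_sphere(self):
        s = Structure([_c_atom("CA", ResidueID("A", 1))], np.zeros((1, 3)))
        res = sf.shrake_rupley_sasa(s)
        assert res.total == pytest.approx(4 * np.pi * 3.1**2, rel=1e-3)

    def test_two_distant_atoms_no_occlusion(self):
        s = Structure(
            [_c_atom("CA", ResidueID("A", 1)), _c_atom("CB", ResidueID("A", 1))],
            np.array([[0.0, 0, 0], [100.0, 0, 0]]),
        )
        res = sf.shrake_rupley_sasa(s)
        assert res.total == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-3)

    def test_enclosed_atom_area_vanishes(self):
        atoms = [_c_atom("CA", ResidueID("A", 1))]
        coords = [np.zeros(3)]
        shell_atoms, shell_coords = _cage([0, 0, 0], 3.0, 10, n_shell=60)
        s = Structure(atoms + shell_atoms, np.array(coords + shell_coords))
        res = sf.shrake_rupley_sasa(s, n_points=960)
        assert res.per_atom_area[0] == pytest.approx(0.0, abs=1e-6)

    def test_polar_nonpolar_split_sums_to_total(self, toy_structure):
        res = sf.shrake_rupley_sasa(toy_structure)
        assert res.npsasa + res.psasa == pytest.approx(res.per_atom_area.sum())

    def test_rigid_motion_invariance(self, toy_structure):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [15, 40, 70], degrees=True).as_matrix()
        base = sf.shrake_rupley_sasa(toy_structure)
        rot = sf.shrake_rupley_sasa(
            toy_structure, coords=toy_structure.coords @ R.T + 7.0
        )
        assert rot.total == pytest.approx(base.total, rel=0.01)

    def test_quadrature_convergence(self, toy_structure):
        a = sf.shrake_rupley_sasa(toy_structure, n_points=960).total
        b = sf.shrake_rupley_sasa(toy_structure, n_points=1920).total
        assert abs(b - a) / b < 0.005

    def test_against_independent_quadrature_oracle(self, toy_structure):
        mine = sf.shrake_rupley_sasa(toy_structure, n_points=960)
        oracle = quadrature_sasa_oracle(toy_structure, n_points=2000)
        assert mine.total == pytest.approx(oracle.sum(), rel=0.01)
        np.testing.assert_allclose(mine.per_atom_area, oracle, atol=2.5)

    def test_occlusion_only_removes_area(self, toy_structure):
        res = sf.shrake_rupley_sasa(toy_structure)
        iso = np.array(
            [4 * np.pi * (a.radius + 1.4) ** 2 for a in toy_structure.atoms]
        )
        assert (res.per_atom_area <= iso + 1e-6).all()

    def test_too_few_points_rejected(self, toy_structure):
        with pytest.raises(ParameterError):
            sf.shrake_rupley_sasa(toy_structure, n_points=16)


class TestRelativeExposure:
    def test_gly_x_gly_context_is_the_reference(self, toy_structure):
        # the middle residue of an extended Gly-X-Gly tripeptide built with
        # the same layout as the internal reference has exposure ~1
        rid = toy_structure.residues[0]
        idx = toy_structure.residue_atom_indices(rid)
        mid_atoms = [toy_structure.atoms[i] for i in idx]
        mid_coords = toy_structure.coords[idx]
        mid_coords = mid_coords - mid_coords.mean(axis=0)
        gly_names = ["N", "CA", "C", "O"]
        gly_offsets = np.array(
            [[-1.2, 0.6, 0.0], [0.0, 0.0, 0.0], [1.3, 0.6, 0.0], [1.4, 1.8, 0.0]]
        )
        atoms, coords = [], []
        for k, shift in ((1, -3.8), (3, +3.8)):
            r = ResidueID("A", k)
            for name, off in zip(gly_names, gly_offsets):
                atoms.append(Atom(name=name, element=name[0], residue=r,
                                  radius={"N": 1.55, "O": 1.52}.get(name[0], 1.70)))
                coords.append(off + np.array([shift, 0.0, 0.0]))
        mid = ResidueID("A", 2)
        for a, xyz in zip(mid_atoms, mid_coords):
            atoms.append(Atom(name=a.name, element=a.element, residue=mid,
                              polarity=a.polarity, radius=a.radius))
            coords.append(xyz)
        tri = Structure(atoms, np.array(coords))
        assert sf.relative_exposure(tri, mid) == pytest.approx(1.0, abs=0.05)

    def test_enclosed_residue_near_zero(self):
        atoms = [_c_atom("C", ResidueID("A", 1))]
        shell_atoms, shell_coords = _cage([0, 0, 0], 3.5, 10, n_shell=60)
        s = Structure(atoms + shell_atoms, np.array([[0.0, 0, 0]] + shell_coords))
        assert sf.relative_exposure(s, ResidueID("A", 1)) < 0.01


class TestBuriedInterface:
    def _bipartite_cage(self):
        """Two contacting residues from different domains under one shell."""
        core = [
            (_c_atom("C", ResidueID("A", 1)), [-2.0, 0, 0]),
            (_c_atom("C", ResidueID("A", 2)), [500.0, 500, 0]),  # spacers keep
            (_c_atom("C", ResidueID("A", 3)), [600.0, 500, 0]),  # sequence sep > 2
            (_c_atom("C", ResidueID("A", 4)), [2.0, 0, 0]),
        ]
        shell_atoms, shell_coords = _cage([0, 0, 0], 5.5, 10, n_shell=140)
        atoms = [a for a, _ in core] + shell_atoms
        coords = np.array([c for _, c in core] + shell_coords)
        s = Structure(atoms, coords)
        dp = DomainPartition(
            {
                "n_domain": {ResidueID("A", 1), ResidueID("A", 2), ResidueID("A", 3)}
                | {ResidueID("A", n) for n in range(10, 150)},
                "c_domain": {ResidueID("A", 4)},
            }
        )
        return s, dp

    def test_buried_bridging_residues_found(self):
        s, dp = self._bipartite_cage()
        buried = sf.buried_interface_residues(s, dp)
        assert ResidueID("A", 1) in buried
        assert ResidueID("A", 4) in buried
        # shell residues have inter-domain contacts with residue 4 but are
        # exposed on the outside, so the 5% rule excludes them
        assert all(r.number in (1, 4) for r in buried)

    def test_no_interface_contacts_empty(self, rng):
        atoms = [
            _c_atom("C", ResidueID("A", 1)),
            _c_atom("C", ResidueID("A", 2)),
            _c_atom("C", ResidueID("A", 3)),
            _c_atom("C", ResidueID("A", 4)),
        ]
        coords = np.array([[0, 0, 0], [4, 0, 0], [100, 0, 0], [104, 0, 0]], float)
        s = Structure(atoms, coords)
        dp = DomainPartition(
            {
                "n_domain": {ResidueID("A", 1), ResidueID("A", 2)},
                "c_domain": {ResidueID("A", 3), ResidueID("A", 4)},
            }
        )
        assert sf.buried_interface_residues(s, dp) == set()


class TestSolvationClasses:
    def _opening_cage_trajectory(self):
        """Three buried residues whose cages open at programmed times."""
        rids = [ResidueID("A", 1), ResidueID("A", 2), ResidueID("A", 3)]
        centers = [np.array([0.0, 0, 0]), np.array([200.0, 0, 0]),
                   np.array([400.0, 0, 0])]
        atoms = [_c_atom("C", r) for r in rids]
        coords0 = list(centers)
        shells = []
        start = 10
        for c in centers:
            sa, sc = _cage(c, 3.5, start, n_shell=50)
            atoms += sa
            coords0 += sc
            shells.append(np.arange(len(coords0) - 50, len(coords0)))
            start += 50
        X0 = np.array(coords0)
        s = Structure(atoms, X0)
        times = 10.0 * np.arange(1, 121)  # 1.2 ns at 10 ps
        open_at = {0: 500.0, 1: 800.0, 2: None}  # crossing = 500 ps
        frames = np.repeat(X0[None], len(times), axis=0)
        for k, t_open in open_at.items():
            if t_open is None:
                continue
            late = times >= t_open
            for f in np.nonzero(late)[0]:
                frames[f][shells[k]] = (frames[f][shells[k]] - centers[k]) * 10 + centers[k]
        return Trajectory(s, frames, times), rids

    def test_programmed_exposure_classes(self):
        traj, rids = self._opening_cage_trajectory()
        cmap = sf.solvation_classes(
            traj, traj.topology, crossing_time=500.0, residues=rids, n_points=240
        )
        assert cmap.classes[rids[0]] == "exposed_at_TSE"
        assert cmap.classes[rids[1]] == "exposed_by_600ps"
        assert cmap.classes[rids[2]] == "still_buried"

    def test_frozen_native_all_still_buried(self):
        traj, rids = self._opening_cage_trajectory()
        frozen = Trajectory(
            traj.topology,
            np.repeat(traj.coords[:1], len(traj), axis=0),
            traj.times,
        )
        cmap = sf.solvation_classes(
            frozen, traj.topology, crossing_time=500.0, residues=rids, n_points=240
        )
        assert set(cmap.classes.values()) == {"still_buried"}

    def test_out_of_range_delay_raises(self):
        traj, rids = self._opening_cage_trajectory()
        with pytest.raises(ParameterError):
            sf.solvation_classes(
                traj, traj.topology, crossing_time=1100.0, residues=rids
            )


class TestFractionalBurial:
    @pytest.mark.parametrize(
        "frame_sasa,expected",
        [(5000.0, 1.0), (15000.0, 0.0), (10000.0, 0.5)],
    )
    def test_linear_scale(self, frame_sasa, expected):
        assert sf.fractional_burial(frame_sasa, 5000.0, 15000.0) == pytest.approx(expected)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ParameterError):
            sf.fractional_burial(1.0, 5000.0, 4000.0)
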