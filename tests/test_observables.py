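"""RMSD/RMSF, NOE back-calculation, H-bond and torsion observables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from g4validate.core import EnsembleBundle, NOERestraint, NOETable, StructureModel, TrajectorySet
from g4validate.observables import (NOEComparison, dihedral_matrix, hbond_series,
                                    noe_backcalculate, noe_violations, rmsd_series,
                                    rmsf_profile, running_average, superpose)
from g4validate.synthetic import generate_fluctuating_trajectory
from g4validate.topology import (DihedralDefinition, HBondDefinition,
                                 enumerate_backbone_dihedrals, parse_sequence)
from tests.conftest import rotation_matrix


def _two_proton_model(d):
    return StructureModel(np.array(["H1'", "H8"], dtype=object), [1, 2],
                          ["DG", "DG"], ["H", "H"],
                          [[0.0, 0.0, 0.0], [d, 0.0, 0.0]])


def _pair_traj(distances):
    """One H-H pair whose separation follows ``distances`` over frames."""
    top = _two_proton_model(distances[0])
    coords = np.zeros((len(distances), 2, 3))
    coords[:, 1, 0] = distances
    return TrajectorySet(top, coords)


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        (rot, t), rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-8)
        assert np.allclose(t, 0.0, atol=1e-8)

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(15, 3))
        true_rot = rotation_matrix(3)
        target = pts @ true_rot.T + [1.0, 2.0, 3.0]
        (rot, t), rmsd = superpose(pts, target)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(rot, true_rot, atol=1e-8)

    def test_matches_brute_force_rotation_search(self):
        """The Kabsch result is the minimum over densely sampled rotations."""
        rng = np.random.default_rng(2)
        a = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [0.5, 0.5, 1.5]])
        b = a + rng.normal(scale=0.3, size=a.shape)
        _, rmsd = superpose(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        samples = Rotation.random(20000, rng=np.random.default_rng(5)).as_matrix()
        brute = min(np.sqrt(np.mean(np.sum((ac @ rot.T - bc) ** 2, axis=1)))
                    for rot in samples)
        assert rmsd <= brute + 1e-9
        assert rmsd == pytest.approx(brute, abs=0.02)

    def test_degenerate_mask_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)
        with pytest.raises(ValueError, match="fewer than 3"):
            superpose(line[:2], line[:2])

    def test_no_reflection(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        mirrored = pts * [1, 1, -1]
        (rot, _), _ = superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-8)


class TestRMSDSeries:
    def test_self_reference_is_zero(self, system_and_annotation):
        model, _ = system_and_annotation
        traj = generate_fluctuating_trajectory(model, {"all": 0.0}, 5, seed=0)
        series = rmsd_series(traj, model, align_mask="heavy")
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_running_average_edge_shrunk(self):
        assert np.allclose(running_average(np.array([0.0, 3.0, 6.0]), 3),
                           [1.5, 3.0, 4.5])

    def test_mean_matches_independent_superposition_oracle(self, ideal_g4):
        """Dual route: scipy's align_vectors RMSD on every frame."""
        sigma = 0.3
        traj = generate_fluctuating_trajectory(ideal_g4, {"all": sigma}, 200, seed=9)
        series = rmsd_series(traj, ideal_g4, align_mask="heavy")
        idx = ideal_g4.indices("heavy")
        ref = ideal_g4.xyz[idx] - ideal_g4.xyz[idx].mean(axis=0)
        oracle = []
        for f in range(traj.n_frames):
            mob = traj.coordinates[f, idx]
            mob = mob - mob.mean(axis=0)
            _, rssd = Rotation.align_vectors(ref, mob)
            oracle.append(rssd / np.sqrt(len(idx)))
        assert np.allclose(series.values[0], oracle, atol=1e-6)
        assert series.values[0].mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_rotation_invariance(self, ideal_g4):
        traj = generate_fluctuating_trajectory(ideal_g4, {"all": 0.2}, 10, seed=4)
        rot = rotation_matrix(8)
        moved = TrajectorySet(traj.topology, traj.coordinates @ rot.T + [3.0, -1.0, 7.0],
                              traj.times)
        a = rmsd_series(traj, ideal_g4, align_mask="heavy").values
        b = rmsd_series(moved, ideal_g4, align_mask="heavy").values
        assert np.allclose(a, b, atol=1e-8)

    def test_empty_mask_rejected(self, static_traj):
        with pytest.raises(ValueError, match="empty mask|no atom"):
            rmsd_series(static_traj, static_traj.topology, align_mask="resname XXX")


class TestRMSF:
    def test_static_is_zero(self, static_traj):
        prof = rmsf_profile(static_traj)
        assert np.allclose(prof.per_atom, 0.0, atol=1e-9)

    def test_recovers_sigma_sqrt3(self, ideal_g4):
        traj = generate_fluctuating_trajectory(ideal_g4, {"all": 0.5}, 5000, seed=21)
        prof = rmsf_profile(traj, mask="heavy")
        assert prof.per_atom.mean() == pytest.approx(0.5 * np.sqrt(3), rel=0.05)

    def test_group_ordering(self, ideal_g4):
        traj = generate_fluctuating_trajectory(
            ideal_g4, {"resid 1-12": 0.2, "element K": 0.6}, 800, seed=5)
        prof = rmsf_profile(traj, mask="all")
        g4_val = prof.per_residue[prof.per_residue.resid <= 12].rmsf.mean()
        ion_val = prof.per_residue[prof.per_residue.resid > 12].rmsf.mean()
        assert ion_val > g4_val

    def test_single_frame_rejected(self, ideal_g4):
        traj = generate_fluctuating_trajectory(ideal_g4, {"all": 0.0}, 1, seed=0)
        with pytest.raises(ValueError, match="two frames"):
            rmsf_profile(traj)


class TestNOE:
    def test_constant_distance_identity(self):
        traj = _pair_traj([4.2] * 10)
        table = NOETable([NOERestraint("r1", [(1, "H1'")], [(2, "H8")], 3.0, 5.0)])
        comp = noe_backcalculate(traj, table, equilibration=0.0)
        assert comp.frame.distance[0] == pytest.approx(4.2, abs=1e-12)

    def test_two_frame_r6_arithmetic(self):
        traj = _pair_traj([3.0, 5.0])
        table = NOETable([NOERestraint("r1", [(1, "H1'")], [(2, "H8")], 0.0, 9.0)])
        comp = noe_backcalculate(traj, table, equilibration=0.0)
        expected = ((3.0 ** -6 + 5.0 ** -6) / 2.0) ** (-1.0 / 6.0)
        assert comp.frame.distance[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(3.34, abs=0.01)

    def test_unresolvable_atoms_listed(self):
        traj = _pair_traj([4.0])
        table = NOETable([NOERestraint("r1", [(1, "H99")], [(2, "H8")], 3.0, 5.0)])
        with pytest.raises(ValueError, match="H99"):
            noe_backcalculate(traj, table)

    @pytest.mark.parametrize("d, expect", [(3.4, False), (3.6, True), (1.4, False), (0.9, True)])
    def test_violation_boundary_logic(self, d, expect):
        traj = _pair_traj([d])
        table = NOETable([NOERestraint("r1", [(1, "H1'")], [(2, "H8")], 2.0, 2.5)])
        comp = noe_backcalculate(traj, table, equilibration=0.0)
        per, _ = noe_violations(comp, tolerance=1.0)
        assert bool(per.violated[0]) is expect

    def test_per_residue_attribution_counts_both(self):
        traj = _pair_traj([9.0])
        table = NOETable([NOERestraint("r1", [(1, "H1'")], [(2, "H8")], 2.0, 2.5)])
        comp = noe_backcalculate(traj, table, equilibration=0.0)
        _, per_res = noe_violations(comp, tolerance=1.0)
        assert dict(zip(per_res.resid, per_res.violations)) == {1: 1, 2: 1}

    def test_within_bounds_gives_empty_residue_table(self):
        traj = _pair_traj([4.0])
        table = NOETable([NOERestraint("r1", [(1, "H1'")], [(2, "H8")], 3.0, 5.0)])
        comp = noe_backcalculate(traj, table, equilibration=0.0)
        per, per_res = noe_violations(comp)
        assert per.violated.sum() == 0 and per_res.empty

    @given(st.lists(st.floats(1.5, 12.0), min_size=1, max_size=25))
    @settings(deadline=None, max_examples=50)
    def test_power_mean_bounds(self, distances):
        """min distance ≤ ⟨r⁻⁶⟩^(−1/6) ≤ arithmetic mean distance."""
        traj = _pair_traj(distances)
        table = NOETable([NOERestraint("r1", [(1, "H1'")], [(2, "H8")], 0.0, 99.0)])
        comp = noe_backcalculate(traj, table, equilibration=0.0)
        d = comp.frame.distance[0]
        assert min(distances) - 1e-9 <= d <= np.mean(distances) + 1e-9

    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    @settings(deadline=None, max_examples=40)
    def test_violations_monotone_in_tolerance(self, t1, t2):
        traj = _pair_traj([1.0, 2.0, 4.0, 6.5])
        table = NOETable([NOERestraint(f"r{i}", [(1, "H1'")], [(2, "H8")], lo, hi)
                          for i, (lo, hi) in enumerate([(2.0, 3.0), (1.0, 5.0), (4.0, 9.0)])])
        comp = noe_backcalculate(traj, table, equilibration=0.0)
        lo_t, hi_t = sorted([t1, t2])
        n_hi = noe_violations(comp, hi_t)[0].violated.sum()
        n_lo = noe_violations(comp, lo_t)[0].violated.sum()
        assert n_hi <= n_lo

    def test_negative_tolerance_rejected(self):
        comp = noe_backcalculate(_pair_traj([4.0]),
                                 NOETable([NOERestraint("r", [(1, "H1'")], [(2, "H8")], 3, 5)]),
                                 equilibration=0.0)
        with pytest.raises(ValueError):
            noe_violations(comp, tolerance=-0.5)

    def test_ambiguous_group_average_keeps_constancy(self):
        """Equivalent protons at equal distance: d equals that distance."""
        top = StructureModel(np.array(["H21", "H22", "H8"], dtype=object), [1, 1, 2],
                             ["DG", "DG", "DG"], ["H", "H", "H"],
                             [[0.0, 1.0, 0.0], [0.0, -1.0, 0.0], [4.0, 0.0, 0.0]])
        coords = np.broadcast_to(top.xyz, (3, 3, 3)).copy()
        traj = TrajectorySet(top, coords)
        table = NOETable([NOERestraint("r", [(1, "H21"), (1, "H22")], [(2, "H8")], 0, 9)])
        comp = noe_backcalculate(traj, table, equilibration=0.0)
        d = np.sqrt(17.0)
        assert comp.frame.distance[0] == pytest.approx(d, abs=1e-12)


class TestHBonds:
    def test_angle_gate(self):
        # donor-acceptor 2.9 Å but bent donor-H-acceptor angle
        top = StructureModel(np.array(["N1", "H1", "O6"], dtype=object), [1, 1, 2],
                             ["DG", "DG", "DG"], ["N", "H", "O"],
                             [[0.0, 0.0, 0.0], [0.0, 1.0, 0.0], [2.9, 0.0, 0.0]])
        traj = TrajectorySet(top, top.xyz[None])
        d = HBondDefinition((1, "N1"), ("H1",), (2, "O6"), "N1-O6")
        hb = hbond_series(traj, [d])
        assert hb.distances[0, 0] == pytest.approx(2.9)
        assert hb.angles[0, 0] < 135.0
        assert hb.persistence[0] == 0.0

    def test_distance_gate(self):
        top = StructureModel(np.array(["N1", "H1", "O6"], dtype=object), [1, 1, 2],
                             ["DG", "DG", "DG"], ["N", "H", "O"],
                             [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [3.2, 0.0, 0.0]])
        traj = TrajectorySet(top, top.xyz[None])
        hb = hbond_series(traj, [HBondDefinition((1, "N1"), ("H1",), (2, "O6"), "N1-O6")])
        assert hb.angles[0, 0] == pytest.approx(180.0)
        assert hb.persistence[0] == 0.0  # 3.2 Å > 3.0 Å cutoff

    def test_missing_hydrogen_rejected(self, duplex3):
        traj = TrajectorySet(duplex3, duplex3.xyz[None])
        bad = HBondDefinition((1, "N1"), ("HX",), (6, "N3"), "N1-N3")
        with pytest.raises(ValueError, match="HX"):
            hbond_series(traj, [bad])


class TestDihedralMatrix:
    def _torsion_traj(self, angles_deg):
        top = StructureModel(np.array(["C5'", "C4'", "C3'", "O3'"], dtype=object),
                             [1, 1, 1, 1], ["DG"] * 4, ["C", "C", "C", "O"],
                             np.zeros((4, 3)))
        phi = np.deg2rad(np.asarray(angles_deg))
        coords = np.zeros((len(phi), 4, 3))
        coords[:, 0] = [1.0, 0.0, 0.0]
        coords[:, 1] = [0.0, 0.0, 0.0]
        coords[:, 2] = [0.0, 0.0, 1.5]
        coords[:, 3, 0] = np.cos(phi)
        coords[:, 3, 1] = np.sin(phi)
        coords[:, 3, 2] = 1.5
        return TrajectorySet(top, coords)

    def test_constant_torsion_single_bin(self):
        traj = self._torsion_traj([60.0] * 7)
        defs = [DihedralDefinition("delta", 1,
                                   [(1, "C5'"), (1, "C4'"), (1, "C3'"), (1, "O3'")])]
        dm = dihedral_matrix(traj, defs)
        hist = dm.histogram(1, "delta")
        nonzero = np.flatnonzero(hist)
        assert len(nonzero) == 1
        k = int(nonzero[0])
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)
        # the single occupied bin contains the set torsion (numeric slack at edges)
        assert dm.bin_edges[k] <= 60.0 + 1e-4 and 60.0 - 1e-4 <= dm.bin_edges[k + 1]
        assert hist[k] == 1.0

    def test_uniform_torsions_fill_bins_uniformly(self):
        rng = np.random.default_rng(17)
        angles = rng.uniform(-180.0, 180.0, size=100_000)
        traj = self._torsion_traj(angles)
        defs = [DihedralDefinition("delta", 1,
                                   [(1, "C5'"), (1, "C4'"), (1, "C3'"), (1, "O3'")])]
        dm = dihedral_matrix(traj, defs)
        hist = dm.histogram(1, "delta")
        p = 1.0 / 24.0
        se = np.sqrt(p * (1 - p) / len(angles))
        assert np.all(np.abs(hist - p) <= 3 * se)

    def test_missing_atoms_marked_undefined(self):
        traj = self._torsion_traj([10.0, 20.0])
        defs = enumerate_backbone_dihedrals(parse_sequence("G"))
        dm = dihedral_matrix(traj, defs)
        assert np.isnan(dm.histogram(1, "gamma")).all()   # O5' absent in topology
        assert not np.isnan(dm.histogram(1, "delta")).any()

    def test_bundle_overlay_values(self, ideal_g4):
        traj = generate_fluctuating_trajectory(ideal_g4, {"all": 0.0}, 3, seed=0)
        bundle = EnsembleBundle([ideal_g4, ideal_g4])
        defs = enumerate_backbone_dihedrals(parse_sequence("G" * 12))
        dm = dihedral_matrix(traj, defs, bundle)
        i = int(np.flatnonzero(dm.resids == 2)[0])
        j = dm.names.index("delta")
        assert dm.overlay.shape[-1] == 2
        assert np.isfinite(dm.overlay[i, j]).all()
        assert dm.overlay[i, j, 0] == pytest.approx(dm.overlay[i, j, 1])
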