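"""Ion-atmosphere RDF/SDF, channel occupancy and binding free energy."""

import numpy as np
import pytest

from g4validate.core import StructureModel, TrajectorySet
from g4validate.ions import (GAS_CONSTANT, binding_free_energy,
                             classify_channel_states, rdf_com, sdf_grid)
from g4validate.synthetic import (SyntheticSpec, build_system,
                                  generate_fluctuating_trajectory, inject_ion_entry)


def _particles_model(n_particles, extra_solute=True):
    names, resids, resnames, elements = [], [], [], []
    if extra_solute:
        for i, nm in enumerate(["C1", "C2", "C3", "C4"]):
            names.append(nm)
            resids.append(1)
            resnames.append("SOL")
            elements.append("C")
    for k in range(n_particles):
        names.append("K")
        resids.append(k + 2)
        resnames.append("K")
        elements.append("K")
    return names, resids, resnames, elements


def _uniform_gas_traj(n_particles=20000, n_frames=10, edge=80.0, seed=13):
    """Static tetrahedral solute at the box centre plus uniform ideal-gas ions."""
    names, resids, resnames, elements = _particles_model(n_particles)
    rng = np.random.default_rng(seed)
    coords = np.empty((n_frames, 4 + n_particles, 3))
    centre = np.array([edge / 2] * 3)
    solute = centre + np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]])
    for f in range(n_frames):
        coords[f, :4] = solute
        coords[f, 4:] = rng.uniform(0.0, edge, size=(n_particles, 3))
    top = StructureModel(np.array(names, dtype=object), resids, resnames, elements,
                         coords[0])
    box = np.tile([edge, edge, edge, 90.0, 90.0, 90.0], (n_frames, 1))
    return TrajectorySet(top, coords, box=box)


class TestRDF:
    def test_ideal_gas_is_unity_within_sampling_error(self):
        traj = _uniform_gas_traj()
        rdf = rdf_com(traj, "element C", "element K", bin_width=0.5, r_max=35.0)
        n_frames = traj.n_frames
        sel = (rdf.bin_centers > 4.0) & (rdf.bin_centers < 28.0)
        expected_counts = (rdf.bulk_density * 4 * np.pi * rdf.bin_centers[sel] ** 2
                           * rdf.bin_width * n_frames)
        # three Poisson standard errors on each bin's relative count
        tol = 3.0 / np.sqrt(expected_counts) + 0.05
        assert np.all(np.abs(rdf.g[sel] - 1.0) <= tol)
        density = 20000 / 80.0 ** 3
        assert rdf.bulk_density == pytest.approx(density, rel=0.05)

    def test_two_channel_ions_integral(self, system_and_annotation):
        """A scripted two-ion channel: n(<r) beyond the peak equals 2."""
        model, _ = system_and_annotation
        traj = generate_fluctuating_trajectory(model, {"all": 0.0}, 10, seed=0,
                                               box_edge=80.0)
        rdf = rdf_com(traj, "heavy and not element K", "element K",
                      bin_width=0.1, r_max=35.0)
        assert rdf.cumulative_at(8.0) == pytest.approx(2.0, abs=1e-9)
        assert rdf.cumulative[-1] == pytest.approx(2.0, abs=1e-9)

    def test_sum_rule_counts_all_particles_within_rmax(self):
        traj = _uniform_gas_traj(n_particles=500, n_frames=3)
        rdf = rdf_com(traj, "element C", "element K", bin_width=0.5, r_max=100.0,
                      bulk_density=1.0)
        # every particle is within sqrt(3)*40 < 70 Å of the COM under PBC
        assert rdf.cumulative[-1] == pytest.approx(500.0, abs=1e-9)

    def test_zero_particles_error_free(self, static_traj):
        rdf = rdf_com(static_traj, "heavy", "resname XYZ")
        assert np.all(rdf.g == 0.0)
        assert np.isnan(rdf.bulk_density)

    def test_bulk_shell_must_fit_in_box(self, system_and_annotation):
        model, _ = system_and_annotation
        traj = generate_fluctuating_trajectory(model, {"all": 0.0}, 2, seed=0,
                                               box_edge=40.0)
        with pytest.raises(ValueError, match="shell"):
            rdf_com(traj, "heavy and not element K", "element K")

    def test_rotation_invariance(self, system_and_annotation):
        from tests.conftest import rotation_matrix
        model, _ = system_and_annotation
        traj = generate_fluctuating_trajectory(model, {"all": 0.1}, 5, seed=2)
        rot = rotation_matrix(4)
        moved = TrajectorySet(traj.topology, traj.coordinates @ rot.T, traj.times)
        a = rdf_com(traj, "heavy and not element K", "element K", bulk_density=1e-3)
        b = rdf_com(moved, "heavy and not element K", "element K", bulk_density=1e-3)
        assert np.allclose(a.g, b.g, atol=1e-9)


class TestSDF:
    def _single_particle_traj(self, n_frames=4):
        top = StructureModel(np.array(["K"], dtype=object), [1], ["K"], ["K"],
                             [[3.3, 4.4, 5.5]])
        coords = np.broadcast_to(top.xyz, (n_frames, 1, 3)).copy()
        return TrajectorySet(top, coords)

    def test_single_fixed_particle_occupies_one_voxel(self):
        traj = self._single_particle_traj()
        grid = sdf_grid(traj, "element K", reference_density=0.033456)
        assert np.count_nonzero(grid.values) == 1
        assert grid.values.max() == pytest.approx(1.0 / (0.033456 * 0.125))
        assert grid.raw_counts.sum() == traj.n_frames  # mean particles x frames

    def test_doubling_reference_density_halves_values(self):
        traj = self._single_particle_traj()
        a = sdf_grid(traj, "element K", reference_density=0.02)
        b = sdf_grid(traj, "element K", reference_density=0.04)
        assert np.allclose(a.values, 2.0 * b.values)

    def test_uniform_particles_at_reference_density_mean_one(self):
        rng = np.random.default_rng(23)
        n, edge, frames = 6000, 25.0, 4
        names = ["K"] * n
        top = StructureModel(np.array(names, dtype=object), np.arange(1, n + 1),
                             ["K"] * n, ["K"] * n, rng.uniform(0, edge, (n, 3)))
        coords = rng.uniform(0, edge, (frames, n, 3))
        traj = TrajectorySet(top, coords)
        density = n / edge ** 3
        grid = sdf_grid(traj, "element K", reference_density=density, padding=0.0)
        assert grid.values.mean() == pytest.approx(1.0, rel=0.03)

    def test_invalid_parameters_rejected(self):
        traj = self._single_particle_traj()
        with pytest.raises(ValueError):
            sdf_grid(traj, "element K", voxel_volume=0.0)
        with pytest.raises(ValueError):
            sdf_grid(traj, "element K", reference_density=-1.0)

    def test_dx_output_round_trips_values(self, tmp_path):
        traj = self._single_particle_traj()
        grid = sdf_grid(traj, "element K")
        path = tmp_path / "grid.dx"
        grid.write_dx(path)
        text = path.read_text()
        assert "gridpositions" in text
        data = [float(x) for line in text.splitlines()
                if line and line[0] in "0123456789.-" for x in line.split()]
        assert max(data) == pytest.approx(grid.values.max(), rel=1e-5)


class TestChannelStates:
    def test_midpoint_ion_is_cavity(self, system_and_annotation, static_traj):
        _, ann = system_and_annotation
        occ = classify_channel_states(static_traj, ann.tetrads)
        # both built-in channel ions sit at inter-plane midpoints
        assert np.all(occ.states == "cavity")
        assert np.all(occ.bound_count == 2)
        assert occ.events.empty

    def test_far_ion_is_bulk_with_zero_events(self, system_and_annotation):
        model, ann = system_and_annotation
        traj = generate_fluctuating_trajectory(model, {"all": 0.0}, 8, seed=0)
        ion = int(model.resids[model.indices("element K")[0]])
        moved = inject_ion_entry(traj, ion, [(0, "bulk")], ann.tetrads)
        occ = classify_channel_states(moved, ann.tetrads)
        k = occ.ion_resids.index(ion)
        assert set(occ.states[k]) == {"bulk"}
        assert not (occ.events.ion == ion).any()

    def test_scheduled_fractions_recovered_exactly(self, system_and_annotation):
        model, ann = system_and_annotation
        traj = generate_fluctuating_trajectory(model, {"all": 0.0}, 40, seed=0)
        ion = int(model.resids[model.indices("element K")[0]])
        schedule = [(0, "bulk"), (10, "approach"), (20, "in-plane"), (30, "cavity")]
        moved = inject_ion_entry(traj, ion, schedule, ann.tetrads)
        occ = classify_channel_states(moved, ann.tetrads)
        fr = occ.state_fractions(ion)
        assert fr == {"bulk": 0.25, "approach": 0.25, "in-plane": 0.25, "cavity": 0.25}
        mine = occ.events[occ.events.ion == ion]
        assert list(mine.frame) == [10, 20, 30]

    def test_fewer_than_two_tetrads_rejected(self, static_traj, system_and_annotation):
        _, ann = system_and_annotation
        with pytest.raises(ValueError, match="two tetrads"):
            classify_channel_states(static_traj, ann.tetrads[:1])


class TestBindingFreeEnergy:
    def _occupancy(self, n_bound, n_unbound):
        from g4validate.ions import ChannelOccupancy
        import pandas as pd
        states = np.array([["cavity"] * n_bound + ["bulk"] * n_unbound], dtype=object)
        return ChannelOccupancy([1], states, (states == "cavity").sum(axis=0),
                                pd.DataFrame(columns=["ion", "frame", "from_state", "to_state"]),
                                np.arange(n_bound + n_unbound, dtype=float))

    def test_even_split_gives_zero(self):
        free = binding_free_energy(self._occupancy(50, 50))
        assert free.equilibrium_constant == 1.0
        assert free.delta_g_kj_mol == pytest.approx(0.0, abs=1e-12)

    def test_seventy_percent_bound(self):
        free = binding_free_energy(self._occupancy(70, 30), temperature=300.0)
        expected = -GAS_CONSTANT * 300.0 * np.log(7.0 / 3.0) / 1000.0
        assert free.delta_g_kj_mol == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-2.11, abs=0.005)

    def test_all_bound_is_flagged_one_sided(self):
        free = binding_free_energy(self._occupancy(10, 0))
        assert free.one_sided and free.delta_g_kj_mol is None

    def test_antisymmetric_under_class_swap(self):
        occ = self._occupancy(30, 70)
        a = binding_free_energy(occ, bound_states=("cavity",))
        b = binding_free_energy(occ, bound_states=("bulk", "approach", "in-plane"))
        assert a.delta_g_kj_mol == pytest.approx(-b.delta_g_kj_mol, abs=1e-12)
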