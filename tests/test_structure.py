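import numpy as np
import pandas as pd
import pytest

from npmicroenv import (
    Frame,
    Trajectory,
    center_of_mass,
    classify_peptide_location,
    core_composition,
    detect_burn_in,
    estimate_core_radius,
    find_largest_aggregate,
    generate_trajectory,
    radial_density_profile,
    radius_of_gyration,
)
from npmicroenv.structure import DensityProfile
from npmicroenv.pbc import min_image_distance

from conftest import make_topology


def single_species_topology(n, species="W", mol_per_bead=True):
    return make_topology([
        (i if mol_per_bead else 0, "water", species, "none", 0) for i in range(n)
    ])


class TestComRg:
    def test_single_bead_com_is_its_position(self):
        topo = single_species_topology(1)
        frame = Frame(0.0, [[1.0, 2.0, 3.0]], [100.0] * 3)
        np.testing.assert_allclose(center_of_mass(frame, topo, [0]), [1, 2, 3])

    def test_equal_masses_at_plus_minus_x_average_to_origin(self):
        topo = single_species_topology(2)
        frame = Frame(0.0, [[52.0, 50, 50], [48.0, 50, 50]], [100.0] * 3)
        np.testing.assert_allclose(center_of_mass(frame, topo, [0, 1]), [50, 50, 50])

    def test_com_matches_naive_summation(self):
        rng = np.random.default_rng(0)
        n = 200
        topo = make_topology([(i, "water", "W", "none", 0) for i in range(n)])
        # vary masses through the table
        table = topo.table.assign(mass=rng.uniform(40, 90, n))
        from npmicroenv import Topology
        topo = Topology(table)
        pos = 40 + rng.random((n, 3)) * 20  # compact: no wrap ambiguity
        frame = Frame(0.0, pos, [100.0] * 3)
        naive = (pos * topo.mass[:, None]).sum(axis=0) / topo.mass.sum()
        np.testing.assert_allclose(
            center_of_mass(frame, topo, np.arange(n)), naive, rtol=1e-10
        )

    def test_rg_trivial_cases(self):
        topo = single_species_topology(2)
        one = Frame(0.0, [[5.0, 5, 5], [7.0, 5, 5]], [100.0] * 3)
        assert radius_of_gyration(one, topo, [0]) == 0.0
        assert radius_of_gyration(one, topo, [0, 1]) == pytest.approx(1.0)

    def test_rg_uniform_sphere_analytic_limit(self):
        # R * sqrt(3/5) for a solid sphere
        rng = np.random.default_rng(3)
        n, radius = 100_000, 50.0
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        r = radius * rng.random(n) ** (1 / 3)
        pos = 200.0 + dirs * r[:, None]
        topo = make_topology([(0, "water", "W", "none", 0)] * 1)
        from npmicroenv import Topology
        topo = Topology(pd.concat([topo.table] * n).assign(bead_id=np.arange(n),
                                                           molecule_id=np.arange(n)))
        frame = Frame(0.0, pos, [400.0] * 3)
        expected = radius * np.sqrt(3 / 5)
        assert radius_of_gyration(frame, topo, np.arange(n)) == pytest.approx(
            expected, rel=5e-3
        )

    def test_empty_selection_errors(self):
        topo = single_species_topology(1)
        frame = Frame(0.0, [[0.0, 0, 0]], [10.0] * 3)
        with pytest.raises(ValueError):
            center_of_mass(frame, topo, [])
        with pytest.raises(ValueError):
            radius_of_gyration(frame, topo, [])


class TestAggregate:
    @staticmethod
    def molecules(positions_by_mol):
        rows, coords = [], []
        for mol, beads in enumerate(positions_by_mol):
            for b in beads:
                rows.append((mol, "polymer", "EO", "PEG", len([r for r in rows
                                                               if r[0] == mol])))
                coords.append(b)
        topo = make_topology(rows)
        return topo, Frame(0.0, np.array(coords, float), [500.0] * 3)

    def test_distant_molecules_are_separate(self):
        topo, frame = self.molecules([[[10, 10, 10]], [[210, 10, 10]]])
        assert find_largest_aggregate(frame, topo, 6.0) == {0}

    def test_dense_sphere_is_one_aggregate(self):
        rng = np.random.default_rng(1)
        mols = [[(250 + rng.normal(0, 3), 250 + rng.normal(0, 3), 250 + rng.normal(0, 3))
                 for _ in range(3)] for _ in range(10)]
        topo, frame = self.molecules(mols)
        assert find_largest_aggregate(frame, topo, 8.0) == set(range(10))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_union_find(self, seed):
        rng = np.random.default_rng(seed)
        n_mol, beads_per = 20, 3
        box = 100.0
        mols = [rng.random((beads_per, 3)) * box for _ in range(n_mol)]
        topo, frame = self.molecules([m.tolist() for m in mols])
        cutoff = 15.0
        # O(N^2) oracle: union-find over the full pairwise distance matrix
        parent = list(range(n_mol))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        pos = frame.positions.reshape(n_mol, beads_per, 3)
        for a in range(n_mol):
            for b in range(a + 1, n_mol):
                d = min_image_distance(
                    pos[a][:, None, :], pos[b][None, :, :], frame.box
                )
                if (d < cutoff).any():
                    parent[find(a)] = find(b)
        comps = {}
        for m in range(n_mol):
            comps.setdefault(find(m), set()).add(m)
        largest = max(comps.values(), key=lambda c: (len(c), -min(c)))
        assert find_largest_aggregate(frame, topo, cutoff) == largest


class TestDensityProfile:
    def test_single_occupied_shell(self):
        # beads all at the same radius from the COM-defining polymer center
        rows = [(0, "polymer", "EO", "PEG", i) for i in range(2)]
        rows += [(1, "water", "W", "none", 0)] * 8
        topo = make_topology(rows)
        center = np.full(3, 50.0)
        water = center + np.array(
            [[7, 0, 0], [-7, 0, 0], [0, 7, 0], [0, -7, 0],
             [0, 0, 7], [0, 0, -7], [7 / np.sqrt(2), 7 / np.sqrt(2), 0],
             [-7 / np.sqrt(2), 0, 7 / np.sqrt(2)]]
        )
        pos = np.vstack([[center, center + [0.5, 0, 0]], water])
        traj = Trajectory(topo, [Frame(0.0, pos, [100.0] * 3)])
        prof = radial_density_profile(
            traj, {"W": topo.select(species="W")}, bin_width=2.0, r_max=20.0
        )
        vol = 4 / 3 * np.pi * (8.0**3 - 6.0**3)
        densities = prof.densities["W"]
        assert densities[3] == pytest.approx(8 / vol)
        assert np.count_nonzero(densities) == 1

    def test_conservation_identity(self, small_system):
        _, traj, _ = small_system
        topo = traj.topology
        groups = {s: topo.select(species=s) for s in ("LA", "GA", "EO")}
        prof = radial_density_profile(traj, groups, bin_width=2.0)
        # sum(density x shell volume) equals the frame-averaged bead count
        # inside the profiled range, exactly
        for s, beads in groups.items():
            counts = []
            from npmicroenv.structure import np_center_of_mass
            for fr in traj.frames:
                com = np_center_of_mass(fr, topo)
                d = min_image_distance(fr.positions[beads], com, fr.box)
                counts.append(np.sum(d < prof.bin_edges[-1] + prof.interface_offset))
            np.testing.assert_allclose(
                prof.mean_counts(s), np.mean(counts), rtol=1e-9
            )


class TestCoreRadius:
    @staticmethod
    def step_profile(radius=70.0, bin_width=2.0, eo_peak=None):
        edges = np.arange(0, 101, bin_width, dtype=float)
        centers = 0.5 * (edges[:-1] + edges[1:])
        la = np.where(centers < radius, 0.02, 0.0)
        dens = {"LA": la, "GA": la * 0.8}
        if eo_peak is not None:
            eo = np.exp(-((centers - eo_peak) ** 2) / 8.0) * 0.01
            dens["EO"] = eo
        return DensityProfile(bin_edges=edges, densities=dens, frame_count=1)

    def test_step_function_boundary_detected(self):
        est = estimate_core_radius(self.step_profile(70.0))
        assert abs(est.core_radius - 70.0) <= 2.0

    def test_interface_width_from_eo_peak(self):
        est = estimate_core_radius(self.step_profile(70.0, eo_peak=75.0))
        assert est.eo_peak_radius == pytest.approx(75.0, abs=1.0)
        assert est.interface_width == pytest.approx(
            abs(est.core_radius - est.eo_peak_radius)
        )

    def test_recovers_planted_core_radius(self, small_system):
        params, traj, gt = small_system
        topo = traj.topology
        groups = {s: topo.select(species=s) for s in ("LA", "GA", "EO")}
        prof = radial_density_profile(traj, groups, bin_width=2.0)
        est = estimate_core_radius(prof)
        assert abs(est.core_radius - gt.true_core_radius) <= 5.0

    def test_no_core_raises(self):
        prof = self.step_profile(70.0)
        prof.densities["LA"][:] = 0.0
        prof.densities["GA"][:] = 0.0
        with pytest.raises(ValueError, match="no core"):
            estimate_core_radius(prof)


class TestComposition:
    def test_constructed_70_30_split(self):
        rows = [(0, "polymer", "LA", "PLGA", i) for i in range(70)]
        rows += [(1, "polymer", "EO", "PEG", i) for i in range(30)]
        topo = make_topology(rows)
        rng = np.random.default_rng(0)
        pos = 50.0 + rng.normal(0, 3, size=(100, 3))
        traj = Trajectory(topo, [Frame(0.0, pos, [100.0] * 3),
                                 Frame(1.0, pos, [100.0] * 3)])
        comp = core_composition(traj, core_radius=30.0)
        assert comp["PLGA"] == pytest.approx(70.0)
        assert comp["PEG"] == pytest.approx(30.0)
        assert comp.sum() == pytest.approx(100.0, abs=1e-9)

    def test_percentages_sum_to_100(self, small_system):
        params, traj, _ = small_system
        comp = core_composition(traj, params.core_radius)
        assert comp.sum() == pytest.approx(100.0, abs=1e-6)

    def test_recovers_planted_composition(self, small_system):
        params, traj, gt = small_system
        topo = traj.topology
        comp = core_composition(traj, gt.true_core_radius)
        # planted truth from the generated frame-0 geometry (box center)
        frame = traj.frames[0]
        center = np.full(3, params.box / 2)
        d = min_image_distance(frame.positions, center, frame.box)
        in_core = d < gt.true_core_radius
        cats = {
            "PLGA": np.isin(topo.species, ("LA", "GA")),
            "PEG": topo.species == "EO",
            "peptide": topo.molecule_class == "peptide",
            "water": topo.molecule_class == "water",
        }
        total = sum(int((mask & in_core).sum()) for mask in cats.values())
        for name, mask in cats.items():
            planted = 100.0 * (mask & in_core).sum() / total
            assert comp[name] == pytest.approx(planted, abs=2.0)


class TestBurnIn:
    def test_static_trajectory_burn_in_zero(self, tiny_params):
        from npmicroenv import generate_trajectory
        traj, _ = generate_trajectory(tiny_params(n_frames=15, frame_noise=0.0))
        trace = detect_burn_in(traj, 30.0)
        assert trace.burn_in_frame == 0

    def test_step_change_detected_in_window(self):
        # constructed trace: a shell-fraction step at frame 25 of 100.  The
        # running-mean criterion admits at most eps*(T-t0)/delta pre-step
        # frames; with tolerance 4e-3 and a ~0.44 outer-shell step that
        # bound is below one frame, so detection must land at the step
        n = 1600
        rows = [(0, "polymer", "LA", "PLGA", i) for i in range(n)]
        topo = make_topology(rows)
        rng = np.random.default_rng(5)
        frames = []
        for t in range(100):
            r_scale = 1.6 if t < 25 else 1.0
            dirs = rng.normal(size=(n, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            radii = 30.0 * r_scale * rng.random(n) ** (1 / 3)
            pos = 100.0 + dirs * radii[:, None]
            frames.append(Frame(float(t), pos, [200.0] * 3))
        traj = Trajectory(topo, frames)
        trace = detect_burn_in(traj, 30.0, tolerance=0.004)
        assert 25 <= trace.burn_in_frame <= 35

    def test_too_few_frames_raises(self, tiny_params):
        from npmicroenv import generate_trajectory
        traj, _ = generate_trajectory(tiny_params(n_frames=5))
        with pytest.raises(ValueError, match="10 frames"):
            detect_burn_in(traj, 30.0)

    def test_shell_fractions_bounded(self, small_system):
        params, traj, _ = small_system
        trace = detect_burn_in(traj, params.core_radius)
        assert np.all(trace.fractions >= 0)
        assert np.all(trace.fractions.sum(axis=1) <= 1 + 1e-12)


class TestPeptideLocation:
    def test_recovers_planted_two_core_thirteen_interface(self, small_system):
        params, traj, gt = small_system
        locations = classify_peptide_location(traj, params.core_radius)
        counts = locations.value_counts().to_dict()
        assert counts == {"interface": 13, "core": 2}
        peps = traj.topology.molecules_of_class("peptide")
        for mol, planted in zip(peps, gt.peptide_locations):
            assert locations[int(mol)] == planted

    def test_no_peptides_raises(self, tiny_params):
        traj, _ = generate_trajectory(tiny_params())
        with pytest.raises(ValueError, match="peptide"):
            classify_peptide_location(traj, 30.0)
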