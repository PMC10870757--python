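import numpy as np
import pandas as pd
import pytest

from npmicroenv import (
    BootstrapSpec,
    Frame,
    Trajectory,
    contact_enrichment,
    count_contacts,
    environment_acf,
    local_environment,
    per_residue_contact_difference,
)
from npmicroenv.contacts import moving_block_bootstrap_ci
from npmicroenv.pbc import min_image_distance, pairs_within

from conftest import make_topology


def water_topology(n):
    return make_topology([(i, "water", "W", "none", 0) for i in range(n)])


class TestCountContacts:
    def test_pair_inside_cutoff(self):
        topo = water_topology(2)
        frame = Frame(0.0, [[10.0, 10, 10], [15.0, 10, 10]], [100.0] * 3)
        assert count_contacts(frame, topo, {0}, {1}, cutoff=6.0) == 1

    def test_pair_exactly_at_cutoff_excluded(self):
        # strict inequality at the boundary
        topo = water_topology(2)
        frame = Frame(0.0, [[10.0, 10, 10], [16.0, 10, 10]], [100.0] * 3)
        assert count_contacts(frame, topo, {0}, {1}, cutoff=6.0) == 0

    def test_periodic_image_counted(self):
        topo = water_topology(2)
        frame = Frame(0.0, [[1.0, 50, 50], [99.0, 50, 50]], [100.0] * 3)
        assert count_contacts(frame, topo, {0}, {1}, cutoff=3.0) == 1

    def test_overlapping_groups_rejected(self):
        topo = water_topology(3)
        frame = Frame(0.0, np.zeros((3, 3)) + 50, [100.0] * 3)
        with pytest.raises(ValueError, match="disjoint"):
            count_contacts(frame, topo, {0, 1}, {1, 2}, cutoff=6.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        box = 60.0
        topo = water_topology(n)
        pos = rng.random((n, 3)) * box
        frame = Frame(0.0, pos, [box] * 3)
        a = np.arange(0, 200)
        b = np.arange(200, n)
        cutoff = 5.0
        d = min_image_distance(pos[a][:, None, :], pos[b][None, :, :], frame.box)
        expected = int((d < cutoff).sum())
        assert count_contacts(frame, topo, a, b, cutoff) == expected


class TestLocalEnvironment:
    def peptide_and_polymer(self, polymer_positions):
        rows = [(0, "peptide", "ALA", "none", 0)]
        rows += [(1, "polymer", "EO", "PEG", i) for i in range(len(polymer_positions))]
        topo = make_topology(rows)
        pos = np.vstack([[[50.0, 50, 50]], polymer_positions])
        return topo, Frame(0.0, pos, [100.0] * 3)

    def test_isolated_peptide_has_empty_environment(self):
        topo, frame = self.peptide_and_polymer([[90.0, 90, 90], [10.0, 10, 10]])
        assert local_environment(frame, topo, 0, cutoff=6.0) == set()

    def test_single_bead_within_half_cutoff(self):
        topo, frame = self.peptide_and_polymer([[53.0, 50, 50], [90.0, 90, 90]])
        assert local_environment(frame, topo, 0, cutoff=6.0) == {1}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        poly = rng.random((100, 3)) * 100
        topo, frame = self.peptide_and_polymer(poly.tolist())
        cutoff = 10.0
        d = min_image_distance(poly, np.array([50.0, 50, 50]), frame.box)
        expected = set((np.flatnonzero(d < cutoff) + 1).tolist())
        assert local_environment(frame, topo, 0, cutoff) == expected


class TestPerResidueDifference:
    @staticmethod
    def build(core_water, iface_water):
        """Two one-residue peptides with fixed numbers of water neighbors."""
        rows = [(0, "peptide", "ALA", "none", 0), (1, "peptide", "ALA", "none", 0)]
        n_w = core_water + iface_water
        rows += [(2 + i, "water", "W", "none", 0) for i in range(n_w)]
        topo = make_topology(rows)
        pos = [[20.0, 50, 50], [80.0, 50, 50]]
        for i in range(core_water):
            pos.append([20.0 + 2 + 0.1 * i, 50, 50])
        for i in range(iface_water):
            pos.append([80.0 + 2 + 0.1 * i, 50, 50])
        frame = Frame(0.0, np.array(pos), [200.0] * 3)
        return Trajectory(topo, [frame, Frame(1.0, np.array(pos), [200.0] * 3)])

    def test_constructed_difference(self):
        traj = self.build(core_water=3, iface_water=5)
        diff = per_residue_contact_difference(traj, [0], [1], "water", cutoff=6.0)
        assert diff["ALA"] == pytest.approx(-2.0)

    def test_identical_environments_give_zero(self):
        traj = self.build(core_water=4, iface_water=4)
        diff = per_residue_contact_difference(traj, [0], [1], "water", cutoff=6.0)
        assert diff["ALA"] == pytest.approx(0.0)

    def test_inconsistent_sequences_rejected(self):
        rows = [(0, "peptide", "ALA", "none", 0), (1, "peptide", "GLU", "none", 0),
                (2, "water", "W", "none", 0)]
        topo = make_topology(rows)
        frame = Frame(0.0, np.zeros((3, 3)) + 50, [100.0] * 3)
        traj = Trajectory(topo, [frame])
        with pytest.raises(ValueError, match="sequence"):
            per_residue_contact_difference(traj, [0], [1], "water")

    def test_group_difference_matches_direct_count(self, small_system):
        # the summed per-residue difference must equal the difference of the
        # groups' mean total polymer contacts, counted independently
        params, traj, gt = small_system
        topo = traj.topology
        peps = topo.molecules_of_class("peptide")
        core = [int(m) for m, l in zip(peps, gt.peptide_locations) if l == "core"]
        iface = [int(m) for m, l in zip(peps, gt.peptide_locations) if l == "interface"]
        short = Trajectory(topo, [f.copy() for f in traj.frames[:10]])
        diff = per_residue_contact_difference(short, core, iface, "polymer")
        poly = topo.select(molecule_class="polymer")

        def mean_total(group):
            totals = []
            for fr in short.frames:
                for m in group:
                    totals.append(count_contacts(
                        fr, topo, set(topo.beads_of_molecule(m)), set(poly), 6.0
                    ))
            return np.mean(totals)

        n_res_per_label = 4  # 16-bead cargo, 4 residues of each label
        expected = (mean_total(core) - mean_total(iface)) / n_res_per_label
        assert diff.sum() == pytest.approx(expected, rel=1e-9)


class TestContactEnrichment:
    @staticmethod
    def build_proportional():
        """Environment {LA:50, GA:30, EO:20}; the peptide's 10 beads are
        placed so contacts are {25, 15, 10} - exactly proportional."""
        rows = [(0, "peptide", "ALA", "none", i) for i in range(10)]
        species = ["LA"] * 50 + ["GA"] * 30 + ["EO"] * 20
        rows += [(1 + i, "polymer", s, "PLGA" if s != "EO" else "PEG", 0)
                 for i, s in enumerate(species)]
        topo = make_topology(rows)
        pos = np.zeros((110, 3))
        # peptide beads stacked: every contacting env bead pairs with all 10,
        # scaling all counts uniformly and leaving the shares untouched
        pos[:10] = [500.0, 500, 500]
        pos[:10, 0] += np.arange(10) * 0.01
        counts = {"LA": 25, "GA": 15, "EO": 10}
        offsets = iter(np.linspace(0, 2 * np.pi, 61)[:-1])
        by_species = {s: [i for i, sp in enumerate(species) if sp == s]
                      for s in ("LA", "GA", "EO")}
        for s, indices in by_species.items():
            for j, i_env in enumerate(indices):
                if j < counts[s]:
                    th = next(offsets)
                    pos[10 + i_env] = [500 + 3 * np.cos(th),
                                       500 + 3 * np.sin(th), 500.3]
                else:
                    pos[10 + i_env] = [100.0 + i_env, 50, 50]
        frame = Frame(0.0, pos, [1000.0] * 3)
        return topo, Trajectory(topo, [frame, Frame(1.0, pos.copy(), [1000.0] * 3)])

    def test_proportional_contacts_give_unit_enrichment(self):
        topo, traj = self.build_proportional()
        env = topo.select(molecule_class="polymer")
        res = contact_enrichment(
            traj, [0], env, ["LA", "GA", "EO"], cutoff=6.0,
            ci=BootstrapSpec(n_resamples=100, seed=0),
        )
        for s in ("LA", "GA", "EO"):
            assert res.value(s) == pytest.approx(1.0, abs=1e-9)

    def test_exclusive_contacts_scale_inverse_abundance(self):
        # contacts only with EO; abundance share of EO = 0.2 -> e_EO = 5
        rows = [(0, "peptide", "ALA", "none", 0)]
        species = ["LA"] * 40 + ["GA"] * 40 + ["EO"] * 20
        rows += [(1 + i, "polymer", s, "PLGA" if s != "EO" else "PEG", 0)
                 for i, s in enumerate(species)]
        topo = make_topology(rows)
        pos = np.zeros((101, 3)) + 400.0
        pos[0] = [50.0, 50, 50]
        for i, s in enumerate(species):
            pos[1 + i] = [52.0 + 0.001 * i, 50, 50] if s == "EO" else [300.0 + i, 50, 50]
        traj = Trajectory(topo, [Frame(0.0, pos, [1000.0] * 3)])
        res = contact_enrichment(traj, [0], topo.select(molecule_class="polymer"),
                                 ["LA", "GA", "EO"], cutoff=6.0,
                                 ci=BootstrapSpec(n_resamples=50, seed=0))
        assert res.value("EO") == pytest.approx(5.0)
        assert res.value("LA") == pytest.approx(0.0)
        assert res.value("GA") == pytest.approx(0.0)

    def test_point_estimate_invariant_under_frame_duplication(self):
        topo, traj = self.build_proportional()
        doubled = Trajectory(topo, [f.copy() for f in traj.frames] + [
            Frame(f.time + 10.0, f.positions.copy(), f.box.copy())
            for f in traj.frames
        ])
        env = topo.select(molecule_class="polymer")
        kw = dict(species_list=["LA", "GA", "EO"], cutoff=6.0,
                  ci=BootstrapSpec(n_resamples=50, seed=0))
        r1 = contact_enrichment(traj, [0], env, **kw)
        r2 = contact_enrichment(doubled, [0], env, **kw)
        np.testing.assert_allclose(r1.table["value"], r2.table["value"])

    def test_abundance_weighted_mean_is_unity(self, small_system):
        # sum_s (n_s/n) = sum_s (B_s/B) = 1, so the B-weighted mean of e_s is 1
        params, traj, gt = small_system
        topo = traj.topology
        from npmicroenv import radial_shell_region
        region = radial_shell_region(
            params.core_radius - 10, params.core_radius + 10,
            beads=topo.select(molecule_class="polymer"),
        )
        peps = topo.molecules_of_class("peptide")
        iface = [int(m) for m, l in zip(peps, gt.peptide_locations) if l == "interface"]
        short = Trajectory(topo, [f.copy() for f in traj.frames[:8]])
        res = contact_enrichment(short, iface, region, ["LA", "GA", "EO"],
                                 cutoff=6.0, ci=BootstrapSpec(n_resamples=50))
        for t, fr in enumerate(short.frames):
            e = res.per_frame[t]
            if np.all(np.isnan(e)):
                continue
            env = region(fr, topo)
            sp = topo.species[env]
            B = np.array([(sp == s).sum() for s in ("LA", "GA", "EO")], float)
            w = B / B.sum()
            ok = ~np.isnan(e)
            assert np.nansum(e[ok] * w[ok]) == pytest.approx(1.0, abs=1e-9)


class TestEnvironmentACF:
    def test_frozen_trajectory_is_fully_correlated(self, tiny_params):
        from npmicroenv import generate_trajectory
        params = tiny_params(n_peptides=2, n_frames=8, frame_noise=0.0)
        traj, _ = generate_trajectory(params)
        pep = traj.topology.molecules_of_class("peptide")[0]
        acf = environment_acf(traj, int(pep), cutoff=8.0, max_lag=5)
        np.testing.assert_allclose(acf.acf, 1.0)

    def test_disjoint_consecutive_environments_decay_to_zero(self):
        rows = [(0, "peptide", "ALA", "none", 0)]
        rows += [(1, "polymer", "EO", "PEG", 0), (2, "polymer", "EO", "PEG", 0)]
        topo = make_topology(rows)
        frames = []
        for t in range(6):
            pos = np.array([[50.0, 50, 50], [53.0, 50, 50], [150.0, 50, 50]])
            if t % 2:
                pos[[1, 2]] = pos[[2, 1]]
            frames.append(Frame(float(t), pos, [400.0] * 3))
        traj = Trajectory(topo, frames)
        acf = environment_acf(traj, 0, cutoff=6.0, max_lag=3)
        assert acf.acf[0] == 1.0
        assert acf.acf[1] == 0.0
        assert acf.acf[2] == 1.0

    def test_two_state_markov_matches_enumeration(self):
        # environment flips between two disjoint single-bead sets with
        # probability p per step; the ACF equals the probability of an even
        # number of flips in tau steps: (1 + (1-2p)^tau) / 2
        rng = np.random.default_rng(11)
        p = 0.3
        n_frames = 4000
        rows = [(0, "peptide", "ALA", "none", 0)]
        rows += [(1, "polymer", "EO", "PEG", 0), (2, "polymer", "EO", "PEG", 0)]
        topo = make_topology(rows)
        state = 0
        frames = []
        states = []
        for t in range(n_frames):
            if rng.random() < p:
                state = 1 - state
            states.append(state)
            pos = np.array([[50.0, 50, 50], [150.0, 50, 50], [150.0, 50, 50]])
            pos[1 + state] = [53.0, 50, 50]
            frames.append(Frame(float(t), pos, [400.0] * 3))
        traj = Trajectory(topo, frames)
        max_lag = 6
        acf = environment_acf(traj, 0, cutoff=6.0, max_lag=max_lag)
        states = np.array(states)
        for tau in range(max_lag + 1):
            empirical = np.mean(states[: n_frames - tau] == states[tau:]) if tau else 1.0
            assert acf.acf[tau] == pytest.approx(empirical, abs=1e-12)
            theoretical = (1 + (1 - 2 * p) ** tau) / 2
            assert acf.acf[tau] == pytest.approx(theoretical, abs=0.05)

    def test_max_lag_must_be_shorter_than_trajectory(self, tiny_params):
        from npmicroenv import generate_trajectory
        traj, _ = generate_trajectory(tiny_params(n_peptides=1, n_frames=5))
        pep = traj.topology.molecules_of_class("peptide")[0]
        with pytest.raises(ValueError):
            environment_acf(traj, int(pep), max_lag=5)


class TestBootstrap:
    def test_ci_reproducible_and_ordered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 1.0, size=(200, 2))
        spec = BootstrapSpec(block_length=10, n_resamples=500, seed=3)
        lo1, hi1 = moving_block_bootstrap_ci(x, spec)
        lo2, hi2 = moving_block_bootstrap_ci(x, spec)
        np.testing.assert_array_equal(lo1, lo2)
        assert np.all(lo1 < hi1)
        assert np.all(lo1 < 5.1) and np.all(hi1 > 4.9)

    def test_nan_frames_ignored(self):
        x = np.full(50, np.nan)
        x[10:40] = 2.0
        lo, hi = moving_block_bootstrap_ci(x, BootstrapSpec(block_length=5,
                                                            n_resamples=200, seed=0))
        assert lo == pytest.approx(2.0)
        assert hi == pytest.approx(2.0)
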