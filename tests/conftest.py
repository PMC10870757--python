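import warnings

import numpy as np
import pandas as pd
import pytest

from npmicroenv import (
    SyntheticParams,
    Topology,
    generate_trajectory,
    scaled_params,
)
from npmicroenv.conformations import ClusterAssignment

warnings.filterwarnings("ignore", category=UserWarning)


def make_topology(rows):
    """Topology from (molecule_id, molecule_class, species, block, monomer_index) rows."""
    return Topology(pd.DataFrame(
        [
            {
                "bead_id": i,
                "molecule_id": r[0],
                "molecule_class": r[1],
                "species": r[2],
                "block": r[3],
                "monomer_index": r[4],
                "mass": 72.0,
            }
            for i, r in enumerate(rows)
        ]
    ))


def random_positions(rng, n, box):
    return rng.random((n, 3)) * box


def planted_assignment(traj, ground_truth):
    """ClusterAssignment carrying the generator's planted labels."""
    topo = traj.topology
    polymers = topo.molecules_of_class("polymer")
    rows = [
        (t, int(m), int(lab))
        for t in range(traj.n_frames)
        for m, lab in zip(polymers, ground_truth.polymer_labels)
    ]
    table = pd.DataFrame(rows, columns=["frame", "polymer_id", "label"])
    k = len(set(ground_truth.polymer_labels))
    return ClusterAssignment(table=table, k=k, noise_pct=0.0, populations=None)


@pytest.fixture(scope="session")
def small_system():
    """Desk-scale nanoparticle trajectory shared across read-only tests."""
    params = scaled_params(seed=1)
    traj, gt = generate_trajectory(params)
    return params, traj, gt


@pytest.fixture(scope="session")
def tiny_params():
    """Minimal fast configuration for tests that generate repeatedly."""
    def factory(**overrides):
        base = dict(
            n_polymers=40,
            n_peptides=0,
            n_peg_monomers=12,
            n_plga_monomers=12,
            core_radius=30.0,
            corona_thickness=12.0,
            water_nucleus_radius=8.0,
            box=120.0,
            cluster_spec=(
                (0.5, 10.0, 16.0, 1.0, "interface"),
                (0.5, 20.0, 8.0, 1.0, "interface"),
            ),
            n_frames=12,
            frame_noise=0.5,
            n_exterior_water=100,
            water_density=0.006,
        )
        base.update(overrides)
        return SyntheticParams(**base)
    return factory
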