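"""Shared fixtures: small synthetic membranes generated at test time."""

import numpy as np
import pandas as pd
import pytest

from annulipid.core import SpeciesTable, Trajectory
from annulipid.synth import MembraneSpec, simulate, write_fixture


def make_table(records):
    """SpeciesTable from (particle_id, molecule_id, species, role, residue_id)."""
    return SpeciesTable(pd.DataFrame(
        records, columns=["particle_id", "molecule_id", "species", "role",
                          "residue_id"]))


def make_traj(coords, box=(19.0, 19.0, 10.0), dt=1.0):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return Trajectory(coords, np.arange(n) * dt, np.tile(box, (n, 1)))


@pytest.fixture(scope="session")
def small_membrane():
    """Two-species membrane with an obstacle; general-stepper code path."""
    spec = MembraneSpec(
        compositions={"outer": {"POPC": 60, "POPS": 40},
                      "inner": {"POPC": 60, "POPS": 40}},
        protein_radius=0.8, n_ring_beads=8, n_frames=120, seed=42)
    return simulate(spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """716-lipid, 100-frame membrane written to GRO + XTC."""
    spec = MembraneSpec(
        compositions={"outer": {"POPC": 180, "SM": 100, "CHOL": 90},
                      "inner": {"POPC": 150, "POPS": 90, "POPE": 56, "CHOL": 50}},
        protein_radius=0.8, n_ring_beads=8,
        flip_rates={"CHOL": 2e-3}, n_frames=100, seed=7)
    traj, table, truth = simulate(spec)
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(traj, table, truth, out)
    return {"paths": paths, "traj": traj, "table": table, "truth": truth}
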