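"""Shared fixtures: small pentamer topologies and generated trajectories."""

import numpy as np
import pytest

from helixmd.model import ReplicaSet, Trajectory, pool_replicas
from helixmd.synthetic import (
    FluctuationSpec,
    make_pentamer_topology,
    gen_fluctuation_traj,
)


@pytest.fixture(scope="session")
def pentamer():
    """5 subunits x 4 residues (TYR, ASP, LYS, ALA) with reference coords."""
    return make_pentamer_topology(4, ["TYR", "ASP", "LYS", "ALA"])


@pytest.fixture(scope="session")
def fluct_traj(pentamer):
    """Isotropic sigma = 1 Å fluctuation trajectory, 5000 frames."""
    spec = FluctuationSpec(sigma=1.0, n_frames=5000, seed=11)
    return gen_fluctuation_traj(pentamer, spec)


@pytest.fixture(scope="session")
def replica_250ns(pentamer):
    """Two static 250 ns replicas at 50 ps sampling (5001 frames each)."""
    ref = pentamer.reference_coordinates
    coords = np.repeat(ref[None], 5001, axis=0)
    traj = Trajectory(pentamer, coords, dt_ps=50.0)
    return ReplicaSet({"R0": traj, "R1": traj}, analysis_window=(50.0, 250.0))


@pytest.fixture(scope="session")
def pooled_8000(replica_250ns):
    return pool_replicas(replica_250ns)
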