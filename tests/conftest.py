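import numpy as np
import pytest

from helixtraj import RegionPartition, RunEnsemble, SSTrajectory, trajectory_from_lines
from helixtraj.trajectory import ALPHABET


@pytest.fixture
def part():
    return RegionPartition.default()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_trajectory(rng, n_frames=30, n_residues=20, run_id="rnd"):
    """Uniform random labels over the full alphabet (no helix geometry)."""
    labels = rng.choice(list(ALPHABET), size=(n_frames, n_residues))
    return SSTrajectory(run_id=run_id, labels=labels)


def random_ensemble(rng, n_runs=4, n_frames=30, n_residues=20, name="rnd-ens"):
    members = [random_trajectory(rng, n_frames, n_residues, run_id=f"r{k}")
               for k in range(n_runs)]
    return RunEnsemble(name=name, members=members)


@pytest.fixture
def toy_unfolding():
    """3-frame toy: all-H, all-H, all-T; t_u at the third frame (60 ps)."""
    return trajectory_from_lines(["H" * 20, "H" * 20, "T" * 20], run_id="toy")
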