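import numpy as np
import pytest

from allodyn.synthetic import (
    EnsembleSpec,
    ToyModel,
    build_enm_dimer,
    pairwise_forces_from_model,
    sample_ensemble,
)


@pytest.fixture(scope="session")
def dimer():
    """A small C2 dimer used across the suite."""
    return build_enm_dimer(12, contact_cutoff=1.2, k_default=500.0, seed=11)


@pytest.fixture(scope="session")
def dimer_traj(dimer):
    spec = EnsembleSpec(n_replicas=3, n_frames=800, temperature=300.0, seed=5)
    return sample_ensemble(dimer, spec)


@pytest.fixture(scope="session")
def dimer_forces(dimer, dimer_traj):
    return pairwise_forces_from_model(dimer, dimer_traj)


def two_node_model(k: float = 400.0, mass: float = 100.0,
                   length: float = 1.0) -> ToyModel:
    """A single spring between two nodes — closed-form observables."""
    return ToyModel(
        positions=np.array([[0.0, 0.0, 0.0], [length, 0.0, 0.0]]),
        masses=np.array([mass, mass]),
        names=["CA", "CA"],
        resids=np.array([1, 1]),
        resnames=["GLY", "GLY"],
        chains=["A", "B"],
        hetero=np.zeros(2, dtype=bool),
        springs=np.array([[0, 1]]),
        stiffness=np.array([k]),
        eq_length=np.array([length]),
        label="pair",
    )
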