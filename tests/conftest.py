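import pytest

import tetranet as tn


@pytest.fixture(scope="session")
def default_dataset():
    """One noiseless planted-cascade dataset shared across tests."""
    return tn.generate(tn.SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def default_grn(default_dataset):
    ds = default_dataset
    traj = tn.discretize(ds.expression)
    return tn.reconstruct(ds.priors, traj, tf_list=set(ds.tf_list))
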