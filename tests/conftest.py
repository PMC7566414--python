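import numpy as np
import pytest

from bhcalib.paradigm import bh_design, task_design
from bhcalib.phantom import PhantomSpec, make_labels, make_truth, simulate_bh_run


@pytest.fixture(scope="session")
def bh_des():
    return bh_design()


@pytest.fixture(scope="session")
def task_des():
    return task_design()


@pytest.fixture(scope="session")
def labels():
    return make_labels((32, 32, 16), seed=1)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(seed=1, noise_sd_pct=0.0, drift_pct_per_run=0.0)


@pytest.fixture(scope="session")
def default_truth(labels, default_spec):
    return make_truth(labels, default_spec)


@pytest.fixture(scope="session")
def bh_run_default(labels, default_spec, default_truth, bh_des):
    run, truth = simulate_bh_run(labels, default_spec, bh_des, truth=default_truth)
    return run, truth


@pytest.fixture(scope="session")
def bh_run_noiseless(labels, noiseless_spec, default_truth, bh_des):
    run, truth = simulate_bh_run(labels, noiseless_spec, bh_des, truth=default_truth)
    return run, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
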