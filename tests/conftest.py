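import numpy as np
import pytest

import cloverdry as cd


@pytest.fixture(scope="session")
def table1():
    return cd.load_table1_fixture()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Five-cultivar noiseless trial, thresholds spread over (0.15, 0.5)."""
    profiles = [
        cd.CultivarProfile(name=f"cv{i}", ftswc_true=c)
        for i, c in enumerate([0.15, 0.25, 0.30, 0.40, 0.50])
    ]
    design = cd.ExperimentDesign(noise_sd_g=0.0, seed=11)
    return profiles, design, cd.simulate_experiment(profiles, design)


@pytest.fixture(scope="session")
def noiseless_points(noiseless_dataset):
    _, _, ds = noiseless_dataset
    return cd.build_response_points(ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
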