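import numpy as np
import pytest

import phylomorph as pm


@pytest.fixture(scope="session")
def small_sim():
    """A modest modular dataset shared by read-only tests."""
    spec = pm.SimSpec(n_species=25, specimens_per_species=3, d=2,
                      module_sizes={"head": 5, "body": 5, "tail": 4},
                      within_module_corr=0.6, between_module_corr=0.1,
                      seed=42)
    return pm.simulate_modular_shapes(spec)


@pytest.fixture(scope="session")
def small_aligned(small_sim):
    aligned = pm.gpa_align(small_sim.specimens)
    return pm.species_mean_shapes(aligned)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def triangle_pair():
    a = np.array([[0.0, 0.0], [1.0, 0.0], [0.2, 0.9]])
    b = np.array([[0.1, -0.1], [1.3, 0.2], [0.5, 1.1]])
    return a, b
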