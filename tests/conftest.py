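import numpy as np
import pytest

import microstatekit as mk


@pytest.fixture(scope="session")
def montage():
    return mk.default_montage()


@pytest.fixture(scope="session")
def templates(montage):
    return mk.make_canonical_templates(montage)


@pytest.fixture(scope="session")
def small_spec():
    """A fast cohort: 3+3 subjects, 60 s records, otherwise study defaults."""
    return mk.GenerativeSpec(n_per_group=3, record_seconds=60.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return mk.simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_config(small_spec):
    cfg = mk.PipelineConfig()
    cfg.generative = small_spec
    cfg.preprocessing.min_epochs = 20
    cfg.n_restarts = 8
    return cfg


@pytest.fixture(scope="session")
def small_study(small_config):
    """Full pipeline on the small cohort (shared across tests)."""
    return mk.run_simulation_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """The full study-scale cohort (25+25 subjects, 300 s, snr 4, seed 0).

    This is the expensive session fixture behind the parameter- and
    prototype-recovery checks; everything that needs the default cohort
    shares this single run.
    """
    return mk.run_simulation_study(mk.PipelineConfig())


def truth_aligned(ls, true_labels):
    """Ground-truth labels reshaped onto the analysed epochs."""
    return true_labels[: ls.labels.size].reshape(ls.labels.shape)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
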