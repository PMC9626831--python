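import numpy as np
import pytest

from rsnbench import (
    SimulationConfig,
    TechniqueOptions,
    make_phantom_atlas,
    simulate_subject,
)


@pytest.fixture(scope="session")
def atlas24():
    return make_phantom_atlas((24, 24, 24), n_seeds=6, n_networks=4, rng_seed=0)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_subjects=4, n_timepoints=120, tr=2.5, rng_seed=7)


@pytest.fixture(scope="session")
def hf_subject(atlas24, small_config):
    """One tremor-like subject on the 24-cubed phantom."""
    return simulate_subject(
        atlas24, small_config, subject_seed=123, motion_mode="hf_tremor"
    )


@pytest.fixture()
def oracle_options(hf_subject):
    return TechniqueOptions(
        n_components=12,
        noise_timecourses=hf_subject.truth_artifact_timecourses,
        signal_timecourses=hf_subject.truth_network_timecourses,
        label_min_abs_r=0.6,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
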