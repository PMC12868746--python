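import numpy as np
import pytest

from topoeeg import (SyntheticCohortConfig, TDAConfig, TrainingConfig,
                     generate_cohort)
from topoeeg.pipeline import extract_pi_sequences

BANDS = ("Delta", "Theta", "Alpha", "Beta", "Gamma")


def zero_effects():
    return {b: 0.0 for b in BANDS}


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject cohort reused by pipeline-level tests."""
    cfg = SyntheticCohortConfig(n_subjects_per_class=2, duration_s=16.0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def desk_tda_config():
    return TDAConfig(max_points=40, max_hom_dim=1, hom_dims=(1,),
                     resolution=20, seed=7)


@pytest.fixture(scope="session")
def small_pi_sequences(small_cohort, desk_tda_config):
    seqs, fitted = extract_pi_sequences(small_cohort, "Alpha", desk_tda_config)
    return seqs, fitted


@pytest.fixture()
def desk_training_config():
    return TrainingConfig(resolution=20, epochs_pretrain=3, epochs_joint=3,
                          seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
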