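import numpy as np
import pytest

from astnet.model import ModelConfig
from astnet.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small architecture for fast unit tests (6 ROIs, short windows)."""
    return ModelConfig(
        n_rois=6, window_length=10, gcn_dims=(8, 8, 4), mlp_dims=(16, 8, 4),
        gru_units=3, gru_layers=2, head_dims=(8, 4, 2), seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Separable little cohort: 12 subjects/group, 6 ROIs, 4 windows."""
    spec = CohortSpec(
        n_subjects_per_group=12, n_rois=6, n_timepoints=40, window_length=10,
        n_states=2, within_block_corr=0.4, effect_edges=[(0, 3), (1, 4)],
        effect_size=0.5, seed=21,
    )
    return generate_cohort(spec)
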