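import numpy as np
import pytest

from mcicps.config import PipelineConfig, SyntheticConfig
from mcicps.synthetic import generate_cohort, generate_train_test


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """One full-size synthetic cohort (train + test block)."""
    return generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def train_test(default_cfg):
    return generate_train_test(default_cfg)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A small cohort for fast pipeline tests."""
    return SyntheticConfig(
        n_train=80, n_test=40, n_snp=40, n_expr=40, n_roi=20,
        n_subtype_informative_snp=15, n_subtype_informative_expr=12,
        n_conv_informative_per_modality=4, seed=3,
    )


@pytest.fixture(scope="session")
def fast_pipeline_cfg() -> PipelineConfig:
    """Reduced selection repetitions for test-speed pipeline runs."""
    return PipelineConfig(inner_reps=25, outer_reps=4, snf_T=10,
                          min_subtype_size=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
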