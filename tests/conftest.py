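import numpy as np
import pytest

from restflow.io import PipelineConfig
from restflow.mvar import MVARModel
from restflow.synth import CohortSpec


@pytest.fixture
def bivariate_var1() -> MVARModel:
    """The worked 2-channel MVAR(1): A1 = [[0.5, 0], [0.3, 0.4]]."""
    A1 = np.array([[0.5, 0.0], [0.3, 0.4]])
    return MVARModel(coeffs=A1[None], noise_cov=np.eye(2))


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Desk-scale cohort used by integration tests."""
    return CohortSpec(n_per_group=3, n_regions=6, fs_hz=128.0, n_epochs=3,
                      epoch_s=2.0, n_sensors=16, snr_db=10.0, seed=7,
                      sources_per_region=2)


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    return PipelineConfig(mvar_order=6, analysis_fs_hz=128.0, n_epochs=3,
                          epoch_s=2.0, ica_max_components=12)
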