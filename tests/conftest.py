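import numpy as np
import pytest

from dipmap.preprocess import AnalysisConfig
from dipmap.synthetic import AcquisitionConfig, ActivationSpec


@pytest.fixture(scope="session")
def acq_small() -> AcquisitionConfig:
    """Small, fast imaging geometry used by most tests."""
    return AcquisitionConfig(frame_rate=10.0, trial_duration=4.0,
                             stim_onset=0.5, image_rows=40, image_cols=40,
                             pixel_pitch=0.05, n_trials=6, n_blank_trials=6)


@pytest.fixture(scope="session")
def analysis_small() -> AnalysisConfig:
    return AnalysisConfig(smooth_kernel=5)


@pytest.fixture
def centered_spec(acq_small) -> ActivationSpec:
    return ActivationSpec(center=(20.0, 20.0), sigma_major=4.0,
                          sigma_minor=4.0, amplitude=-0.01)


def disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius
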