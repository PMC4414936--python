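import warnings

import pytest

from myoelbow import (
    PipelineConfig,
    SyntheticSubject,
    TrajectorySpec,
    calibrate,
    compute_mvc,
    generate_dataset,
)

FS = 1000.0


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def continuous_dataset():
    """Ten synthetic continuous trials plus the MVC trial (seed 42)."""
    subject = SyntheticSubject(seed=42)
    trials, mvc = generate_dataset(TrajectorySpec(), subject, 10, seed=42)
    return trials, mvc


@pytest.fixture(scope="session")
def fitted_model(continuous_dataset, config):
    """Calibration on trial 1 of the shared continuous dataset."""
    trials, mvc = continuous_dataset
    mvc_value = compute_mvc([mvc], smooth_cutoff=config.lowpass_cutoff)
    raw0, ang0 = trials[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        model = calibrate(raw0, ang0, mvc_value, config)
    return model, mvc_value
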