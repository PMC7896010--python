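import numpy as np
import pytest

from renshaw.synthetic import (
    IPSPKernel,
    NonlinearityConfig,
    RecordingConfig,
    StimulusTrain,
    TrainConfig,
    generate_poisson_train,
    synthesize_recording,
)


@pytest.fixture(scope="session")
def clean_recording():
    """Zero-noise linear recording with well-separated stimuli.

    Stimuli are spaced far beyond the kernel support so per-stimulus
    responses never overlap and superposition identities are exact.
    """
    kern = IPSPKernel(amplitude_uv=200.0)
    times = np.arange(0.25, 30.0, 0.25)
    config = TrainConfig(duration=30.0, mean_rate=4.0, dead_time=0.003, seed=0)
    train = StimulusTrain("n1", times, config)
    rec_cfg = RecordingConfig(
        kernels={"n1": kern},
        noise_sd_uv=0.0,
        artifact_amplitude_uv=0.0,
        field_amplitude_uv=0.0,
        nonlinearity=NonlinearityConfig.linear(),
        seed=0,
    )
    return synthesize_recording(rec_cfg, [train])


@pytest.fixture(scope="session")
def poisson_recording():
    """Noisy linear recording under the standard 10 Hz Poisson protocol."""
    train = generate_poisson_train(TrainConfig(duration=120.0, seed=5), "n1")
    rec_cfg = RecordingConfig(
        kernels={"n1": IPSPKernel(amplitude_uv=300.0)},
        noise_sd_uv=100.0,
        nonlinearity=NonlinearityConfig.linear(),
        seed=5,
    )
    return synthesize_recording(rec_cfg, [train])
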