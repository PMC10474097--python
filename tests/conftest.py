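import numpy as np
import pytest

from pcgbeat import PipelineConfig, SimulationSpec, generate_recording


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_recording():
    """A 30 s resting-rhythm record (72 bpm, SNR 20 dB) with ground truth."""
    spec = SimulationSpec(duration=30.0, hr_bpm=72.0, seed=7)
    return generate_recording(spec)
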