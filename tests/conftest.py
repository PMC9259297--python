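import numpy as np
import pytest

from evoeeg.io import EEGRecording, EventMarker
from evoeeg.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def small_recording() -> EEGRecording:
    """A short default-configuration synthetic recording."""
    return generate(SynthConfig(seed=7, duration=60.0, n_events=20))


@pytest.fixture(scope="session")
def default_recording() -> EEGRecording:
    """The generator's default study conditions."""
    return generate(SynthConfig(seed=11))


def recording_with_markers(n_samples: int, marker_positions, n_channels: int = 1) -> EEGRecording:
    """Flat helper: a deterministic ramp recording with given markers."""
    data = np.arange(n_channels * n_samples, dtype=float).reshape(n_channels, n_samples)
    return EEGRecording(
        data=data, fs=250.0,
        channel_labels=tuple(f"c{i}" for i in range(n_channels)),
        markers=[EventMarker(int(p)) for p in marker_positions],
    )
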