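import numpy as np
import pytest

from sepkit.recording import ContinuousRecording
from sepkit.synth import SyntheticConfig, generate_recording


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_recording(
    data: np.ndarray,
    fs: float = 2048.0,
    events: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> ContinuousRecording:
    n_ch = data.shape[0]
    if labels is None:
        labels = [f"CH{i}" for i in range(n_ch)]
    return ContinuousRecording(
        sample_rate_hz=fs,
        channel_labels=labels,
        data=data,
        events=np.array([] if events is None else events, dtype=np.int64),
    )


@pytest.fixture(scope="session")
def small_synth():
    """One small synthetic session shared by read-only tests."""
    config = SyntheticConfig(n_channels=8, n_stimuli=40, edge_s=3.0, seed=7)
    return generate_recording(config)
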