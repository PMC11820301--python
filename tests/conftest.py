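import numpy as np
import pytest

from vagpipe import Recording, RecordingMeta
from vagpipe.synthetic_vag import two_tone


@pytest.fixture(scope="session")
def two_tone_probe() -> np.ndarray:
    """Fixed 1 Hz + 10 Hz probe, 10 s at 1 kHz."""
    return two_tone(1.0, 10.0, 10.0, 1000.0)


@pytest.fixture
def meta() -> RecordingMeta:
    return RecordingMeta(subject_id="S0001", group="OA", sensor="M2", chain="CKC")


@pytest.fixture
def noise_recording(meta) -> Recording:
    rng = np.random.default_rng(42)
    return Recording(samples=rng.standard_normal(2000), fs=1000.0, meta=meta)
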