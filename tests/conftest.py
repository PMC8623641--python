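import numpy as np
import pytest

from eegconn.io import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng):
    """Two-channel white-noise recording, 10 s at 256 Hz."""
    return EEGRecording(
        subject_id="noise",
        channel_labels=["Fp1", "T6"],
        data=20.0 * rng.standard_normal((2, 2560)),
        fs=256.0,
    )


@pytest.fixture
def edf_file(tmp_path):
    """Factory writing a synthetic EDF and returning its path."""
    from eegconn._edf import write_edf

    def make(data, labels, fs=256, name="fixture.edf"):
        p = tmp_path / name
        write_edf(p, np.asarray(data, dtype=float), labels, fs)
        return p

    return make
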