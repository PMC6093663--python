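import numpy as np
import pytest

from larcfft.io_uds import UDSRecording
from larcfft.synthgen import LarcSpec, SyntheticSpec, generate_recording


@pytest.fixture
def si_recording():
    """Vesical-only 3 cycles/min rhythm, p2p 10 cm-H2O, over noisy baseline."""
    spec = SyntheticSpec(
        noise_sd=1.0, larc=LarcSpec(frequency_cpm=3.0, peak_to_peak=10.0), seed=11
    )
    return generate_recording(spec, study_id="si")[0]


@pytest.fixture
def translated_recording():
    """The same rhythm injected identically into both pressure channels."""
    spec = SyntheticSpec(
        noise_sd=1.0,
        larc=LarcSpec(frequency_cpm=3.0, peak_to_peak=10.0, channel="both"),
        seed=11,
    )
    return generate_recording(spec, study_id="translated")[0]


@pytest.fixture
def flat_recording():
    """No rhythm: baseline drift plus noise only."""
    return generate_recording(SyntheticSpec(noise_sd=1.0, seed=11), study_id="flat")[0]


def make_recording(
    p_ves,
    p_abd=None,
    voided=None,
    rate=10.0,
    study_id="manual",
):
    """Assemble a minimal UDSRecording from raw arrays."""
    p_ves = np.asarray(p_ves, dtype=float)
    n = p_ves.size
    if p_abd is None:
        p_abd = np.zeros(n)
    if voided is None:
        voided = np.zeros(n)
    return UDSRecording(
        study_id=study_id,
        sample_rate=rate,
        time=np.arange(n) / rate,
        p_ves=p_ves,
        p_abd=np.asarray(p_abd, dtype=float),
        voided_volume=np.asarray(voided, dtype=float),
    )
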