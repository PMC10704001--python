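import numpy as np
import pytest

from hearlab.stimuli import (
    BmldChirpParams,
    CmrParams,
    F0dlParams,
    GapParams,
    IldParams,
    ItdParams,
    ToneSpec,
)

#: Reduced sample rate for synthesis-heavy tests; all stimulus content in
#: these tasks sits well below this Nyquist (upper CMR flanker ~5.6 kHz).
FAST_SR = 16_000


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_tone():
    return ToneSpec(sample_rate=FAST_SR, duration=0.5)


@pytest.fixture
def fast_bmld():
    return BmldChirpParams(sample_rate=FAST_SR, duration=0.6, seed=7)


@pytest.fixture
def fast_f0dl():
    return F0dlParams(sample_rate=FAST_SR, inter_tone_interval=0.05)


@pytest.fixture
def fast_gap():
    return GapParams(sample_rate=FAST_SR, seed=3)


@pytest.fixture
def fast_itd():
    return ItdParams(sample_rate=48_000)  # full rate: lag resolution matters


@pytest.fixture
def fast_ild():
    return IldParams(sample_rate=FAST_SR)


@pytest.fixture
def fast_cmr():
    return CmrParams(sample_rate=FAST_SR, duration=1.2, seed=11)
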