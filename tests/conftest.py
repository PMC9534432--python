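import numpy as np
import pytest

from cardioqc import ECGGenSpec, RRGenSpec, RRSequence, beats_from_rr, gen_ecg, gen_rr


@pytest.fixture
def clean_periodic():
    """Noise-free ECG with a cycle length commensurate with the sampling grid.

    1000 ms cycles at 256 Hz put every cycle on the same sample phase, so
    the rendered waveform is exactly periodic and the local median-cycle
    index is zero up to float rounding.
    """
    rr = gen_rr(RRGenSpec(n_beats=20, mean_rr=1000.0, sdnn=0.0, resp_depth=0.0, seed=0))
    record, beats = gen_ecg(rr, ECGGenSpec(fs=256.0))
    return record, beats


@pytest.fixture
def ramp_rr():
    """Monotone HR-recovery ramp: intervals lengthen by 12 ms per beat.

    Every off-diagonal interval pairing differs by >= 12 ms, and
    neighbouring intervals differ by exactly 12 ms, which makes planted
    annotation errors uniquely attributable by local alignment.
    """
    return RRSequence(600.0 + 12.0 * np.arange(160))


@pytest.fixture
def ramp_beats(ramp_rr):
    return beats_from_rr(ramp_rr, source="reference")
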