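import numpy as np
import pytest

from prp.preprocess import PupilTrace


def make_trace(values, valid=None, rate=60.0) -> PupilTrace:
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return PupilTrace(values, np.asarray(valid, dtype=bool), rate)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
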