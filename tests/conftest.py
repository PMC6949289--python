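import numpy as np
import pytest

from iemgkit import preprocess as pp
from iemgkit import spikesort as ss
from iemgkit import synthetic as syn

FS = 10240.0


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic session with ground truth (seed 1)."""
    cfg = syn.default_config(seed=1)
    return syn.synthesize_session(cfg)


@pytest.fixture(scope="session")
def notch_bank():
    return pp.design_notch_bank(FS)


@pytest.fixture(scope="session")
def sorted_session(default_session, notch_bank):
    """Per-channel sorter output on the filtered default session."""
    rec, truth = default_session
    out = {}
    for lab in rec.emg_labels:
        x = rec.column(lab)
        spec = pp.select_active_notches(notch_bank, x)
        xf = pp.apply_zero_phase(spec, x)
        events = ss.detect_candidates(xf, rec.fs)
        out[lab] = (events, ss.sort(events, rec.fs))
    return rec, truth, out


def align_match_r(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation of two waveforms after zero-padding and lag alignment."""
    n = max(a.size, b.size)
    a = np.pad(a, (0, n - a.size))
    b = np.pad(b, (0, n - b.size))
    m = ss.match(a, b, max_lag=n - 1)
    return m.r if m.valid else float("-inf")
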