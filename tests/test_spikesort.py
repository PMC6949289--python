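"""Candidate detection, the match rule, template updates, and the 3-pass sorter."""

import numpy as np
import pytest

from iemgkit import spikesort as ss
from iemgkit import synthetic as syn

FS = 10240.0


def place(x, w, s):
    peak = int(np.argmax(np.abs(w)))
    x[s - peak : s - peak + w.size] += w


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def test_detect_injected_muaps_at_8x_noise():
    rng = np.random.default_rng(0)
    noise_sd = 0.05
    x = rng.normal(0, noise_sd, int(2 * FS))
    w = syn.muap_template(FS, amplitude_mv=8 * noise_sd)
    truth = [5000, 9000, 15000]
    for s in truth:
        place(x, w, s)
    events = ss.detect_candidates(x, FS)
    assert len(events) == 3
    for ev, s in zip(events, truth):
        # noise riding the broad MUAP peak can move the |x| argmax by a few
        # samples; localization within half a millisecond
        assert abs(ev.peak - s) <= 5
        lo, hi = s - 51, s + 52
        assert ev.peak == lo + np.argmax(np.abs(x[lo:hi]))


def test_pure_noise_rarely_crosses_5x_robust_sd():
    rng = np.random.default_rng(1)
    x = rng.normal(size=int(1 * FS))
    events = ss.detect_candidates(x, FS)
    # Gaussian tail: P(|z| > 5) ~ 6e-7 per sample -> expected < 1 event
    assert len(events) <= 1


def test_close_peaks_merge_onto_larger():
    x = np.zeros(int(1 * FS))
    w = syn.muap_template(FS, amplitude_mv=1.0)
    place(x, w, 5000)
    place(x, 0.6 * w, 5000 + int(0.002 * FS))  # 2 ms apart, smaller
    x += 0.01 * np.random.default_rng(2).normal(size=x.size)
    events = ss.detect_candidates(x, FS)
    assert len(events) == 1
    assert abs(events[0].peak - 5000) <= 5


def test_snippets_have_odd_constant_length_and_boundary_padding():
    x = np.zeros(2000)
    w = syn.muap_template(FS, amplitude_mv=1.0)
    place(x, w, 60)  # snippet window overhangs the signal start
    x[3] = 0.0
    events = ss.detect_candidates(x, FS, threshold_mult=5.0)
    # robust SD is 0 here; inject tiny noise instead
    rng = np.random.default_rng(3)
    x += 0.01 * rng.normal(size=x.size)
    events = ss.detect_candidates(x, FS)
    assert events and events[0].snippet.size == 103


# ---------------------------------------------------------------------------
# match rule
# ---------------------------------------------------------------------------


def test_match_identity_accepted():
    w = syn.muap_template(FS)
    m = ss.match(w, w)
    assert m.r == pytest.approx(1.0)
    assert m.mse == pytest.approx(0.0, abs=1e-15)
    assert m.lag == 0
    assert m.accepted


def test_match_scaled_copy_rejected_by_mse():
    """A 3x copy has r=1 but MSE = 4x template power (> half power)."""
    w = syn.muap_template(FS)
    m = ss.match(3.0 * w, w)
    assert m.r == pytest.approx(1.0)
    assert m.mse == pytest.approx(4.0 * np.mean(w**2), rel=1e-9)
    assert not m.accepted


def test_match_negated_copy_rejected_by_correlation():
    w = syn.muap_template(FS)
    # at zero lag the correlation is exactly -1
    assert np.corrcoef(-w, w)[0, 1] == pytest.approx(-1.0)
    # the lag search maximizes the (signed) cross-correlation, so it may
    # settle on a shifted positive alignment; the match is still rejected
    m = ss.match(-w, w)
    assert m.r < ss.R_THRESHOLD
    assert not m.accepted


def test_match_zero_variance_snippet_flagged_invalid():
    w = syn.muap_template(FS)
    m = ss.match(np.zeros_like(w), w)
    assert not m.valid and not m.accepted


def test_match_recovers_constructed_lag():
    w = syn.muap_template(FS)
    shifted = np.roll(w, 7)
    m = ss.match(shifted, w)
    assert m.lag == 7
    assert m.r == pytest.approx(1.0, abs=1e-6)
    assert m.accepted


# ---------------------------------------------------------------------------
# template updates
# ---------------------------------------------------------------------------


def test_update_with_identical_snippet_is_fixed_point():
    w = syn.muap_template(FS)
    t = ss.Template(w.copy(), count=3)
    ss.update_template(t, w.copy())
    np.testing.assert_allclose(t.waveform, w)
    assert t.count == 4


def test_update_n1_gives_midpoint():
    w = syn.muap_template(FS)
    s = w + 0.1
    t = ss.Template(w.copy(), count=1)
    ss.update_template(t, s)
    np.testing.assert_allclose(t.waveform, (w + s) / 2)


def test_running_mean_converges_as_one_over_sqrt_n():
    rng = np.random.default_rng(4)
    w = syn.muap_template(FS)
    sd = 0.2

    def err_after(n):
        t = ss.Template(w + rng.normal(0, sd, w.size), count=1)
        for _ in range(n - 1):
            ss.update_template(t, w + rng.normal(0, sd, w.size))
        return np.sqrt(np.mean((t.waveform - w) ** 2))

    e25 = np.mean([err_after(25) for _ in range(8)])
    e400 = np.mean([err_after(400) for _ in range(8)])
    # 16x more members -> ~4x smaller RMS error
    assert e25 / e400 == pytest.approx(4.0, rel=0.4)


# ---------------------------------------------------------------------------
# three-pass sorter
# ---------------------------------------------------------------------------


def two_unit_events(n_a=60, n_b=40, seed=5, noise=0.0):
    wa = syn.default_units(2)[0].waveform(FS)
    wb = syn.default_units(2)[1].waveform(FS)
    n = max(wa.size, wb.size)
    wa = np.pad(wa, (0, n - wa.size))
    wb = np.pad(wb, (0, n - wb.size))
    rng = np.random.default_rng(seed)
    labels = np.array([0] * n_a + [1] * n_b)
    rng.shuffle(labels)
    events, truth = [], []
    for i, lab in enumerate(labels):
        w = (wa if lab == 0 else wb).copy()
        if noise:
            w += rng.normal(0, noise, n)
        events.append(ss.CandidateEvent(i * 500, w))
        truth.append(lab)
    return events, truth, wa, wb


def test_two_separated_units_fully_recovered():
    events, truth, wa, wb = two_unit_events()
    res = ss.sort(events, FS)
    assert res.n_units == 2
    assert len(res.unknown) == 0
    # every event assigned, and units are internally pure
    assigned = {s: i for i, train in enumerate(res.samples) for s in train}
    assert len(assigned) == len(events)
    for i, train in enumerate(res.samples):
        labs = {truth[s // 500] for s in train}
        assert len(labs) == 1


def test_minority_unit_below_5pct_is_discarded():
    events, truth, wa, wb = two_unit_events(n_a=97, n_b=3)
    res = ss.sort(events, FS)
    assert res.n_units == 1
    # the 3 minority events end up unknown in pass 3
    minority = {i * 500 for i, lab in enumerate(truth) if lab == 1}
    assert minority <= set(res.unknown.tolist())


def test_surviving_template_share_at_least_5pct():
    events, _, _, _ = two_unit_events(n_a=80, n_b=20, noise=0.02)
    res = ss.sort(events, FS)
    total = len(events)
    for train in res.samples:
        assert len(train) / total >= 0.05


def test_sort_deterministic_and_partition(sorted_session):
    rec, truth, out = sorted_session
    for lab, (events, res) in out.items():
        again = ss.sort(events, rec.fs)
        assert again.n_units == res.n_units
        for a, b in zip(again.samples, res.samples):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(again.templates, res.templates):
            np.testing.assert_array_equal(a, b)
        # partition: every event appears exactly once across units + unknown
        all_labels = np.concatenate(res.samples + [res.unknown]) if res.n_units else res.unknown
        peaks = np.array([e.peak for e in events])
        np.testing.assert_array_equal(np.sort(all_labels), np.sort(peaks))


def test_empty_event_list_gives_empty_result():
    res = ss.sort([], FS)
    assert res.n_units == 0
    assert res.unknown.size == 0


def test_unordered_events_rejected():
    events, _, _, _ = two_unit_events(n_a=4, n_b=4)
    with pytest.raises(ValueError):
        ss.sort(events[::-1], FS)
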