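"""Notch bank, zero-phase filtering, sync detection, alignment, upsampling."""

import numpy as np
import pytest

from iemgkit import preprocess as pp
from iemgkit import synthetic as syn
from iemgkit.errors import AlignmentError, DesignError, LengthError

FS = 10240.0


# ---------------------------------------------------------------------------
# notch bank design
# ---------------------------------------------------------------------------


def test_bank_has_one_center_per_harmonic(notch_bank):
    assert len(notch_bank.centers) == 100
    assert notch_bank.centers[0] == 50.0
    assert notch_bank.centers[-1] == 5000.0


def test_design_rejects_fmax_at_nyquist():
    with pytest.raises(DesignError):
        pp.design_notch_bank(8000.0, fmax=4000.0)


def test_center_attenuation_and_passband(notch_bank):
    h50 = np.abs(notch_bank.frequency_response([50.0]))[0]
    assert 20 * np.log10(max(h50, 1e-300)) <= -40.0
    h60 = np.abs(notch_bank.frequency_response([60.0]))[0]
    assert 0.95 <= h60 <= 1.05


def test_zero_phase_removes_50hz_keeps_60hz(notch_bank):
    t = np.arange(int(10 * FS)) / FS
    interior = slice(int(FS), -int(FS))  # skip the filter's edge transients
    x50 = np.sin(2 * np.pi * 50.0 * t)
    y50 = pp.apply_zero_phase(notch_bank, x50)
    assert np.sqrt(np.mean(y50[interior] ** 2)) <= 0.01 * np.sqrt(np.mean(x50**2))
    x60 = np.sin(2 * np.pi * 60.0 * t)
    y60 = pp.apply_zero_phase(notch_bank, x60)
    assert np.sqrt(np.mean(y60[interior] ** 2)) == pytest.approx(
        np.sqrt(np.mean(x60**2)), rel=0.05
    )


def test_zero_phase_lag_zero_on_broadband_noise(notch_bank):
    rng = np.random.default_rng(3)
    x = rng.normal(size=int(4 * FS))
    y = pp.apply_zero_phase(notch_bank, x)
    c = np.correlate(x - x.mean(), y - y.mean(), mode="full")
    assert np.argmax(c) == x.size - 1  # lag 0


def test_filtering_idempotent_in_stopband_sense(notch_bank):
    """A second application leaves the stopband annihilated and changes the
    passband (bins > 10 Hz from every center) RMS by < 0.5%.

    Whole-signal RMS is not idempotent for broadband input: the biquad
    skirts keep attenuating transition-band energy on every pass.
    """
    rng = np.random.default_rng(4)
    x = rng.normal(size=int(4 * FS))
    once = pp.apply_zero_phase(notch_bank, x)
    twice = pp.apply_zero_phase(notch_bank, once)
    freqs = np.fft.rfftfreq(x.size, 1 / FS)
    centers = np.asarray(notch_bank.centers)
    dist = np.min(np.abs(freqs[:, None] - centers[None, :]), axis=1)
    f1 = np.fft.rfft(once)
    f2 = np.fft.rfft(twice)
    passband = dist > 20.0  # mid-harmonic bins, clear of the biquad skirts
    r1 = np.sqrt(np.mean(np.abs(f1[passband]) ** 2))
    r2 = np.sqrt(np.mean(np.abs(f2[passband]) ** 2))
    assert abs(r2 - r1) / r1 < 0.005
    stop = dist <= 0.5
    assert np.sqrt(np.mean(np.abs(f2[stop]) ** 2)) <= np.sqrt(
        np.mean(np.abs(f1[stop]) ** 2)
    ) + 1e-9


def test_too_short_input_raises(notch_bank):
    with pytest.raises(LengthError):
        pp.apply_zero_phase(notch_bank, np.zeros(100))


# ---------------------------------------------------------------------------
# active-notch selection
# ---------------------------------------------------------------------------


def test_select_active_notches_finds_injected_harmonics(notch_bank):
    rng = np.random.default_rng(5)
    t = np.arange(int(10 * FS)) / FS
    x = 0.02 * rng.normal(size=t.size)
    x += 0.5 * np.sin(2 * np.pi * 50.0 * t) + 0.3 * np.sin(2 * np.pi * 150.0 * t)
    active = pp.select_active_notches(notch_bank, x)
    assert set(active.centers) == {50.0, 150.0}


def test_select_active_notches_white_noise_rarely_fires(notch_bank):
    rng = np.random.default_rng(6)
    x = rng.normal(size=int(10 * FS))
    active = pp.select_active_notches(notch_bank, x)
    assert len(active.centers) < 0.05 * len(notch_bank.centers)


def test_select_active_notches_all_harmonics(notch_bank):
    rng = np.random.default_rng(7)
    t = np.arange(int(6 * FS)) / FS
    x = 0.001 * rng.normal(size=t.size)
    for f0 in notch_bank.centers:
        x += 0.2 * np.sin(2 * np.pi * f0 * t + 0.1 * f0)
    active = pp.select_active_notches(notch_bank, x)
    assert set(active.centers) == set(notch_bank.centers)


# ---------------------------------------------------------------------------
# sync pulses and alignment
# ---------------------------------------------------------------------------


def test_detect_sync_pulses_default_train():
    fs = 200.0
    sync = syn.sync_pulse_train(60.0, fs)
    ev = pp.detect_sync_pulses(sync, fs)
    assert ev.count == 30
    assert abs(ev.leading[0] - 1.0 * fs) <= 1
    np.testing.assert_allclose(ev.widths_s, 0.2, atol=1.5 / fs)


def test_detect_sync_pulses_all_zero():
    ev = pp.detect_sync_pulses(np.zeros(1000), 200.0)
    assert ev.count == 0


def test_truncated_final_pulse_excluded():
    fs = 200.0
    sync = syn.sync_pulse_train(60.0, fs)
    # cut the recording in the middle of the last pulse (onset 59.0 s)
    cut = sync[: int(59.1 * fs)]
    ev = pp.detect_sync_pulses(cut, fs)
    assert ev.count == 29


def test_align_identical_streams_zero_offset():
    fs = 200.0
    sync = syn.sync_pulse_train(30.0, fs)
    ev = pp.detect_sync_pulses(sync, fs)
    res = pp.align_streams(ev, ev)
    assert res.offset_s == 0.0
    assert res.verified


def test_align_recovers_constructed_delay():
    fs_e, fs_f = 10240.0, 200.0
    emg = syn.sync_pulse_train(30.0, fs_e, n_pulses=12)
    force = syn.sync_pulse_train(30.0, fs_f, start_s=1.0 - 0.35, n_pulses=12)
    res = pp.align_streams(
        pp.detect_sync_pulses(emg, fs_e), pp.detect_sync_pulses(force, fs_f)
    )
    assert res.offset_s == pytest.approx(0.35, abs=1.0 / fs_f)


def test_alignment_property_100_random_offsets():
    """Constructed offsets are recovered to one force-sample resolution."""
    rng = np.random.default_rng(11)
    fs_e, fs_f = 10240.0, 200.0
    emg = syn.sync_pulse_train(30.0, fs_e, n_pulses=12)
    ev_e = pp.detect_sync_pulses(emg, fs_e)
    for tau in rng.uniform(0.0, 0.9, size=100):
        force = syn.sync_pulse_train(30.0, fs_f, start_s=1.0 - tau, n_pulses=12)
        ev_f = pp.detect_sync_pulses(force, fs_f)
        res = pp.align_streams(ev_e, ev_f)
        assert res.offset_s == pytest.approx(tau, abs=1.0 / fs_f)


def test_pulse_count_mismatch_raises_with_counts():
    fs = 200.0
    a = pp.detect_sync_pulses(syn.sync_pulse_train(70.0, fs, n_pulses=30), fs)
    b = pp.detect_sync_pulses(syn.sync_pulse_train(70.0, fs, n_pulses=29), fs)
    with pytest.raises(AlignmentError) as exc:
        pp.align_streams(a, b)
    assert (exc.value.count_a, exc.value.count_b) == (30, 29)
    res = pp.align_streams(a, b, strict=False)
    assert not res.verified


# ---------------------------------------------------------------------------
# force upsampling
# ---------------------------------------------------------------------------


def test_upsample_constant_and_ramp():
    const = pp.upsample_force(np.full(200, 2.5))
    np.testing.assert_allclose(const, 2.5)
    ramp = np.linspace(0.0, 1.0, 201)  # exactly linear in time
    up = pp.upsample_force(ramp)
    t = np.arange(up.size) / 10240.0
    np.testing.assert_allclose(up, t, atol=1e-12)


def test_upsample_grid_covers_input_interval():
    out = pp.upsample_force(np.zeros(200))  # 1 s minus one sample at 200 Hz
    # span (n-1)/200 s mapped onto the 10240 Hz grid
    assert out.size == int(np.floor(199 / 200 * 10240)) + 1


def test_upsample_preserves_bounds():
    rng = np.random.default_rng(12)
    x = rng.normal(size=400)
    up = pp.upsample_force(x)
    assert up.min() >= x.min() - 1e-12
    assert up.max() <= x.max() + 1e-12


def test_upsample_needs_two_samples():
    with pytest.raises(LengthError):
        pp.upsample_force(np.array([1.0]))
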