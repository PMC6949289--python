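"""Protocol generation, unit trains, interference, and full sessions."""

import numpy as np
import pytest

from iemgkit import codes
from iemgkit import synthetic as syn
from iemgkit.errors import ConfigError
from iemgkit.records import SessionRecord


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


def test_emitted_codes_are_subset_of_protocol_table():
    proto = syn.generate_protocol(syn.default_schedule(), 200.0)
    emitted = {round(c * 100) for c in np.unique(proto.code) if c != 0}
    valid = {codes.code_to_int(mc) for mc in codes.iter_codes()}
    assert emitted <= valid
    # every generated code decodes
    for c in emitted:
        codes.int_to_code(c)


def test_mvc_cue_lasts_five_seconds():
    fs = 200.0
    proto = syn.generate_protocol(syn.default_schedule(), fs)
    cue_code = round(codes.encode_code(4, 1, cue=True) * 100)
    stream = np.round(proto.code * 100).astype(int)
    n_cue = int(np.sum(stream == cue_code))
    assert n_cue == int(5.0 * fs)


def test_sine_cue_dominant_frequency():
    fs = 200.0
    st = syn.Stage(4, 3, joints=("little",), signs=(-1.0,), amplitude=0.6, cycles=4)
    proto = syn.generate_protocol(syn.ProtocolSchedule([st]), fs)
    cue = proto.cue - proto.cue.mean()
    spec = np.abs(np.fft.rfft(cue))
    freqs = np.fft.rfftfreq(cue.size, 1 / fs)
    assert freqs[np.argmax(spec)] == pytest.approx(0.1, abs=freqs[1])


def test_circle_radius_is_lesser_amplitude():
    st = syn.Stage(9, 1, joints=("thumb_fe", "thumb_aa"), signs=(1.0, 1.0),
                   amplitude=(2.0, 1.0), cycles=1)
    proto = syn.generate_protocol(syn.ProtocolSchedule([st]), 200.0)
    a = proto.targets["thumb_fe"]
    b = proto.targets["thumb_aa"]
    radius = np.sqrt(a**2 + b**2)
    np.testing.assert_allclose(radius, 1.0, atol=1e-9)


def test_synergy_emits_four_repetitions():
    fs = 200.0
    st = syn.Stage(20, 1, joints=("index",), signs=(1.0,), amplitude=0.7, cue_s=3.0)
    proto = syn.generate_protocol(syn.ProtocolSchedule([st]), fs)
    cue_code = round(codes.encode_code(20, 1, cue=True) * 100)
    stream = np.round(proto.code * 100).astype(int)
    onsets = np.sum(np.diff((stream == cue_code).astype(int)) == 1) + int(
        stream[0] == cue_code
    )
    assert onsets == 4


def test_out_of_order_schedule_rejected():
    sched = syn.ProtocolSchedule(
        [
            syn.Stage(4, 1, joints=("little",)),
            syn.Stage(1, 1, joints=("index",)),
        ]
    )
    with pytest.raises(ConfigError):
        sched.validate()


def test_non_five_second_mvc_rejected():
    with pytest.raises(ConfigError):
        syn.ProtocolSchedule(
            [syn.Stage(4, 1, joints=("little",), cue_s=3.0)]
        ).validate()


# ---------------------------------------------------------------------------
# unit trains
# ---------------------------------------------------------------------------


def test_train_silent_below_threshold():
    unit = syn.UnitModel(recruitment_threshold=0.3)
    f = np.full(10240, 0.1)
    assert syn.simulate_unit_train(f, 10240.0, unit, seed=0).size == 0


def test_zero_jitter_count_equals_rate_times_duration():
    unit = syn.UnitModel(recruitment_threshold=0.0, rate_min=5.0, rate_max=20.0,
                         jitter=0.0)
    f = np.ones(int(10 * 10240))
    spikes = syn.simulate_unit_train(f, 10240.0, unit, seed=0)
    assert abs(spikes.size - 200) <= 2


def test_train_deterministic_under_seed():
    unit = syn.UnitModel(recruitment_threshold=0.0)
    f = np.ones(int(5 * 10240)) * 0.7
    a = syn.simulate_unit_train(f, 10240.0, unit, seed=42)
    b = syn.simulate_unit_train(f, 10240.0, unit, seed=42)
    np.testing.assert_array_equal(a, b)


def test_trains_strictly_increasing_and_in_range():
    unit = syn.UnitModel(recruitment_threshold=0.1, jitter=0.3)
    n = int(8 * 10240)
    f = 0.5 + 0.5 * np.sin(2 * np.pi * 0.1 * np.arange(n) / 10240.0) ** 2
    spikes = syn.simulate_unit_train(np.clip(f, 0, 1), 10240.0, unit, seed=1)
    assert np.all(np.diff(spikes) > 0)
    assert spikes.min() >= 0 and spikes.max() < n


# ---------------------------------------------------------------------------
# interference and templates
# ---------------------------------------------------------------------------


def test_interference_centers_must_be_50hz_multiples():
    with pytest.raises(ConfigError):
        syn.InterferenceModel(harmonics={60.0: 0.1}).validate()


def test_interference_peaks_at_configured_harmonics():
    """FFT argmax within each 2 Hz band sits on the configured center."""
    fs = 10240.0
    t = np.arange(int(8 * fs)) / fs
    rng = np.random.default_rng(2)
    x = 0.001 * rng.normal(size=t.size)
    for f0 in (50.0, 150.0, 250.0):
        x += 0.2 * np.sin(2 * np.pi * f0 * t + f0)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    for f0 in (50.0, 150.0, 250.0):
        band = (freqs >= f0 - 1.0) & (freqs <= f0 + 1.0)
        assert freqs[band][np.argmax(spec[band])] == pytest.approx(f0, abs=0.2)


def test_muap_template_zero_mean_and_odd_length():
    for um in syn.default_units(3):
        w = um.waveform(10240.0)
        assert w.size % 2 == 1
        assert abs(w.mean()) < 1e-12
        assert np.max(np.abs(w)) == pytest.approx(um.amplitude_mv)


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------


def test_noiseless_single_unit_is_exact_template_superposition():
    sched = syn.ProtocolSchedule(
        [syn.Stage(4, 1, joints=("little",), signs=(-1.0,), amplitude=0.8)]
    )
    unit = syn.UnitModel(recruitment_threshold=0.05)
    cfg = syn.SessionConfig(
        schedule=sched,
        channels=[syn.ChannelConfig("FDP", "little", -1.0, [unit])],
        interference=syn.InterferenceModel(harmonics={}, noise_sd=0.0),
        force_noise_v=0.0,
        seed=5,
    )
    rec, truth = syn.synthesize_session(cfg)
    x = rec.column("FDP")
    rebuilt = np.zeros_like(x)
    u = truth.units[0]
    peak = int(np.argmax(np.abs(u.template)))
    for s in u.spikes:
        lo = s - peak
        rebuilt[lo : lo + u.template.size] += u.template
    np.testing.assert_allclose(x, rebuilt, atol=1e-12)


def test_session_sync_trains_on_both_streams(default_session):
    from iemgkit import preprocess as pp

    rec, truth = default_session
    for sync, fs in ((truth.sync_emg, truth.fs_emg), (truth.sync_force, truth.fs_force)):
        ev = pp.detect_sync_pulses(sync, fs)
        assert ev.count >= 2
        np.testing.assert_allclose(ev.widths_s, 0.2, atol=1.5 / fs)
        rate = 1.0 / np.mean(np.diff(ev.leading_times))
        assert rate == pytest.approx(0.5, rel=1e-3)


def test_generated_record_roundtrips_with_invariants(default_session, tmp_path):
    from iemgkit import io

    rec, _ = default_session
    assert isinstance(rec, SessionRecord)
    rec.validate()
    path = tmp_path / "gen.mat"
    io.save_session(rec, path)
    back = io.load_session(path)  # load_session validates
    np.testing.assert_array_equal(back.data, rec.data)


def test_all_generated_codes_decode(default_session):
    rec, _ = default_session
    for c in np.unique(rec.code_stream()):
        if c != 0:
            codes.decode_code(c)


def test_config_requires_known_joint():
    cfg = syn.default_config(seed=0)
    cfg.channels[0].joint = "elbow"
    with pytest.raises(ConfigError):
        cfg.validate()


def test_config_yaml_roundtrip(tmp_path):
    import yaml

    d = {
        "seed": 3,
        "schedule": [
            {"base": 4, "substage": 1, "joints": ["little"], "signs": [-1.0],
             "amplitude": 0.8},
            {"base": 4, "substage": 3, "joints": ["little"], "signs": [-1.0],
             "amplitude": 0.6},
        ],
        "channels": [
            {"label": "FDP", "joint": "little", "sign": -1.0,
             "units": [{"recruitment_threshold": 0.05}]}
        ],
        "interference": {"noise_sd": 0.02, "harmonics": {"50": 0.05}},
    }
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(d))
    cfg = syn.load_config(path)
    assert cfg.seed == 3
    assert cfg.interference.harmonics == {50.0: 0.05}
    rec, truth = syn.synthesize_session(cfg)
    assert rec.duration_s == pytest.approx(9.0 + 20.0)
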