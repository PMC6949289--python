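"""Ground-truth-annotated synthetic iEMG sessions.

The generator emulates the structure of the recorded database so every
downstream stage (IO, filtering, sync alignment, spike sorting, envelopes,
pairing QC) can be exercised and scored without the real archive:

* a cue-driven protocol stream with the published movement codes
  (x.x0/x.x1 cue sub-codes, 5 s MVC cues, 0.1 Hz sine tracking cues,
  circle cues with radius = the lesser single-DoF amplitude, 4-repetition
  synergies);
* motor-unit spike trains from a gamma-renewal process whose recruitment
  and firing rate scale with the force target, convolved with parametric
  biphasic/triphasic MUAP templates;
* additive broadband noise plus 50 Hz-harmonic powerline interference;
* force channels in raw sensor volts (inverse calibration) at 200 Hz;
* a 5 V / 200 ms / 0.5 Hz synchronization pulse train on both streams.

Physiological MUAP amplitude/duration and firing-rate defaults follow
standard clinical EMG ranges (amplitudes a few hundred microvolts to a few
millivolts, 5-15 ms support, 8-16 Hz sustained rates) and are all
config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import codes as mc
from .errors import ConfigError
from .records import (
    CODE_LABEL,
    CUE_LABEL,
    FORCE_PREFIX,
    SessionRecord,
    newtons_to_volts,
)

__all__ = [
    "UnitModel",
    "InterferenceModel",
    "Stage",
    "ProtocolSchedule",
    "ProtocolStreams",
    "ChannelConfig",
    "SessionConfig",
    "SyntheticGroundTruth",
    "TrueUnit",
    "muap_template",
    "simulate_unit_train",
    "generate_protocol",
    "sync_pulse_train",
    "synthesize_session",
    "default_config",
    "default_units",
    "load_config",
    "config_from_dict",
]

#: protocol constants of the recording procedure
SINE_HZ = 0.1  # tracking-cue repetition frequency
MVC_CUE_S = 5.0  # MVC cue duration
SYNERGY_REPS = 4  # repetitions per synergistic stage
SYNC_AMPLITUDE_V = 5.0
SYNC_WIDTH_S = 0.2
SYNC_RATE_HZ = 0.5
SYNC_START_S = 1.0


# ---------------------------------------------------------------------------
# motor units
# ---------------------------------------------------------------------------


@dataclass
class UnitModel:
    """One motor unit: waveform shape and force-dependent firing behaviour.

    The unit is silent below ``recruitment_threshold`` (fraction of MVC);
    above it the instantaneous rate interpolates linearly from ``rate_min``
    at threshold to ``rate_max`` at full drive.  ``jitter`` is the
    inter-spike-interval coefficient of variation of the gamma-renewal
    process (0 gives a deterministic train).
    """

    recruitment_threshold: float = 0.1
    rate_min: float = 8.0
    rate_max: float = 16.0
    jitter: float = 0.15
    amplitude_mv: float = 0.8
    duration_ms: float = 8.0
    asymmetry: float = 0.3
    lobe_sep: float = 0.22  # lobe half-separation as fraction of support
    flip: bool = False  # invert polarity (positive-first main lobe)

    def __post_init__(self):
        if not self.rate_min < self.rate_max:
            raise ConfigError("rate_min must be below rate_max")
        if not 0.0 <= self.recruitment_threshold < 1.0:
            raise ConfigError("recruitment_threshold must be in [0, 1)")
        if self.jitter < 0:
            raise ConfigError("jitter must be non-negative")

    def waveform(self, fs: float) -> np.ndarray:
        return muap_template(
            fs,
            duration_ms=self.duration_ms,
            amplitude_mv=self.amplitude_mv,
            asymmetry=self.asymmetry,
            lobe_sep=self.lobe_sep,
            flip=self.flip,
        )


def muap_template(
    fs: float,
    duration_ms: float = 8.0,
    amplitude_mv: float = 0.8,
    asymmetry: float = 0.3,
    lobe_sep: float = 0.22,
    flip: bool = False,
) -> np.ndarray:
    """Parametric MUAP: sum of two Gaussian-derivative lobes, zero mean.

    ``asymmetry`` scales the second lobe relative to the first, sliding the
    shape between biphasic (0) and markedly triphasic appearances;
    ``lobe_sep`` sets the lobe spacing as a fraction of the support.
    """
    n = int(round(duration_ms * fs / 1000.0))
    n += 1 - n % 2  # odd length, symmetric support
    t = np.linspace(-1.0, 1.0, n)
    sep = lobe_sep
    sigma = 0.35

    def dgauss(u):
        return -u * np.exp(-(u**2) / 2.0)

    w = dgauss((t + sep) / sigma) - (1.0 - asymmetry) * dgauss((t - sep) / (sigma * 0.8))
    w -= w.mean()
    w /= np.max(np.abs(w))
    if flip:
        w = -w
    return w * amplitude_mv


def simulate_unit_train(
    force_profile: np.ndarray,
    fs: float,
    unit: UnitModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Simulate one unit's spike train along a fraction-of-MVC force profile.

    Implemented by time rescaling an ordinary gamma-renewal process: the
    instantaneous rate is integrated over the profile and unit-mean gamma
    increments (shape 1/jitter^2) mark the spike crossings.  With zero
    jitter the increments are exactly 1, so the spike count equals the
    integrated rate rounded down.  Returns sorted 0-based sample indices;
    reproducible for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = np.asarray(force_profile, dtype=float)
    if f.size == 0:
        return np.empty(0, dtype=np.int64)
    if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
        raise ConfigError("force profile must lie in [0, 1] (fraction of MVC)")
    thr = unit.recruitment_threshold
    excess = np.clip((f - thr) / max(1.0 - thr, 1e-12), 0.0, 1.0)
    rate = np.where(f > thr, unit.rate_min + (unit.rate_max - unit.rate_min) * excess, 0.0)
    cum = np.concatenate([[0.0], np.cumsum(rate) / fs])
    total = cum[-1]
    if total <= 0:
        return np.empty(0, dtype=np.int64)
    n_draw = int(total + 10.0 * np.sqrt(total) + 10.0)
    if unit.jitter == 0:
        increments = np.ones(n_draw)
    else:
        shape = 1.0 / unit.jitter**2
        increments = rng.gamma(shape, 1.0 / shape, size=n_draw)
    thresholds = np.cumsum(increments)
    thresholds = thresholds[thresholds <= total]
    spikes = np.searchsorted(cum, thresholds, side="left") - 1
    spikes = np.unique(np.clip(spikes, 0, f.size - 1))
    return spikes.astype(np.int64)


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


@dataclass
class Stage:
    """One protocol sub-stage.

    ``joints`` are the driven force transducers; ``signs`` give the force
    direction per joint on the bidirectional transducers (flexion negative).
    ``amplitude`` is the target in fractions of MVC (two values for circle
    stages, whose radius becomes the lesser of the two).
    """

    base: int
    substage: int
    joints: tuple[str, ...]
    amplitude: float | tuple[float, float] = 0.6
    signs: tuple[float, ...] | None = None
    pre_rest_s: float = 2.0
    post_rest_s: float = 2.0
    cue_s: float = MVC_CUE_S  # MVC: must stay 5 s; synergy: per-repetition cue
    cycles: int = 2  # sine/circle stages: number of 0.1 Hz periods

    def __post_init__(self):
        self.joints = tuple(self.joints)
        if self.signs is None:
            self.signs = tuple(-1.0 for _ in self.joints)
        self.signs = tuple(float(s) for s in self.signs)

    @property
    def kind(self) -> str:
        return mc.stage_kind(self.base, self.substage)


@dataclass
class ProtocolSchedule:
    """Ordered protocol stages, validated against the movement table."""

    stages: list[Stage]

    def validate(self) -> "ProtocolSchedule":
        order = []
        for st in self.stages:
            kind = st.kind  # raises UnknownCodeError for bad base/substage
            if len(st.joints) == 0:
                raise ConfigError(f"stage {st.base}.{st.substage} drives no joint")
            if len(st.signs) != len(st.joints):
                raise ConfigError("signs must match joints")
            if kind == "mvc" and st.cue_s != MVC_CUE_S:
                raise ConfigError(
                    f"MVC cue duration is fixed at {MVC_CUE_S} s "
                    f"(stage {st.base}.{st.substage} asks {st.cue_s})"
                )
            if kind == "circle":
                if len(st.joints) != 2 or np.ndim(st.amplitude) != 1:
                    raise ConfigError(
                        "circle stages need two joints and two amplitudes"
                    )
            order.append((st.base, st.substage))
        if order != sorted(order):
            raise ConfigError("stages must follow the protocol table order")
        return self

    @property
    def joints(self) -> list[str]:
        seen: list[str] = []
        for st in self.stages:
            for j in st.joints:
                if j not in seen:
                    seen.append(j)
        return seen


@dataclass
class ProtocolStreams:
    """Protocol emitted at one sampling rate."""

    fs: float
    code: np.ndarray  # two-decimal movement codes (0 between stages)
    cue: np.ndarray  # presented cue level (fraction of MVC)
    targets: dict[str, np.ndarray]  # per-joint signed force target


def generate_protocol(schedule: ProtocolSchedule, fs: float) -> ProtocolStreams:
    """Render a schedule into code/cue/force-target streams at rate ``fs``."""
    schedule.validate()
    joints = schedule.joints
    code_parts: list[np.ndarray] = []
    cue_parts: list[np.ndarray] = []
    target_parts: list[dict[str, np.ndarray]] = []

    def block(n, code_val, cue_vals, tgt: dict[str, np.ndarray]):
        code_parts.append(np.full(n, code_val))
        cue_parts.append(np.broadcast_to(cue_vals, (n,)).astype(float))
        target_parts.append(tgt)

    for st in schedule.stages:
        kind = st.kind
        if kind in ("mvc", "synergy"):
            rest_code = mc.encode_code(st.base, st.substage, cue=False)
            cue_code = mc.encode_code(st.base, st.substage, cue=True)
            amp = float(np.max(st.amplitude))
            reps = 1 if kind == "mvc" else SYNERGY_REPS
            n_pre = int(round(st.pre_rest_s * fs))
            n_cue = int(round(st.cue_s * fs))
            n_post = int(round(st.post_rest_s * fs))
            for _ in range(reps):
                block(n_pre, rest_code, 0.0, {j: np.zeros(n_pre) for j in joints})
                tgt = {j: np.zeros(n_cue) for j in joints}
                for j, s in zip(st.joints, st.signs):
                    tgt[j] = np.full(n_cue, s * amp)
                block(n_cue, cue_code, amp, tgt)
            block(n_post, rest_code, 0.0, {j: np.zeros(n_post) for j in joints})
        elif kind in ("sine", "trumpet"):
            code_val = mc.encode_code(st.base, st.substage)
            amp = float(np.max(st.amplitude))
            n = int(round(st.cycles / SINE_HZ * fs))
            t = np.arange(n) / fs
            profile = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * SINE_HZ * t))
            tgt = {j: np.zeros(n) for j in joints}
            for j, s in zip(st.joints, st.signs):
                tgt[j] = s * profile
            block(n, code_val, profile, tgt)
        elif kind == "circle":
            code_val = mc.encode_code(st.base, st.substage)
            radius = float(np.min(st.amplitude))
            n = int(round(st.cycles / SINE_HZ * fs))
            t = np.arange(n) / fs
            tgt = {j: np.zeros(n) for j in joints}
            ja, jb = st.joints
            sa, sb = st.signs
            tgt[ja] = sa * radius * np.cos(2.0 * np.pi * SINE_HZ * t)
            tgt[jb] = sb * radius * np.sin(2.0 * np.pi * SINE_HZ * t)
            block(n, code_val, radius, tgt)
        else:  # pragma: no cover - table kinds are exhaustive
            raise ConfigError(f"unhandled stage kind {kind!r}")

    code = np.concatenate(code_parts)
    cue = np.concatenate(cue_parts)
    targets = {
        j: np.concatenate([p.get(j, np.zeros(len(c))) for p, c in zip(target_parts, code_parts)])
        for j in joints
    }
    return ProtocolStreams(fs, code, cue, targets)


# ---------------------------------------------------------------------------
# sync pulses
# ---------------------------------------------------------------------------


def sync_pulse_train(
    duration_s: float,
    fs: float,
    amplitude: float = SYNC_AMPLITUDE_V,
    width_s: float = SYNC_WIDTH_S,
    rate_hz: float = SYNC_RATE_HZ,
    start_s: float = SYNC_START_S,
    n_pulses: int | None = None,
) -> np.ndarray:
    """Square synchronization pulse train (5 V, 200 ms, 0.5 Hz by default)."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    out = np.zeros(n)
    k = 0
    while True:
        onset = start_s + k / rate_hz
        if onset >= duration_s or (n_pulses is not None and k >= n_pulses):
            break
        out[(t >= onset) & (t < onset + width_s)] = amplitude
        k += 1
    return out


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------


@dataclass
class InterferenceModel:
    """Powerline harmonics (center Hz -> amplitude mV) plus broadband noise."""

    harmonics: dict[float, float] = field(default_factory=dict)
    noise_sd: float = 0.03  # mV

    def validate(self) -> "InterferenceModel":
        for f0 in self.harmonics:
            if round(f0) % 50 != 0 or f0 <= 0:
                raise ConfigError(
                    f"interference centers must be positive multiples of 50 Hz"
                    f" (got {f0})"
                )
        if self.noise_sd < 0:
            raise ConfigError("noise SD must be non-negative")
        return self


@dataclass
class ChannelConfig:
    """One iEMG channel: the muscle label, its driven joint and units."""

    label: str
    joint: str
    sign: float  # force direction of this muscle's action (flexion -1)
    units: list[UnitModel]


@dataclass
class SessionConfig:
    """Full synthetic-session description; ``seed`` is mandatory."""

    schedule: ProtocolSchedule
    channels: list[ChannelConfig]
    seed: int
    interference: InterferenceModel = field(default_factory=InterferenceModel)
    fs_emg: float = 10240.0
    fs_force: float = 200.0
    mvc_newtons: float = 60.0  # full-scale MVC force per joint
    force_noise_v: float = 0.002
    sync_start_s: float = SYNC_START_S

    def validate(self) -> "SessionConfig":
        self.schedule.validate()
        self.interference.validate()
        if self.seed is None:
            raise ConfigError("seed is a mandatory config field")
        if not self.channels:
            raise ConfigError("at least one iEMG channel is required")
        joints = set(self.schedule.joints)
        for ch in self.channels:
            if not ch.units:
                raise ConfigError(f"channel {ch.label} has no units")
            if ch.joint not in joints:
                raise ConfigError(
                    f"channel {ch.label} drives joint {ch.joint!r}, absent "
                    f"from the schedule"
                )
        for f0 in self.interference.harmonics:
            if f0 >= self.fs_emg / 2:
                raise ConfigError(f"interference center {f0} above Nyquist")
        return self


@dataclass
class TrueUnit:
    """Ground truth for one simulated unit."""

    channel: str
    unit_index: int
    spikes: np.ndarray  # 0-based iEMG sample indices of waveform peaks
    template: np.ndarray  # placed waveform (mV)
    model: UnitModel


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    fs_emg: float
    fs_force: float
    units: list[TrueUnit]
    pairing: list[tuple[str, str, float, int]]  # emg, force label, code, sign
    cue: np.ndarray  # presented cue level at fs_force
    code_force: np.ndarray  # movement-code stream at fs_force
    targets: dict[str, np.ndarray]  # signed fraction-of-MVC targets, fs_force
    sync_emg: np.ndarray  # auxiliary sync channel at fs_emg (V)
    sync_force: np.ndarray  # recorded sync channel at fs_force (V)
    force_stream_v: dict[str, np.ndarray]  # raw 200 Hz force channels (V)

    def to_json_dict(self) -> dict:
        return {
            "fs_emg": self.fs_emg,
            "fs_force": self.fs_force,
            "units": [
                {
                    "channel": u.channel,
                    "unit_index": u.unit_index,
                    "spikes": u.spikes.tolist(),
                }
                for u in self.units
            ],
            "pairing": [
                {
                    "emg_channel": e,
                    "force_channel": f,
                    "movement_code": c,
                    "sign": s,
                }
                for e, f, c, s in self.pairing
            ],
        }


def _upsample_hold(stream: np.ndarray, fs_in: float, n_out: int, fs_out: float):
    idx = np.minimum(
        (np.arange(n_out) / fs_out * fs_in).astype(np.int64), stream.size - 1
    )
    return stream[idx]


def _place_spikes(signal: np.ndarray, spikes: np.ndarray, w: np.ndarray):
    peak = int(np.argmax(np.abs(w)))
    n = signal.size
    for s in spikes:
        lo = s - peak
        hi = lo + w.size
        wlo = max(0, -lo)
        whi = w.size - max(0, hi - n)
        if whi <= wlo:
            continue
        signal[max(0, lo) : min(n, hi)] += w[wlo:whi]


def synthesize_session(
    config: SessionConfig, seed: int | None = None
) -> tuple[SessionRecord, SyntheticGroundTruth]:
    """Generate a full synthetic session and its ground truth.

    The returned record holds iEMG channels (mV, ``fs_emg``), the force
    channels linearly up-sampled onto the iEMG grid but kept in raw sensor
    volts, the movement-code stream and the cue-level stream.  The ground
    truth also carries the raw 200 Hz force stream and both devices' sync
    channels for exercising the dual-stream alignment path.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    fs_e, fs_f = config.fs_emg, config.fs_force

    proto = generate_protocol(config.schedule, fs_f)
    n_f = proto.code.size
    duration = n_f / fs_f
    n_e = int(round(n_f * fs_e / fs_f))

    t_e = np.arange(n_e) / fs_e
    t_f = np.arange(n_f) / fs_f

    code_e = _upsample_hold(proto.code, fs_f, n_e, fs_e)
    cue_e = np.interp(t_e, t_f, proto.cue)

    # iEMG channels
    emg_cols: list[np.ndarray] = []
    units: list[TrueUnit] = []
    for ch in config.channels:
        target_e = np.interp(t_e, t_f, proto.targets[ch.joint])
        drive = np.clip(ch.sign * target_e, 0.0, 1.0)
        x = np.zeros(n_e)
        for ui, um in enumerate(ch.units):
            spikes = simulate_unit_train(drive, fs_e, um, rng)
            w = um.waveform(fs_e)
            _place_spikes(x, spikes, w)
            units.append(TrueUnit(ch.label, ui, spikes, w, um))
        if config.interference.noise_sd > 0:
            x += rng.normal(0.0, config.interference.noise_sd, n_e)
        for f0, amp in config.interference.harmonics.items():
            x += amp * np.sin(2.0 * np.pi * f0 * t_e + rng.uniform(0, 2 * np.pi))
        emg_cols.append(x)

    # force channels in raw sensor volts at 200 Hz
    force_stream_v: dict[str, np.ndarray] = {}
    for joint in config.schedule.joints:
        newtons = proto.targets[joint] * config.mvc_newtons
        v = newtons_to_volts(newtons)
        if config.force_noise_v > 0:
            v = v + rng.normal(0.0, config.force_noise_v, n_f)
        force_stream_v[joint] = v

    sync_e = sync_pulse_train(duration, fs_e, start_s=config.sync_start_s)
    sync_f = sync_pulse_train(duration, fs_f, start_s=config.sync_start_s)

    force_cols = [np.interp(t_e, t_f, force_stream_v[j]) for j in config.schedule.joints]
    labels = (
        [ch.label for ch in config.channels]
        + [FORCE_PREFIX + j for j in config.schedule.joints]
        + [CODE_LABEL, CUE_LABEL]
    )
    data = np.column_stack(emg_cols + force_cols + [code_e, cue_e])
    rec = SessionRecord(
        data=data, channels=labels, movements=mc.movement_table(), fs=fs_e
    ).validate()

    pairing = []
    for ch in config.channels:
        code = next(
            (
                float(st.base + st.substage / 10.0)
                for st in config.schedule.stages
                if ch.joint in st.joints
            ),
            0.0,
        )
        pairing.append((ch.label, FORCE_PREFIX + ch.joint, code, int(ch.sign)))

    truth = SyntheticGroundTruth(
        fs_emg=fs_e,
        fs_force=fs_f,
        units=units,
        pairing=pairing,
        cue=proto.cue,
        code_force=proto.code,
        targets=proto.targets,
        sync_emg=sync_e,
        sync_force=sync_f,
        force_stream_v=force_stream_v,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# defaults and config files
# ---------------------------------------------------------------------------


def default_units(n: int = 2) -> list[UnitModel]:
    """Distinct, physiologically plausible units with staggered recruitment."""
    presets = [
        UnitModel(recruitment_threshold=0.05, rate_min=8.0, rate_max=16.0,
                  amplitude_mv=0.8, duration_ms=7.0, asymmetry=0.35,
                  lobe_sep=0.2, flip=False),
        UnitModel(recruitment_threshold=0.35, rate_min=8.0, rate_max=15.0,
                  amplitude_mv=1.2, duration_ms=11.0, asymmetry=0.6,
                  lobe_sep=0.3, flip=True),
        UnitModel(recruitment_threshold=0.55, rate_min=9.0, rate_max=14.0,
                  amplitude_mv=1.6, duration_ms=9.0, asymmetry=0.1,
                  lobe_sep=0.35, flip=False),
    ]
    if not 1 <= n <= len(presets):
        raise ConfigError(f"default units available for 1..{len(presets)}")
    return [UnitModel(**vars(p)) for p in presets[:n]]


def default_schedule() -> ProtocolSchedule:
    """A compact schedule in protocol-table order covering four joints."""
    return ProtocolSchedule(
        stages=[
            Stage(1, 2, joints=("index",), signs=(1.0,), amplitude=0.8),
            Stage(1, 3, joints=("index",), signs=(1.0,), amplitude=0.6),
            Stage(4, 1, joints=("little",), signs=(-1.0,), amplitude=0.8),
            Stage(4, 3, joints=("little",), signs=(-1.0,), amplitude=0.6),
            Stage(6, 2, joints=("thumb_aa",), signs=(1.0,), amplitude=0.8),
            Stage(6, 3, joints=("thumb_aa",), signs=(1.0,), amplitude=0.6),
            Stage(7, 1, joints=("wrist_fe",), signs=(-1.0,), amplitude=0.8),
            Stage(7, 3, joints=("wrist_fe",), signs=(-1.0,), amplitude=0.6),
            Stage(20, 1, joints=("index", "thumb_aa"), signs=(1.0, 1.0),
                  amplitude=0.7, cue_s=3.0),
        ]
    )


def default_config(seed: int) -> SessionConfig:
    """Default study-like session: four muscles, two units each.

    Muscle/joint map follows the database convention (FDP drives little
    finger flexion with sign -1, EDC extension +1, etc.).
    """
    return SessionConfig(
        schedule=default_schedule(),
        channels=[
            ChannelConfig("FDP", "little", -1.0, default_units(2)),
            ChannelConfig("EDC", "index", 1.0, default_units(2)),
            ChannelConfig("FCR", "wrist_fe", -1.0, default_units(2)),
            ChannelConfig("APL", "thumb_aa", 1.0, default_units(2)),
        ],
        interference=InterferenceModel(
            harmonics={50.0: 0.05, 100.0: 0.02, 150.0: 0.015}, noise_sd=0.03
        ),
        seed=seed,
    )


def config_from_dict(d: dict) -> SessionConfig:
    """Build a SessionConfig from a plain (YAML/JSON) mapping."""
    schedule = ProtocolSchedule(
        stages=[Stage(**{**s, "joints": tuple(s["joints"])}) for s in d["schedule"]]
    )
    channels = [
        ChannelConfig(
            label=c["label"],
            joint=c["joint"],
            sign=float(c.get("sign", -1.0)),
            units=[UnitModel(**u) for u in c["units"]],
        )
        for c in d["channels"]
    ]
    interference = InterferenceModel(
        harmonics={float(k): float(v) for k, v in d.get("interference", {}).get("harmonics", {}).items()},
        noise_sd=float(d.get("interference", {}).get("noise_sd", 0.03)),
    )
    kwargs = {
        k: d[k]
        for k in ("fs_emg", "fs_force", "mvc_newtons", "force_noise_v", "sync_start_s")
        if k in d
    }
    if "seed" not in d:
        raise ConfigError("seed is a mandatory config field")
    return SessionConfig(
        schedule=schedule,
        channels=channels,
        interference=interference,
        seed=int(d["seed"]),
        **kwargs,
    ).validate()


def load_config(path) -> SessionConfig:
    """Load a session configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
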