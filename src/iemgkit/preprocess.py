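"""Pre-processing chain: harmonic notch bank, sync detection, alignment,
force up-sampling.

The powerline interference is removed with a bank of narrow IIR notch
filters centred at 50 Hz and its harmonics up to 5 kHz, each 2 Hz wide
(-3 dB), applied forward-backward so the multi-channel record keeps exact
inter-channel timing.  Dual-device synchronization uses the shared square
pulse train: edges are found on the differentiated sync channel, the pulse
counts of the two streams are compared as a completeness check, and the
offset between first leading edges aligns the time axes.  The 200 Hz force
stream is then linearly interpolated onto the iEMG sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal as sig

from .errors import AlignmentError, DesignError, LengthError

__all__ = [
    "NotchBankSpec",
    "SyncEvents",
    "AlignmentResult",
    "design_notch_bank",
    "apply_zero_phase",
    "select_active_notches",
    "detect_sync_pulses",
    "align_streams",
    "upsample_force",
]


# ---------------------------------------------------------------------------
# notch bank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NotchBankSpec:
    """A cascade of second-order notch filters at harmonic centers."""

    fs: float
    base: float
    width: float  # -3 dB bandwidth in Hz
    centers: tuple[float, ...]
    sos: np.ndarray = field(repr=False)  # (n_sections, 6)

    def subset(self, centers) -> "NotchBankSpec":
        """Restrict the bank to the given active centers."""
        centers = tuple(float(c) for c in centers)
        missing = set(centers) - set(self.centers)
        if missing:
            raise DesignError(f"centers {sorted(missing)} not in this bank")
        idx = [self.centers.index(c) for c in centers]
        sos = self.sos[idx] if idx else np.empty((0, 6))
        return NotchBankSpec(self.fs, self.base, self.width, centers, sos)

    def frequency_response(self, freqs) -> np.ndarray:
        """Complex single-pass response of the cascade at ``freqs`` (Hz)."""
        if len(self.centers) == 0:
            return np.ones(np.asarray(freqs).shape, dtype=complex)
        _, h = sig.sosfreqz(self.sos, worN=np.asarray(freqs, float), fs=self.fs)
        return h


def design_notch_bank(
    fs: float, base: float = 50.0, fmax: float = 5000.0, width: float = 2.0
) -> NotchBankSpec:
    """Design the harmonic notch bank: centers k*base for k*base <= fmax.

    Each section is a second-order IIR notch (zero on the unit circle at the
    center) with -3 dB bandwidth ``width``.
    """
    if fmax >= fs / 2:
        raise DesignError(f"fmax={fmax} Hz is not below Nyquist ({fs / 2} Hz)")
    if width <= 0:
        raise DesignError("notch width must be positive")
    centers = tuple(
        base * k for k in range(1, int(np.floor(fmax / base)) + 1)
    )
    sections = []
    for f0 in centers:
        b, a = sig.iirnotch(f0, Q=f0 / width, fs=fs)
        sections.append(np.hstack([b, a]))
    return NotchBankSpec(fs, base, width, centers, np.asarray(sections))


def apply_zero_phase(spec: NotchBankSpec, x: np.ndarray) -> np.ndarray:
    """Apply the bank forward-backward (zero net phase, length preserved)."""
    x = np.asarray(x, dtype=float)
    if len(spec.centers) == 0:
        return x.copy()
    padlen = 3 * (2 * spec.sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise LengthError(
            f"input of {x.shape[-1]} samples is shorter than the filter "
            f"transient ({padlen} samples)"
        )
    return sig.sosfiltfilt(spec.sos, x, axis=-1)


def select_active_notches(
    spec: NotchBankSpec,
    x: np.ndarray,
    factor: float = 3.0,
    band: float = 1.0,
    guard: float = 10.0,
) -> NotchBankSpec:
    """Keep only centers whose narrow-band power stands out of the baseline.

    A center is active when the mean periodogram power within ``center ±
    band`` exceeds ``factor`` times the median power of the surrounding
    ``± guard`` region (the band itself excluded).  This per-recording
    customization minimizes spectral distortion from unneeded notches.
    """
    x = np.asarray(x, dtype=float)
    freqs, pxx = sig.periodogram(x, fs=spec.fs, detrend="constant")
    active = []
    for f0 in spec.centers:
        in_band = (freqs >= f0 - band) & (freqs <= f0 + band)
        in_guard = (freqs >= f0 - guard) & (freqs <= f0 + guard) & ~in_band
        if not in_band.any() or not in_guard.any():
            continue
        baseline = float(np.median(pxx[in_guard]))
        if np.mean(pxx[in_band]) > factor * max(baseline, 1e-300):
            active.append(f0)
    return spec.subset(active)


# ---------------------------------------------------------------------------
# sync pulses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyncEvents:
    """Leading/trailing edge sample indices of complete sync pulses."""

    leading: np.ndarray
    trailing: np.ndarray
    fs: float

    @property
    def count(self) -> int:
        """Number of complete pulses (leading edge with a trailing edge)."""
        return len(self.leading)

    @property
    def leading_times(self) -> np.ndarray:
        return self.leading / self.fs

    @property
    def widths_s(self) -> np.ndarray:
        return (self.trailing - self.leading) / self.fs


def detect_sync_pulses(
    sync: np.ndarray, fs: float, debounce_s: float = 0.1
) -> SyncEvents:
    """Detect sync-pulse edges by differentiating the sync channel.

    Edges are taken where the first difference crosses half the pulse
    amplitude (estimated as peak minus median baseline); crossings closer
    than the debounce window collapse onto the first.  A final pulse with no
    trailing edge (signal ends high) is excluded from the count.
    """
    sync = np.asarray(sync, dtype=float)
    empty = SyncEvents(
        np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), fs
    )
    if sync.size < 2:
        return empty
    baseline = float(np.median(sync))
    amp = float(np.max(sync)) - baseline
    if amp <= 0:
        return empty
    thr = amp / 2.0
    d = np.diff(sync)
    rising = np.flatnonzero(d > thr) + 1  # first sample at high level
    falling = np.flatnonzero(d < -thr) + 1  # first sample back at low level
    debounce = max(1, int(round(debounce_s * fs)))
    rising = _debounce(rising, debounce)
    falling = _debounce(falling, debounce)

    # pair each leading edge with the next trailing edge before the next lead
    leading, trailing = [], []
    j = 0
    for i, r in enumerate(rising):
        while j < len(falling) and falling[j] <= r:
            j += 1
        if j >= len(falling):
            break  # truncated final pulse: excluded
        nxt = rising[i + 1] if i + 1 < len(rising) else np.inf
        if falling[j] < nxt:
            leading.append(r)
            trailing.append(falling[j])
            j += 1
    return SyncEvents(
        np.asarray(leading, dtype=np.int64),
        np.asarray(trailing, dtype=np.int64),
        fs,
    )


def _debounce(idx: np.ndarray, window: int) -> np.ndarray:
    """Collapse runs of crossings closer than ``window`` onto the first."""
    if idx.size == 0:
        return idx
    keep = [idx[0]]
    for i in idx[1:]:
        if i - keep[-1] >= window:
            keep.append(i)
    return np.asarray(keep, dtype=np.int64)


@dataclass(frozen=True)
class AlignmentResult:
    """Dual-stream alignment: offset between first leading edges."""

    offset_s: float  # positive: the second (force) stream started later
    verified: bool
    count_a: int
    count_b: int


def align_streams(
    emg_sync: SyncEvents, force_sync: SyncEvents, strict: bool = True
) -> AlignmentResult:
    """Align two streams on their first sync leading edges.

    ``offset_s = t_first_lead(emg) - t_first_lead(force)``; a positive value
    means the force stream started recording later.  Pulse counts are
    compared to verify both files hold the same data; with ``strict`` a
    mismatch raises :class:`~iemgkit.errors.AlignmentError`.
    """
    if emg_sync.count == 0 or force_sync.count == 0:
        raise AlignmentError(
            "cannot align: a stream has no complete sync pulses",
            emg_sync.count,
            force_sync.count,
        )
    verified = emg_sync.count == force_sync.count
    if strict and not verified:
        raise AlignmentError(
            f"sync pulse counts differ: {emg_sync.count} vs {force_sync.count}",
            emg_sync.count,
            force_sync.count,
        )
    offset = float(emg_sync.leading_times[0] - force_sync.leading_times[0])
    return AlignmentResult(offset, verified, emg_sync.count, force_sync.count)


# ---------------------------------------------------------------------------
# force up-sampling
# ---------------------------------------------------------------------------


def upsample_force(
    force: np.ndarray, fs_in: float = 200.0, fs_target: float = 10240.0
) -> np.ndarray:
    """Linearly interpolate a force series onto the iEMG sampling grid.

    The output grid spans the same time interval as the input; endpoints are
    held.  Linear interpolation guarantees the output stays within the input
    min/max bounds.
    """
    force = np.asarray(force, dtype=float)
    if force.size < 2:
        raise LengthError("need at least 2 samples to interpolate")
    t_in = np.arange(force.size) / fs_in
    n_out = int(np.floor(t_in[-1] * fs_target)) + 1
    t_out = np.arange(n_out) / fs_target
    return np.interp(t_out, t_in, force)
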