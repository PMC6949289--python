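"""Envelope extraction and quantitative quality control.

* RMS envelope over a 250 ms window sliding in one-sample steps, either
  centered (zero phase) or causal (the centered envelope delayed by half the
  window — 1280 samples at 10240 Hz).  Envelopes are not normalized.
* Pairwise channel cross-correlation: per pair, the maximum absolute
  normalized cross-correlation within a +/-100 ms lag window, aggregated as
  the median with 5th/95th percentiles across movement segments.  Low values
  certify the selectivity of the fine-wire channels.
* Welch amplitude-spectrum percentile summaries across a signal collection.
* A computational channel/force pairing table: for each iEMG channel, the
  force channel and movement during which its envelope correlates most with
  the measured force, with the sign of that association.  This is a
  computational surrogate for the expert-derived pairing table and is
  labelled as such in its output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal as sig

from .errors import LengthError
from .records import SessionRecord, segment_by_code, volts_to_newtons

__all__ = [
    "EnvelopeSeries",
    "CrossCorrMatrix",
    "SpectrumSummary",
    "PairingEntry",
    "rms_envelope",
    "channel_crosscorr",
    "spectrum_summary",
    "pair_channels_with_forces",
]


# ---------------------------------------------------------------------------
# RMS envelope
# ---------------------------------------------------------------------------


@dataclass
class EnvelopeSeries:
    """A non-negative RMS envelope, same length as its source signal."""

    values: np.ndarray
    fs: float
    window_ms: float
    mode: str  # "zero-phase" or "causal"

    @property
    def shift_samples(self) -> int:
        """Causal delay relative to zero phase: half the window."""
        return int(round(self.window_ms * self.fs / 1000.0)) // 2


def rms_envelope(
    x: np.ndarray, fs: float, window_ms: float = 250.0, causal: bool = False
) -> EnvelopeSeries:
    """Sliding-window RMS envelope, one-sample steps.

    The window of ``round(window_ms * fs / 1000)`` samples is centered on
    the current sample (zero phase); boundary windows shrink to the
    available samples rather than padding.  With ``causal=True`` the
    centered envelope is delayed by half the window (the first half-window
    holds the initial value), which restores causality for real-time-style
    consumption.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    w = int(round(window_ms * fs / 1000.0))
    if w >= n:
        raise LengthError(f"window of {w} samples >= signal of {n} samples")
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(x**2)])
    i = np.arange(n)
    lo = np.clip(i - half, 0, n)
    hi = np.clip(i + (w - half), 0, n)
    vals = np.sqrt((csum[hi] - csum[lo]) / (hi - lo))
    if causal:
        shifted = np.empty_like(vals)
        shifted[half:] = vals[: n - half]
        shifted[:half] = vals[0]
        vals = shifted
    return EnvelopeSeries(vals, fs, window_ms, "causal" if causal else "zero-phase")


# ---------------------------------------------------------------------------
# cross-correlation QC
# ---------------------------------------------------------------------------


@dataclass
class CrossCorrMatrix:
    """Pairwise channel similarity: median with 5th/95th percentiles."""

    labels: list[str]
    median: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    excluded: list[str] = field(default_factory=list)  # zero-variance channels


def _max_abs_xcorr(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Max |normalized cross-correlation| over lags within +/- max_lag."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if denom == 0:
        return float("nan")
    c = sig.correlate(a, b, mode="full", method="auto") / denom
    mid = b.size - 1
    lo = max(0, mid - max_lag)
    hi = min(c.size, mid + max_lag + 1)
    return float(np.max(np.abs(c[lo:hi])))


def channel_crosscorr(
    rec: SessionRecord,
    per_segment: bool = True,
    max_lag_ms: float = 100.0,
    labels: list[str] | None = None,
) -> CrossCorrMatrix:
    """Pairwise max-|cross-correlation| QC matrix of the iEMG channels.

    With ``per_segment`` the coefficient is computed inside each movement
    segment (runs of a constant movement code) and aggregated as the median
    with 5th/95th percentiles; otherwise the whole record forms a single
    segment.  Channels with zero variance are flagged and excluded.
    """
    labels = list(labels) if labels is not None else rec.emg_labels
    if len(labels) < 2:
        raise ValueError("need at least two iEMG channels")
    cols = {lab: rec.column(lab) for lab in labels}
    excluded = [lab for lab, x in cols.items() if np.std(x) == 0]
    active = [lab for lab in labels if lab not in excluded]
    max_lag = int(round(max_lag_ms * rec.fs / 1000.0))

    segments: list[tuple[int, int]] = []
    if per_segment:
        stream = np.round(rec.code_stream() * 100).astype(np.int64)
        for code in np.unique(stream):
            if code == 0:
                continue
            segments.extend(segment_by_code(rec, code / 100.0))
        segments = [s for s in segments if s[1] - s[0] > 2 * max_lag]
    if not segments:
        segments = [(0, rec.data.shape[0])]

    k = len(active)
    stack = np.ones((len(segments), k, k))
    for si, (s0, s1) in enumerate(segments):
        for i in range(k):
            for j in range(i + 1, k):
                v = _max_abs_xcorr(cols[active[i]][s0:s1], cols[active[j]][s0:s1], max_lag)
                stack[si, i, j] = stack[si, j, i] = v

    med = np.nanmedian(stack, axis=0)
    p5 = np.nanpercentile(stack, 5, axis=0)
    p95 = np.nanpercentile(stack, 95, axis=0)
    for m in (med, p5, p95):
        np.fill_diagonal(m, 1.0)
    return CrossCorrMatrix(active, med, p5, p95, excluded)


# ---------------------------------------------------------------------------
# spectrum summary
# ---------------------------------------------------------------------------


@dataclass
class SpectrumSummary:
    """Pointwise amplitude-spectrum percentiles across a signal collection."""

    freqs: np.ndarray
    percentiles: dict[int, np.ndarray]  # {9, 25, 50, 75, 91} -> band


def spectrum_summary(
    signals, fs: float, seg_seconds: float = 1.0
) -> SpectrumSummary:
    """Welch amplitude spectra (Hann, 1 s segments, 50% overlap) summarised
    as pointwise 9/25/50/75/91 percentiles across the collection."""
    signals = [np.asarray(s, dtype=float) for s in signals]
    if not signals:
        raise ValueError("empty signal collection")
    nperseg = int(round(seg_seconds * fs))
    spectra = []
    freqs = None
    for s in signals:
        f, pxx = sig.welch(
            s, fs=fs, window="hann", nperseg=min(nperseg, s.size),
            noverlap=min(nperseg, s.size) // 2,
        )
        if freqs is None:
            freqs = f
        elif f.shape != freqs.shape or not np.allclose(f, freqs):
            raise ValueError("signals yield inconsistent frequency grids")
        spectra.append(np.sqrt(pxx))
    arr = np.vstack(spectra)
    pct = {q: np.percentile(arr, q, axis=0) for q in (9, 25, 50, 75, 91)}
    return SpectrumSummary(freqs, pct)


# ---------------------------------------------------------------------------
# channel/force pairing
# ---------------------------------------------------------------------------


@dataclass
class PairingEntry:
    """Computationally derived iEMG/force channel association.

    ``sign`` is the direction of the force during this channel's activity on
    the bidirectional transducers (flexion negative).  Metadata note: this
    table is a computational surrogate for the expert-reviewed pairing of
    the deposited archive.
    """

    emg_channel: str
    force_channel: str
    movement_code: float  # base code of the maximal-association movement
    sign: int
    score: float  # |r| of the winning association
    paired: bool


def pair_channels_with_forces(
    rec: SessionRecord,
    envelopes: dict[str, EnvelopeSeries] | None = None,
    floor: float = 0.3,
    tie_margin: float = 0.05,
) -> list[PairingEntry]:
    """Associate each iEMG channel with the force channel it best explains.

    For every (force channel, base movement) pair, the Pearson correlation
    between the channel's RMS envelope and the force (in newtons) is
    computed over that movement's samples; the winner is the pair with the
    largest |r| and the sign of that correlation becomes the entry sign.

    Movements where the top two force channels correlate within
    ``tie_margin`` of each other are skipped as non-identifying: during
    synergistic stages several joints are driven by the same cue, so every
    co-driven force explains the envelope equally well and only the
    channel's discriminating (typically single-DoF) movements can attribute
    it.  Channels whose best |r| stays below ``floor`` are marked unpaired.
    """
    if envelopes is None:
        envelopes = {
            lab: rms_envelope(rec.column(lab), rec.fs) for lab in rec.emg_labels
        }
    stream = np.round(rec.code_stream() * 100).astype(np.int64)
    bases = sorted({c // 100 for c in np.unique(stream) if c != 0})
    masks = {b: (stream // 100) == b for b in bases}
    forces_n = {
        lab: volts_to_newtons(rec.column(lab)) for lab in rec.force_labels
    }

    entries = []
    for emg_lab, env in envelopes.items():
        best = (0.0, "", 0.0, 1)  # |r|, force label, code, sign
        for b in bases:
            m = masks[b]
            if m.sum() < 2:
                continue
            e = env.values[m]
            if np.std(e) == 0:
                continue
            rs = []
            for f_lab, f_n in forces_n.items():
                f = f_n[m]
                if np.std(f) == 0:
                    continue
                rs.append((float(np.corrcoef(e, f)[0, 1]), f_lab))
            if not rs:
                continue
            rs.sort(key=lambda t: abs(t[0]), reverse=True)
            if len(rs) > 1 and abs(rs[0][0]) - abs(rs[1][0]) < tie_margin:
                continue  # ambiguous movement: co-driven forces
            r, f_lab = rs[0]
            if abs(r) > best[0]:
                best = (abs(r), f_lab, float(b), 1 if r >= 0 else -1)
        score, f_lab, code, sign = best
        entries.append(
            PairingEntry(
                emg_channel=emg_lab,
                force_channel=f_lab,
                movement_code=code,
                sign=sign,
                score=score,
                paired=score >= floor,
            )
        )
    return entries
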