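"""Three-pass template-matching motor-unit spike sorter.

Candidate MUAPs are detected by an amplitude threshold on the filtered
signal and compared against a growing set of waveform templates.  A
candidate matches a template when, after aligning at the lag that maximizes
their cross-correlation, (a) the correlation coefficient exceeds 0.9 and
(b) the mean square difference is below half the template power.  The sorter
runs three chronological passes over the candidates:

1. assign-or-create — a matching template is updated with the running mean,
   otherwise the candidate seeds a new template;
2. re-process every candidate, updating templates but never creating;
3. label every candidate with its best accepted template or "unknown".

After each of the first two passes, templates holding less than 5% of all
candidates are discarded.  The whole procedure is deterministic for a given
candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal as sig

from .records import SpikeSortResult

__all__ = [
    "CandidateEvent",
    "Template",
    "MatchScore",
    "detect_candidates",
    "match",
    "update_template",
    "sort",
    "R_THRESHOLD",
    "MSE_POWER_FRACTION",
    "PRUNE_SHARE",
]

#: match criterion (a): correlation coefficient after alignment
R_THRESHOLD = 0.9
#: match criterion (b): MSE below this fraction of template power
MSE_POWER_FRACTION = 0.5
#: templates with less than this share of all MUAPs are discarded
PRUNE_SHARE = 0.05


@dataclass(frozen=True)
class CandidateEvent:
    """A detected MUAP: peak sample index plus a centered snippet."""

    peak: int
    snippet: np.ndarray  # odd fixed length, mV


@dataclass
class Template:
    """A unit's running-mean waveform with its member count."""

    waveform: np.ndarray
    count: int = 1

    @property
    def power(self) -> float:
        """Mean of squared waveform samples (updated with the waveform)."""
        return float(np.mean(self.waveform**2))


@dataclass(frozen=True)
class MatchScore:
    """Similarity of a snippet to a template after optimal-lag alignment."""

    r: float
    mse: float
    lag: int
    accepted: bool
    valid: bool = True  # False when r is undefined (zero-variance snippet)


def detect_candidates(
    x: np.ndarray,
    fs: float,
    threshold_mult: float = 5.0,
    window_ms: float = 10.0,
) -> list[CandidateEvent]:
    """Threshold detection of candidate MUAPs on a filtered channel.

    The threshold is ``threshold_mult`` times the robust noise SD
    (median(|x|)/0.6745).  Peaks of |x| closer than one snippet window merge
    onto the larger peak; snippets are extracted centered on the absolute
    peak and zero-padded at the signal boundaries.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window_ms * fs / 1000.0))
    w += 1 - w % 2
    half = w // 2
    sd = float(np.median(np.abs(x))) / 0.6745
    thr = threshold_mult * sd
    if x.size == 0 or thr <= 0:
        return []
    peaks, _ = sig.find_peaks(np.abs(x), height=thr, distance=w)
    events = []
    for p in peaks:
        snippet = np.zeros(w)
        lo = p - half
        hi = p + half + 1
        slo = max(0, lo)
        shi = min(x.size, hi)
        snippet[slo - lo : shi - lo] = x[slo:shi]
        events.append(CandidateEvent(int(p), snippet))
    return events


def _best_lag(snippet: np.ndarray, template: np.ndarray, max_lag: int) -> int:
    c = sig.correlate(snippet, template, mode="full")
    n = template.size
    lags = np.arange(-(n - 1), n)
    mask = np.abs(lags) <= max_lag
    return int(lags[mask][np.argmax(c[mask])])


def match(
    snippet: np.ndarray,
    template: np.ndarray | Template,
    r_threshold: float = R_THRESHOLD,
    mse_fraction: float = MSE_POWER_FRACTION,
    max_lag: int | None = None,
) -> MatchScore:
    """Score a snippet against a template.

    The snippet is aligned at the lag (within +/- half the window) that
    maximizes the cross-correlation; r and MSE are computed on the aligned
    overlap.  Acceptance requires r > ``r_threshold`` and MSE below
    ``mse_fraction`` of the template power.  A zero-variance snippet has
    undefined r and is rejected with ``valid=False``.
    """
    tw = template.waveform if isinstance(template, Template) else np.asarray(template, float)
    s = np.asarray(snippet, dtype=float)
    if s.shape != tw.shape:
        raise ValueError("snippet and template must have equal length")
    n = tw.size
    if max_lag is None:
        max_lag = n // 2
    lag = _best_lag(s, tw, max_lag)
    # aligned overlap: s[k + lag] against tw[k]
    k0 = max(0, -lag)
    k1 = n - max(0, lag)
    a = s[k0 + lag : k1 + lag]
    b = tw[k0:k1]
    power = float(np.mean(tw**2))
    if np.std(a) == 0 or np.std(b) == 0:
        return MatchScore(float("nan"), float(np.mean((a - b) ** 2)), lag,
                          accepted=False, valid=False)
    r = float(np.corrcoef(a, b)[0, 1])
    mse = float(np.mean((a - b) ** 2))
    accepted = r > r_threshold and mse < mse_fraction * power
    return MatchScore(r, mse, lag, accepted)


def _aligned_full(snippet: np.ndarray, lag: int) -> np.ndarray:
    """Shift a snippet by ``lag`` samples onto the template frame (zero pad)."""
    out = np.zeros_like(snippet)
    n = snippet.size
    k0 = max(0, -lag)
    k1 = n - max(0, lag)
    out[k0:k1] = snippet[k0 + lag : k1 + lag]
    return out


def update_template(t: Template, aligned_snippet: np.ndarray) -> Template:
    """Fold an accepted snippet into the running-mean template.

    waveform <- (n * waveform + snippet) / (n + 1); power follows the
    updated waveform.
    """
    n = t.count
    t.waveform = (n * t.waveform + np.asarray(aligned_snippet, float)) / (n + 1)
    t.count = n + 1
    return t


def _best_accepted(
    snippet: np.ndarray,
    templates: list[Template],
    r_threshold: float,
    mse_fraction: float,
) -> tuple[int, MatchScore] | None:
    """Best accepted template: highest r, ties by lower MSE, then index."""
    best = None
    for i, t in enumerate(templates):
        m = match(snippet, t, r_threshold, mse_fraction)
        if not m.accepted:
            continue
        if best is None or (m.r, -m.mse) > (best[1].r, -best[1].mse):
            best = (i, m)
    return best


def sort(
    events: list[CandidateEvent],
    fs: float,
    r_threshold: float = R_THRESHOLD,
    mse_fraction: float = MSE_POWER_FRACTION,
    prune_share: float = PRUNE_SHARE,
) -> SpikeSortResult:
    """Run the three-pass sorter over chronologically ordered candidates."""
    if any(events[i].peak > events[i + 1].peak for i in range(len(events) - 1)):
        raise ValueError("events must be in chronological order")
    total = len(events)
    if total == 0:
        return SpikeSortResult(samples=[], templates=[], fs=fs)

    templates: list[Template] = []

    # pass 1: assign-or-create
    counts = []
    for ev in events:
        best = _best_accepted(ev.snippet, templates, r_threshold, mse_fraction)
        if best is None:
            templates.append(Template(ev.snippet.copy(), count=1))
            counts.append(1)
        else:
            i, m = best
            update_template(templates[i], _aligned_full(ev.snippet, m.lag))
            counts[i] += 1
    keep = [c / total >= prune_share for c in counts]
    templates = [t for t, k in zip(templates, keep) if k]

    # pass 2: update only, never create
    if templates:
        counts = [0] * len(templates)
        for ev in events:
            best = _best_accepted(ev.snippet, templates, r_threshold, mse_fraction)
            if best is not None:
                i, m = best
                update_template(templates[i], _aligned_full(ev.snippet, m.lag))
                counts[i] += 1
        keep = [c / total >= prune_share for c in counts]
        templates = [t for t, k in zip(templates, keep) if k]

    # pass 3: label to best accepted template or unknown
    assigned: list[list[int]] = [[] for _ in templates]
    unknown: list[int] = []
    for ev in events:
        best = _best_accepted(ev.snippet, templates, r_threshold, mse_fraction)
        if best is None:
            unknown.append(ev.peak)
        else:
            assigned[best[0]].append(ev.peak)

    return SpikeSortResult(
        samples=[np.asarray(a, dtype=np.int64) for a in assigned],
        templates=[t.waveform.copy() for t in templates],
        fs=fs,
        unknown=np.asarray(unknown, dtype=np.int64),
    ).validate()
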