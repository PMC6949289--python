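"""Empirical probes of the pipeline's decision rules.

These helpers measure, rather than restate, the thresholds baked into the
sorter and the generator: they construct controlled inputs, run the actual
implementation, and locate decision boundaries by bisection or direct
measurement.  They back both the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import spikesort as ss
from .preprocess import (
    apply_zero_phase,
    design_notch_bank,
    detect_sync_pulses,
    select_active_notches,
)
from .synthetic import (
    default_config,
    muap_template,
    sync_pulse_train,
    synthesize_session,
)

__all__ = [
    "snippet_with_correlation",
    "locate_correlation_boundary",
    "locate_pruning_boundary",
    "measure_sync_train",
    "score_sorter_on_default_session",
]


def _probe_template(n: int = 103, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A zero-mean template plus a smooth zero-mean direction orthogonal to it."""
    rng = np.random.default_rng(seed)
    t = muap_template(10240.0, duration_ms=n / 10.24, amplitude_mv=1.0)
    if t.size != n:
        t = t[:n] if t.size > n else np.pad(t, (0, n - t.size))
    t = t - t.mean()
    # smooth orthogonal perturbation: low-pass noise, centered, projected
    q = np.convolve(rng.normal(size=n + 40), np.hanning(41) / 21.0, mode="valid")
    q = q - q.mean()
    q -= (q @ t) / (t @ t) * t
    q = q - q.mean()
    q -= (q @ t) / (t @ t) * t  # re-project after re-centering
    return t, q


def snippet_with_correlation(r: float, n: int = 103, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Construct (template, snippet) whose centered correlation is exactly r.

    snippet = template + beta * q with q orthogonal to the template, where
    beta is solved from r; the MSE then equals (1/r^2 - 1) times the
    template power, comfortably below the half-power criterion throughout
    the bisection bracket.
    """
    t, q = _probe_template(n, seed)
    var_t = float(np.var(t))
    var_q = float(np.var(q))
    beta = np.sqrt((1.0 / r**2 - 1.0) * var_t / var_q)
    return t, t + beta * q


def locate_correlation_boundary(
    lo: float = 0.85, hi: float = 0.95, tol: float = 0.001, seed: int = 0
) -> float:
    """Bisect the accept/reject outcome of the match rule over correlation.

    Candidate snippets are built with a continuously varying aligned
    correlation while their MSE stays below half the template power, so the
    correlation criterion is the binding one inside the bracket.
    """

    def score(r: float) -> ss.MatchScore:
        t, s = snippet_with_correlation(r, seed=seed)
        return ss.match(s, t)

    if score(lo).accepted or not score(hi).accepted:
        raise RuntimeError("bisection bracket does not straddle the boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if score(mid).accepted:
            hi = mid
        else:
            lo = mid
    # report the boundary in the units the rule thresholds: the aligned
    # correlation coefficient of the marginal snippet
    return float(score(0.5 * (lo + hi)).r)


def locate_pruning_boundary(
    n_events: int = 2000,
    lo_pct: float = 2.0,
    hi_pct: float = 8.0,
    tol_pct: float = 0.05,
    fs: float = 10240.0,
) -> float:
    """Bisect the minority-unit share (in %) below which its template is
    discarded by the full three-pass sorter.

    Noiseless two-unit event streams are built with the minority share swept
    between the bracket ends; the granularity is one event (100/n_events %).
    Returns the bracket midpoint between the largest discarded and smallest
    kept share.
    """
    wa = muap_template(fs, duration_ms=7.0, amplitude_mv=1.0, asymmetry=0.35)
    wb = muap_template(fs, duration_ms=7.0, amplitude_mv=1.2, asymmetry=0.6,
                       lobe_sep=0.35, flip=True)
    n = wa.size
    spacing = 4 * n

    def minority_kept(share_pct: float) -> bool:
        k = int(round(share_pct / 100.0 * n_events))
        k = max(1, k)
        # spread minority events evenly through the chronological stream
        is_minor = np.zeros(n_events, dtype=bool)
        pos = np.linspace(0, n_events - 1, k).astype(int)
        is_minor[pos] = True
        events = [
            ss.CandidateEvent(i * spacing, (wb if m else wa).copy())
            for i, m in enumerate(is_minor)
        ]
        res = ss.sort(events, fs)
        for tmpl in res.templates:
            num = float(np.dot(tmpl - tmpl.mean(), wb - wb.mean()))
            den = np.std(tmpl) * np.std(wb) * n
            if den > 0 and num / den > 0.99:
                return True
        return False

    if minority_kept(lo_pct) or not minority_kept(hi_pct):
        raise RuntimeError("bisection bracket does not straddle the boundary")
    lo, hi = lo_pct, hi_pct
    while hi - lo > tol_pct:
        mid = 0.5 * (lo + hi)
        if minority_kept(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def measure_sync_train(
    duration_s: float = 60.0, fs: float = 200.0
) -> dict[str, float]:
    """Generate the default sync channel and measure rate, width and count.

    The rate is the reciprocal of the mean inter-onset interval of the
    detected leading edges; the width is the mean leading-to-trailing edge
    separation (half-amplitude crossings of the differentiated signal).
    """
    sync = sync_pulse_train(duration_s, fs)
    ev = detect_sync_pulses(sync, fs)
    if ev.count < 2:
        raise RuntimeError("too few pulses detected to measure the train")
    onsets = ev.leading_times
    rate = 1.0 / float(np.mean(np.diff(onsets)))
    width_ms = float(np.mean(ev.widths_s)) * 1000.0
    return {"rate_hz": rate, "width_ms": width_ms, "count": float(ev.count)}


def _aligned_r(a: np.ndarray, b: np.ndarray) -> float:
    n = max(a.size, b.size)
    a = np.pad(a, (0, n - a.size))
    b = np.pad(b, (0, n - b.size))
    m = ss.match(a, b, max_lag=n - 1)
    return m.r if m.valid else float("-inf")


def score_sorter_on_default_session(
    seed: int, tol_ms: float = 1.0
) -> dict[str, float]:
    """Run the full pipeline on a default synthetic session and score it.

    Generates the default session, notch-filters each iEMG channel, runs
    detection and the three-pass sorter, maps each recovered template to its
    generating unit by aligned correlation, and reports:

    * ``assignment_accuracy`` — among detected events lying within
      ``tol_ms`` of a true spike, the fraction assigned to the correct unit;
    * ``template_r_min`` — worst, over true units, of the best aligned
      correlation between any recovered template and that unit's waveform
      (extra clusters seeded by unresolved MUAP superpositions may also
      survive; they are judged through the assignment metric instead);
    * ``spike_recall`` — fraction of all true spikes recovered on the
      correct unit within ``tol_ms`` (depressed by MUAP superpositions,
      which merge at detection and are not resolved).
    """
    rec, truth = synthesize_session(default_config(seed))
    bank = design_notch_bank(rec.fs)
    tol = int(round(tol_ms * 1e-3 * rec.fs))
    n_labelable = 0
    n_correct = 0
    n_true = 0
    n_recalled = 0
    template_r_min = 1.0
    for lab in rec.emg_labels:
        x = rec.column(lab)
        xf = apply_zero_phase(select_active_notches(bank, x), x)
        events = ss.detect_candidates(xf, rec.fs)
        res = ss.sort(events, rec.fs)
        true_units = [u for u in truth.units if u.channel == lab]
        n_true += sum(u.spikes.size for u in true_units)
        rmap = {}
        for ri, w in enumerate(res.templates):
            scores = [(_aligned_r(w, u.template), u.unit_index) for u in true_units]
            rmap[ri] = max(scores)[1]
        for u in true_units:
            if res.templates:
                best = max(_aligned_r(w, u.template) for w in res.templates)
                template_r_min = min(template_r_min, best)
        for ri, train in enumerate(res.samples):
            for s in train:
                true_label = next(
                    (
                        u.unit_index
                        for u in true_units
                        if np.any(np.abs(u.spikes - s) <= tol)
                    ),
                    None,
                )
                if true_label is None:
                    continue
                n_labelable += 1
                if rmap[ri] == true_label:
                    n_correct += 1
        for u in true_units:
            rec_trains = [
                res.samples[ri] for ri in rmap if rmap[ri] == u.unit_index
            ]
            if rec_trains:
                allspk = np.concatenate(rec_trains)
                n_recalled += int(
                    sum(np.any(np.abs(allspk - s) <= tol) for s in u.spikes)
                )
        for s in res.unknown:
            if any(np.any(np.abs(u.spikes - s) <= tol) for u in true_units):
                n_labelable += 1
    return {
        "assignment_accuracy": n_correct / max(n_labelable, 1),
        "template_r_min": template_r_min,
        "spike_recall": n_recalled / max(n_true, 1),
        "n_true_spikes": float(n_true),
        "n_detected_true": float(n_labelable),
    }
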