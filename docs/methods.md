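# Methods

This note documents the models, parameters and numerical choices behind
iemgkit, and what the synthetic-data tests do and do not establish about
real recordings.

## Signal model and session layout

A session is a sample-by-channel matrix at 10240 Hz holding iEMG channels
(mV), force-sensor channels (raw volts), a movement-code stream and a
cue-level stream, with channel labels, a movement table, and the sampling
rate. Forces stay in sensor volts inside the container, as deposited;
conversion is explicit through the affine calibration `force = v·40 − 100 N`
(0–5 V spanning ±100 N), which is exactly invertible. Spike-sort metadata
stores per-unit spike sample lists, the same lists divided by the sampling
rate, and waveform templates; on disk the indices are 1-based (MATLAB
provenance of the published files), in memory 0-based, with the IO layer
performing the shift.

Movement codes are held internally as integers scaled by 100 (311 for 3.11)
because 0.01 increments are not representable in binary floating point;
files keep the published float encoding and all comparisons happen at
two-decimal precision. Cue-driven stages (MVC, synergies) carry the
x.x0/x.x1 rest/cue digit; tracking stages (sine, circle, trumpet) do not,
and their decoded cue state is "not applicable".

## Synthetic sessions

The generator emulates the recording protocol and physiology so that every
pipeline stage can be scored against ground truth:

- **Protocol.** Stages follow the movement-table order. MVC cues last
  exactly 5 s; sine tracking cues run at 0.1 Hz; circle cues use the lesser
  of the two referenced single-DoF amplitudes as radius; synergies are 4
  repetitions. Default stage padding (2 s rests, 2 tracking cycles, 3 s
  synergy cues) keeps a default session at ~138 s — long enough for a few
  hundred spikes per unit while the full suite stays desk-scale.
- **Motor units.** A MUAP is a sum of two Gaussian-derivative lobes with
  configurable support (default 7–11 ms), asymmetry and polarity, zero-mean,
  peak-normalized to the configured amplitude (defaults 0.8–1.6 mV). Firing
  is a gamma-renewal process simulated by time rescaling: silent below the
  recruitment threshold, instantaneous rate linear in excess drive between
  `rate_min` (8 Hz) and `rate_max` (14–16 Hz), ISI coefficient of variation
  `jitter` (0.15 default; 0 gives a deterministic train whose count equals
  the integrated rate). These ranges follow standard clinical EMG values;
  the source publication gives only qualitative statements ("physiological
  amplitude, duration and frequency"), so all are config-overridable.
- **Noise.** Broadband Gaussian noise (0.03 mV SD default) plus sinusoidal
  powerline harmonics restricted to 50 Hz multiples with random phases.
- **Forces and sync.** Force targets (fractions of MVC, flexion negative on
  the bidirectional transducers) are converted to sensor volts through the
  inverse calibration at 200 Hz; both device streams carry the 5 V, 200 ms,
  0.5 Hz synchronization pulse train. The first pulse onset sits at t = 1 s
  so edge detection has a clean baseline.
- **Ground truth** records every unit's spike samples (waveform-peak
  aligned), the unit-to-channel map, the channel/force pairing with sign,
  the cue trace, and the raw 200 Hz force stream.

What the generator does **not** model: volume conduction, electrode
migration, the expert-graded "questionable"/"bad" channel pathologies,
inter-channel crosstalk (channels share no sources by default), or
superposition-resolving structure. Passing tests therefore certify the
computation — filtering, alignment, sorting mechanics, envelope and pairing
logic — not robustness to every pathology of real fine-wire data.

## Pre-processing

- **Notch bank.** One second-order IIR notch per 50 Hz harmonic up to
  5 kHz, −3 dB bandwidth 2 Hz ("2 Hz width" is not defined in the source;
  −3 dB single-pass is adopted and configurable), applied forward-backward
  (zero phase, length preserving). Per-recording customization keeps only
  centers whose ±1 Hz periodogram band exceeds 3× the median of the
  surrounding ±10 Hz. Idempotence holds in the stopband sense: repeated
  application leaves annihilated bins annihilated and changes the
  mid-harmonic passband (> 20 Hz from every center) by < 0.5% RMS; the
  biquad skirts do keep attenuating transition-band energy on every pass,
  so whole-signal RMS is not invariant.
- **Sync detection.** Edges where the first difference of the sync channel
  crosses ± half the pulse amplitude (peak minus median baseline — the
  amplifier's auxiliary-input scaling is unknown, so detection is
  amplitude-normalized); crossings within a 100 ms debounce window (half
  the pulse width) collapse onto the first; a final pulse with no trailing
  edge is excluded from the count. Alignment offset is the difference of
  first leading-edge times (positive = force stream started later);
  mismatched pulse counts raise an error carrying both counts.
- **Force up-sampling.** Linear interpolation onto the iEMG grid with held
  endpoints; linearity guarantees no overshoot.

## Spike sorter

Detection threshold 5× the robust SD (`median(|x|)/0.6745`); snippet window
10 ms (103 samples at 10240 Hz, forced odd); one event per local maximum of
`|x|` within a window (closer peaks merge onto the larger). The match rule
aligns at the lag maximizing the (signed) cross-correlation within ± half a
window and requires aligned correlation > 0.9 and MSE < half the template
power; template power follows the current running-mean waveform, making
pass-1 acceptance order-dependent exactly as an online chronological
algorithm implies. Pass 2 re-evaluates acceptance with the evolving
templates and updates them without creating new ones; pruning (< 5% member
share) runs after each of the first two passes using that pass's assignment
counts. Pass 3 labels every event by its best accepted template — highest
r, ties by lower MSE, then lower template index — or "unknown"; events of a
discarded template are not reassigned unless they independently satisfy the
criteria. The procedure is deterministic for a given event order.

Two consequences worth knowing. First, the lag search maximizes the signed
cross-correlation, so an inverted waveform may align at a shifted lag with
a positive (but sub-threshold) correlation rather than r = −1; it is
rejected either way. Second, MUAPs from different units that coincide
within the detection merge window produce a single event: on default
synthetic sessions ~97–98% of detected true-spike events are assigned to
the correct unit and every true unit's waveform is recovered at r > 0.97,
but recall against all true spikes is ~87% because the merged partner of a
superposition is never detected. Resolving superpositions is out of scope.
Occasional extra templates seeded by recurring superpositions can survive
pruning; they are judged through the assignment metric.

## Features and QC

The RMS envelope uses a 250 ms window (2560 samples at 10240 Hz) sliding in
one-sample steps, centered on the current sample; boundary windows shrink
to the available samples (no padding, avoiding amplitude bias within half a
window of the ends). The causal variant is the centered envelope delayed by
half the window — 1280 samples (125 ms) at 10240 Hz — with the first
half-window holding the initial value. Envelopes are not normalized.

Channel cross-correlation takes, per pair, the maximum absolute normalized
cross-correlation within ±100 ms (capturing near-synchronous crosstalk; the
cap is configurable), computed per movement segment on notch-filtered
channels and aggregated as the median with 5th/95th percentiles; the
source's "5th and 95th quartile" wording is read as percentiles, and
per-movement aggregation with a whole-record option resolves its silence on
the segmentation. Spectra are Welch estimates (Hann, 1 s segments, 50%
overlap; the estimator is not specified in the source), summarised as
pointwise 9/25/50/75/91 amplitude percentiles.

The pairing table associates each iEMG channel with the (force channel,
movement) maximizing the |Pearson correlation| between its envelope and the
force in newtons over that movement's samples; the correlation's sign is
the entry sign and |r| < 0.3 marks a channel unpaired. Movements in which
the top two force channels correlate within a 0.05 margin are skipped as
non-identifying: synergistic stages drive several joints with the same cue,
and a scale-invariant correlation cannot attribute the envelope among
co-driven forces — pairing must happen during a channel's discriminating
(single-DoF) movement, which is also how the expert-derived table of the
deposited archive is organised. The computational table is a surrogate for
that expert review and says so in its output metadata.

## Problem sizes and determinism

Default synthetic sessions are ~138 s, four channels, two units each —
large enough for stable statistics (≈ 2200 true spikes) while a full test
run stays around a minute. Decision boundaries are located by bisection on
constructed inputs: the correlation boundary on snippet families with
exactly controlled aligned correlation (reported in the units the rule
thresholds), the pruning boundary on 2000-event two-unit streams (0.05%
share granularity, bracket midpoint reported). All stochastic paths take
explicit seeds (the session config's seed is mandatory) and are exactly
reproducible.
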