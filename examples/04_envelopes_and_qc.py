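"""RMS envelopes, cross-correlation QC, spectra, and channel/force pairing.

Computes the 250 ms RMS envelope (zero-phase and causal), the pairwise
channel cross-correlation matrix used to certify fine-wire selectivity, a
spectrum percentile summary, and the computational channel/force pairing
table with signs.
"""

import numpy as np

from iemgkit import features as ft
from iemgkit import preprocess as pp
from iemgkit import synthetic as syn
from iemgkit.records import SessionRecord

rec, truth = syn.synthesize_session(syn.default_config(seed=1))

# QC runs on notch-filtered channels: otherwise the shared powerline
# harmonics dominate the pairwise cross-correlation
bank = pp.design_notch_bank(rec.fs)
data = rec.data.copy()
for lab in rec.emg_labels:
    col = rec.channels.index(lab)
    spec = pp.select_active_notches(bank, data[:, col])
    data[:, col] = pp.apply_zero_phase(spec, data[:, col])
rec = SessionRecord(data, rec.channels, rec.movements, rec.fs)

x = rec.column("FDP")
env = ft.rms_envelope(x, rec.fs)  # 250 ms window, centered
causal = ft.rms_envelope(x, rec.fs, causal=True)
print(f"envelope: {env.values.size} samples, causal delay "
      f"{causal.shift_samples} samples "
      f"({1000 * causal.shift_samples / rec.fs:.0f} ms)")

xc = ft.channel_crosscorr(rec)
off = xc.median[~np.eye(len(xc.labels), dtype=bool)]
print(f"cross-correlation (median over movement segments): "
      f"off-diagonal median {np.median(off):.3f}, max {off.max():.3f}")
# low values certify that the simulated channels are selective, as the
# fine-wire electrodes are in the real recordings

summ = ft.spectrum_summary([rec.column(c) for c in rec.emg_labels], rec.fs)
peak = summ.freqs[np.argmax(summ.percentiles[50])]
print(f"spectrum summary: median band peaks at {peak:.0f} Hz")

for e in ft.pair_channels_with_forces(rec):
    status = "paired" if e.paired else "unpaired"
    print(f"  {e.emg_channel}: {status} -> {e.force_channel} "
          f"(movement {e.movement_code:g}, sign {e.sign:+d}, |r|={e.score:.2f})")
# sign -1 means the force goes negative (flexion) during iEMG activity,
# matching the bidirectional-transducer convention
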