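"""Powerline notch filtering, sync-pulse alignment, force up-sampling.

Filters one iEMG channel with the per-recording active subset of the
50 Hz-harmonic notch bank, detects the 5 V / 200 ms / 0.5 Hz sync pulses on
both device streams, verifies the pulse counts, and up-samples the 200 Hz
force stream onto the 10240 Hz iEMG grid.
"""

import numpy as np

from iemgkit import preprocess as pp
from iemgkit import synthetic as syn

rec, truth = syn.synthesize_session(syn.default_config(seed=1))

bank = pp.design_notch_bank(rec.fs)  # 100 centers: 50, 100, ... 5000 Hz
x = rec.column("FDP")
active = pp.select_active_notches(bank, x)
xf = pp.apply_zero_phase(active, x)
print(f"notch bank: {len(bank.centers)} centers designed, "
      f"{len(active.centers)} active on FDP: {sorted(active.centers)}")
print(f"FDP RMS before/after filtering: {np.std(x):.4f} / {np.std(xf):.4f} mV")

ev_emg = pp.detect_sync_pulses(truth.sync_emg, truth.fs_emg)
ev_force = pp.detect_sync_pulses(truth.sync_force, truth.fs_force)
res = pp.align_streams(ev_emg, ev_force)
print(f"sync pulses: {res.count_a} (amplifier) vs {res.count_b} (force card), "
      f"verified={res.verified}, offset={res.offset_s * 1000:.2f} ms")
# a positive offset would mean the force stream started recording later

force_v = truth.force_stream_v["little"]
up = pp.upsample_force(force_v, truth.fs_force, rec.fs)
print(f"force stream: {force_v.size} samples at 200 Hz -> {up.size} at 10240 Hz")
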