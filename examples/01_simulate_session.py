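"""Generate a synthetic recording session with ground truth.

Builds the default session (four muscles, two motor units each, a compact
cue protocol) and prints its shape, the movement codes it emits, and the
ground-truth spike counts.  The record has the same container layout as the
published database files.
"""

import numpy as np

from iemgkit import synthetic as syn

cfg = syn.default_config(seed=1)
rec, truth = syn.synthesize_session(cfg)

print(f"session: {rec.data.shape[0]} samples x {rec.data.shape[1]} channels "
      f"at {rec.fs:g} Hz ({rec.duration_s:.1f} s)")
print(f"iEMG channels: {rec.emg_labels}")
print(f"force channels (raw sensor volts): {rec.force_labels}")
codes = sorted(c for c in np.unique(rec.code_stream()) if c != 0)
print(f"movement codes emitted: {[f'{c:.2f}' for c in codes]}")
for u in truth.units:
    print(f"  true unit {u.channel}/{u.unit_index}: {u.spikes.size} spikes, "
          f"{np.max(np.abs(u.template)):.2f} mV peak")
# Each x.x0/x.x1 pair is one cue-driven sub-stage (rest vs cue); plain codes
# are tracking stages. Spike counts scale with each unit's recruitment.
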