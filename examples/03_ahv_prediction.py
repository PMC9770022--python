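"""Is a firing-rate change explained by angular-head-velocity sampling?

Builds the HD x AHV firing-probability map from the first half of a
baseline session, predicts the spiking of the second half from its own
(HD, AHV) occupancy, and scores the prediction.  Indices near 0 mean
the cell fired exactly as its baseline (HD, AHV) modulation predicts;
a thinned (suppressed) copy of the spike train scores negative.
"""

import numpy as np

import hddisorient as hdd

proto = hdd.ProtocolSpec.baseline(duration=480.0)
session = hdd.generate_session(hdd.CellSpec(preferred_direction=120.0), proto, seed=11)
hd = hdd.compute_hd_ahv(session.tracking)
spikes = session.spikes[0].t

first, second = spikes[spikes < 240.0], spikes[spikes >= 240.0]
map_a = hdd.build_ahv_map(first, hd.slice(0.0, 240.0))
map_b = hdd.build_ahv_map(second, hd.slice(240.0, 480.0))
pred = hdd.predict_spikes(map_a, map_b)
print(f"self-consistent half : spike rate index = "
      f"{hdd.spike_rate_index(map_b, pred):+.3f} (expected ~0)")

rng = np.random.default_rng(0)
thinned = np.sort(rng.choice(second, size=int(0.6 * len(second)), replace=False))
map_c = hdd.build_ahv_map(thinned, hd.slice(240.0, 480.0))
pred_c = hdd.predict_spikes(map_a, map_c)
print(f"40%-suppressed copy  : spike rate index = "
      f"{hdd.spike_rate_index(map_c, pred_c):+.3f} (negative: fewer spikes "
      "than AHV sampling predicts)")
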