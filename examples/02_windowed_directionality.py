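"""Directionality collapsing during dark rotation and recovering after.

A freely moving animal is rotated at 260 deg/s in darkness for 60 s and
then forages for 120 s.  Tuning is computed in coverage-extended 10-s
windows; the Rayleigh vector per window shows the directional signal
fading while the rotation disorients the cell and climbing back during
recovery.
"""

import hddisorient as hdd

proto = hdd.ProtocolSpec.unidirectional_free(
    speed=260.0, illumination="dark", durations=(60.0, 60.0, 120.0)
)
session = hdd.generate_session(hdd.CellSpec(preferred_direction=250.0), proto, seed=7)
hd = hdd.compute_hd_ahv(session.tracking)
spikes = session.spikes[0].t

print("rotation phase (60-120 s):")
for w in hdd.windowed_tuning(spikes, hd, (60.0, 120.0)):
    print(f"  {w.t_start:5.0f}-{w.t_end:5.0f} s  r = {w.stats.rayleigh_r:.2f}")
print("recovery phase (120-240 s):")
for w in hdd.windowed_tuning(spikes, hd, (120.0, 240.0))[:6]:
    print(f"  {w.t_start:5.0f}-{w.t_end:5.0f} s  r = {w.stats.rayleigh_r:.2f}")
print("Directionality falls through the dark rotation and recovers afterwards.")
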