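"""Pooling conditions with the combined GLM.

Builds a small synthetic cohort of sessions across rotation speeds,
illumination and restraint, measures each cell's directionality,
z-scores against the light baselines, and fits
z ~ speed + dark + restrained + unidirectional + speed x dark.
The standardized betas recover the structure built into the generator:
faster dark rotation disorients more (negative speed and interaction
effects on directionality).
"""

import numpy as np

import hddisorient as hdd

conditions = [
    dict(proto=hdd.ProtocolSpec.baseline(duration=240.0), n=6),
    dict(proto=hdd.ProtocolSpec.unidirectional_free(
        speed=111.0, illumination="light", durations=(30.0, 60.0, 0.0)), n=5),
    dict(proto=hdd.ProtocolSpec.unidirectional_free(
        speed=111.0, illumination="dark", durations=(30.0, 60.0, 0.0)), n=5),
    dict(proto=hdd.ProtocolSpec.unidirectional_free(
        speed=260.0, illumination="light", durations=(30.0, 60.0, 0.0)), n=5),
    dict(proto=hdd.ProtocolSpec.unidirectional_free(
        speed=260.0, illumination="dark", durations=(30.0, 60.0, 0.0)), n=5),
    dict(proto=hdd.ProtocolSpec.head_fixed(
        speed=186.0, illumination="light", durations=(10.0, 60.0, 0.0),
        underestimation=0.0), n=5),
    dict(proto=hdd.ProtocolSpec.head_fixed(
        speed=186.0, illumination="dark", durations=(10.0, 60.0, 0.0),
        underestimation=0.0), n=5),
]

rows = []
seed = 0
for cond in conditions:
    proto = cond["proto"]
    for _ in range(cond["n"]):
        seed += 1
        ses = hdd.generate_session(
            hdd.CellSpec(preferred_direction=float(37 * seed % 360)), proto, seed=seed
        )
        hd = hdd.compute_hd_ahv(ses.tracking)
        window = None
        if proto.protocol != "baseline":
            window = (proto.phase_times[0], proto.phase_times[1])
        tc = hdd.tuning_curve(ses.spikes[0].t, hd, window=window)
        rows.append({
            "r": hdd.directional_stats(tc).rayleigh_r,
            "speed": proto.nominal_speed,
            "dark": float(proto.illumination == "dark"),
            "restrained": float(proto.protocol == "head_fixed"),
            "uni": float(proto.protocol in ("unidirectional_free", "head_fixed")),
            "baseline": proto.protocol == "baseline",
        })

base = [r["r"] for r in rows if r["baseline"]]
z = [n.z for n in hdd.normalize([r["r"] for r in rows], base)]
res = hdd.fit_glm(
    [r["speed"] for r in rows], [r["dark"] for r in rows],
    [r["restrained"] for r in rows], [r["uni"] for r in rows], z,
)
print(f"F = {res.f_stat:.1f} (p = {res.f_p:.2g}), R^2 = {res.r_squared:.2f}")
for name, b, p in zip(res.beta.index, res.beta, res.beta_p):
    print(f"  beta[{name:13s}] = {b:+.2f}  (p = {p:.3g})")
print("The negative speed x dark interaction carries the effect in this "
      "cohort: faster rotation costs directionality mainly in darkness.")
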