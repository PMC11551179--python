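"""Stepped-velocity flow-phantom simulation (tube at 8 degrees).

Mirrors the phantom validation: a straight tube at a shallow angle, pump
speed stepped, each step measured end-to-end (simulate -> velocimetry ->
graph).  Prints set vs measured velocities and the regression slope.
"""

from vascuflow.experiments import phantom_velocity_study

out = phantom_velocity_study(seed=4)
for s, m in zip(out["set"], out["measured"]):
    print(f"set {s:5.1f} mm/s -> measured {m:5.2f} mm/s")
print(f"slope = {out['slope']:.3f}  (unity means a calibrated velocimeter)")
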