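"""Continuity-driven luminal flow under a slow peristaltic wave.

Derives the section-mean velocity from wall motion by mass conservation in
the closed, partially filled tube and prints the characteristic flow
pattern at an inter-segment probe: an antegrade episode while the upstream
segment contracts, then a retrograde burst when the downstream segment
contracts.
"""

import numpy as np

import colonmotion as cm

geometry = cm.DCMGeometry(fill_fraction=0.69, fill_volume=200)
program = cm.WallMotionProgram(wave_speed=0.4)
flow = cm.continuity_flow(geometry, program, damping_tau=0.1, dt=0.1, t_max=62.0)

V = flow.total_volume
print(f"fluid volume drift over the scan: {(V.max() - V.min()) / V.mean():.2e} "
      "(relative; the free surface takes up all displaced volume)")

x_probe = 150.0  # rigid boundary between segments 6 and 7
for k in (6, 7):
    t0 = program.segment_delay(geometry, k) + program.relax_duration
    ts = np.arange(t0, t0 + program.contract_duration, 0.1)
    u = np.mean([flow.section_mean(x_probe, t) for t in ts])
    where = "upstream" if k == 6 else "downstream"
    print(f"mean velocity at x = {x_probe:.0f} mm while segment {k} "
          f"({where}) contracts: {u:+.2f} cm/s")

print("positive = antegrade (toward the hepatic flexure); the sign flip is "
      "the to-and-fro signature of a non-occlusive peristaltic wave")
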