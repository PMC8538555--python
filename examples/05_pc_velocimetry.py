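"""Phase-contrast velocimetry and wall tracking on one transverse slice.

Renders a PC cine pair (velocity + magnitude) at the midpoint of segment 2
while the slow wave passes, segments the lumen from the magnitude images,
and prints mean/peak velocities alongside the tracked wall displacement.
"""

import numpy as np

import colonmotion as cm

geometry = cm.DCMGeometry(fill_fraction=0.69, fill_volume=200)
program = cm.WallMotionProgram(wave_speed=0.4)
flow = cm.continuity_flow(geometry, program, damping_tau=0.1, dt=0.1, t_max=40.0)

acq = cm.PCAcquisition(n_frames=14, slice_x_position=geometry.segment_centre(2),
                       seed=1)
seq = cm.render_pc_sequence(flow, geometry, acq)

trace = cm.velocity_trace(seq, use_central=False)
central = cm.velocity_trace(seq, use_central=True)
wall = cm.track_wall(seq)

print("t [s]   mean v [cm/s]   central v    peak+/peak-    wall disp [mm]")
for i, t in enumerate(seq.frame_times):
    print(f"{t:5.1f}   {trace.mean_v[i]:+8.3f}      {central.mean_v[i]:+8.3f} "
          f"  {trace.peak_pos_v[i]:+5.2f}/{trace.peak_neg_v[i]:+5.2f} "
          f"    {wall.displacement[i]:+6.2f}")

truth = [cm.wall_displacement(program, geometry, 2, t) for t in seq.frame_times]
print(f"\nprogrammed max contraction {max(truth):.2f} mm; "
      f"tracked {np.nanmax(wall.displacement):.2f} mm")
print("the retrograde burst coincides with the local contraction; the "
      "central flow region amplifies the centre-weighted flow profile")
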