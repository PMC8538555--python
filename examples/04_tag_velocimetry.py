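"""Tag-displacement velocimetry: recovering a known plug flow.

Renders a noiseless tagged sequence of a 1.2 cm/s plug flow, detects each
tag band's sub-voxel centreline and converts centroid displacement over
the 250 ms tag delay into velocity (u = dx/dt).
"""

import numpy as np

import colonmotion as cm

geometry = cm.DCMGeometry()
flow = cm.prescribed_flow("plug", geometry, u0=1.2)
acq = cm.TagAcquisition(noise_sigma=0.0, n_frames=2)
seq = cm.render_tagged_sequence(flow, geometry, acq)
roi = cm.neutral_lumen_roi(geometry, seq.x_coords, seq.z_coords)
tracks = cm.track_tags(seq, roi)

v = np.concatenate([t.v_avg_cms[t.valid] for t in tracks])
print(f"{len(seq.nominal_tag_positions)} tags at {acq.tag_spacing} mm pitch; "
      f"{v.size} valid tag-frames")
print(f"recovered velocity: {v.mean():.3f} cm/s (true 1.200)")
print(f"stated resolution: +/- {acq.velocity_uncertainty:.2f} cm/s "
      "(half a voxel over the 250 ms delay)")

# a seeded noisy 100-frame calibration of the same recovery
rep = cm.plug_recovery(u0=1.0, seed=1, n_frames=100, noise_sigma=0.03)
print(f"noisy calibration (n = {rep['n']} tag-frames): "
      f"bias {rep['bias_cms']:+.4f} cm/s, RMSE {rep['rmse_cms']:.4f} cm/s")
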