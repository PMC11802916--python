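"""Leading-edge extension dynamics and 3D shape metrics.

A cell mask growing a single 60-degree protrusion at 1 µm/frame: per-pixel
edge-extension speeds, the largest contiguous extension and its direction
relative to cell motion, plus volume/sphericity of a voxelized ellipsoid.
"""

import math

import numpy as np

import hemoflow as hf
from hemoflow import synthetic as syn

masks, gt = syn.make_mask_sequence(
    base_radius=8.0, protrusions=[(0.0, 60.0, 1.0)], n_frames=5,
    pixel_size=0.2, frame_interval=10.0,
)
c = gt.params["center_x_um"]
nucleus = hf.Track(t=10.0 * np.arange(5), x=np.full(5, c), y=np.full(5, c))

dyn = hf.edge_dynamics(masks, nucleus)
ef = dyn.frames[1]
ex, ey = ef.extension_vector
angle = math.degrees(math.atan2(-ey, ex))
print(f"largest-extension speed  : {ef.largest_extension_speed:.3f} µm/s "
      f"(programmed {gt.params['growth_um_per_s']:.3f})")
print(f"all-extension mean speed : {ef.all_extension_speed:.3f} µm/s")
print(f"extension direction      : {angle:+.1f}° "
      f"(sector bisector {gt.params['largest_sector_bisector_deg']:+.1f}°)")

mask3d, gt3 = syn.make_ellipsoid_mask((8.0, 4.0, 2.0), voxel_size=0.25)
m = hf.shape_metrics(mask3d, 0.25)
print(f"ellipsoid volume         : {m['volume_um3']:.1f} µm³ "
      f"(closed form {gt3.params['volume_um3']:.1f})")
print(f"ellipsoid sphericity     : {m['sphericity']:.3f} "
      f"(analytic {gt3.params['sphericity']:.3f})")
print("-> edge speeds recover the programmed protrusion; sphericity < 1 "
      "quantifies departure from a sphere.")
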