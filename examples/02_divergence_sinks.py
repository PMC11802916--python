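"""Map network compression (sinks) in a flow field.

A sink ring around the cell body — where retrograde lamellar flow meets the
cortex — shows up as negative divergence concentrated in the cortical
region.
"""

import numpy as np

import hemoflow as hf
from hemoflow.fieldstats import negative_divergence_summary

# radial inflow converging on a ring at the body edge (r0 = 8 µm)
n, spacing = 41, 1.0
x = np.arange(n) * spacing
xx, yy = np.meshgrid(x, x)
c = x.mean()
r = np.hypot(xx - c, yy - c)
r0, w, a = 8.0, 2.0, 0.5
vr = a * (r0 - r) * np.exp(-(((r - r0) / w) ** 2))
with np.errstate(invalid="ignore"):
    u = np.where(r > 0, vr * (xx - c) / r, 0.0)
    v = np.where(r > 0, vr * (yy - c) / r, 0.0)
field = hf.FlowField(x=x, y=x, u=u[None], v=v[None],
                     valid=np.ones((1, n, n), bool), grid_spacing=spacing,
                     frame_interval=5.0)

div = hf.divergence(field)
body, cell = r <= r0, r <= 20.0
ring = hf.cortical_ring(body, width=5.0, pixel_size=1.0)
lamella = hf.lamellar_region(cell, body, ring)

m_ring = negative_divergence_summary(div, hf.nodes_in_mask(div, ring, 1.0))
m_lam = negative_divergence_summary(div, hf.nodes_in_mask(div, lamella, 1.0))
print(f"mean negative divergence, cortical ring : {m_ring:+.4f} 1/min")
print(f"mean negative divergence, lamella       : {m_lam:+.4f} 1/min")
print("-> the sink ring makes the cortical region markedly more negative "
      "(compressed) than the lamella, the signature of actin accumulating "
      "around the cell body.")
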