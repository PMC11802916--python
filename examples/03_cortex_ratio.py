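"""Ratiometric cortex mapping of membrane-proximal actin.

A synthetic two-channel cell with a 2x cortical ring at the body edge:
the per-pixel ratio image, its whole-cell mean, the lamellar distribution
anchored at the body/lamella transition, and the cortical-enrichment
statistic.
"""

import numpy as np

import hemoflow as hf
from hemoflow import synthetic as syn

movie, cell, body, gt = syn.make_two_channel_cell(
    body_radius=5.0, lamella_extent=12.0, ring_width=2.0, ring_amplitude=2.0,
    pixel_size=0.1, seed=2,
)
ratio = hf.ratio_image(movie, numerator="mpact", denominator="caax")

mean = hf.mpact_mean(ratio, cell.masks[0])
print(f"whole-cell mean ratio        : {mean:.3f}")

profile = hf.mpact_lamellar_distribution(ratio, cell.masks[0], body.masks[0],
                                         pixel_size=0.1, spacing_px=40)
peak_px = profile.distance[np.argmax(profile.mean)]
print(f"profile peak at              : {peak_px:+.1f} px from the body edge "
      f"(ratio {profile.mean.max():.3f})")

ce = hf.cortical_enrichment(ratio, body.masks[0], cell.masks[0],
                            pixel_size=0.1)
print(f"cortical enrichment          : {ce:.3f} (ground truth "
      f"{gt.params['ratio_at_body_edge'] / gt.params['ratio_at_center']:.1f})")
print("-> the ratio peaks at the cell-body edge and the enrichment statistic "
      "recovers the programmed 2x edge/center contrast.")
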