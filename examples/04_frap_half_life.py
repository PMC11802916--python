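"""FRAP recovery half-life under acquisition photobleaching.

Generates the three ROI traces of a bleach experiment (5 pre-bleach frames,
45 post-bleach frames every 0.5 s) with acquisition bleaching, applies the
control-ROI correction and bleach-depth normalization, and fits the
one-phase recovery over 0-14 s.
"""

import numpy as np

import hemoflow as hf
from hemoflow import synthetic as syn

k_true = 0.35  # 1/s
series, gt = syn.make_frap_series(
    A=0.6, k=k_true, acq_bleach_rate=0.02, baseline=0.0, noise_sd=0.01, seed=4,
)
result = hf.process_series(series, window=(0.0, 14.0))
fit = result["fit"]

print(f"trace length             : {series.time_s.size} frames "
      f"({series.n_pre} pre-bleach)")
print(f"fitted plateau           : {fit.plateau:.3f} (normalized)")
print(f"fitted rate k            : {fit.k:.4f} 1/s")
print(f"recovery half-life       : {fit.half_life:.3f} s "
      f"(ground truth {gt.params['half_life_s']:.3f} s)")
print(f"fit residual RMS         : {fit.residual_rms:.4f} over "
      f"{fit.n_points} points")
print("-> the control-ROI correction removes the acquisition decay, so the "
      "fitted half-life matches ln(2)/k despite photobleaching and noise.")
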