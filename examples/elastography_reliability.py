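"""Shear-wave elastography: speed maps -> modulus, and clip reliability.

Renders 5-frame shear-wave-speed clips for 15 resting muscles (control
stiffness 9.3 +/- 2.0 kPa), converts each ROI pixel to shear modulus
(mu = rho * Vs^2), and quantifies intra-clip reliability with the two-way
consistency ICC and the standard error of measurement.
"""

import numpy as np

from myofatigue import (GeneratorConfig, clip_modulus, icc_sem,
                        render_swe_clip, roi_frame_modulus)

rng = np.random.default_rng(3)
config = GeneratorConfig()

mus = np.maximum(rng.normal(9.3, 2.0, 15), 1.0)
clips = [render_swe_clip(mu, config, rng) for mu in mus]

frame_matrix = np.array([roi_frame_modulus(c) for c in clips])  # 15 x 5
clip_means = [clip_modulus(c).clip_mu for c in clips]
print(f"cohort mean clip modulus: {np.mean(clip_means):.2f} kPa "
      f"(true mean {mus.mean():.2f} kPa)")

rel = icc_sem(frame_matrix)
print(f"intra-clip ICC = {rel.icc * 100:.1f}%  SEM = {rel.sem:.2f} kPa")
# The ICC compares between-subject stiffness spread to the within-clip
# frame-to-frame noise; values above ~97% match reported scanner behavior.
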