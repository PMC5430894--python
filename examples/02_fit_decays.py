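"""Fit per-pixel biexponential decays on a red-blood-cell patch.

Simulates a homogeneous RBC smear (fast ~100 ps hemoglobin decay with a
~500 ps minor component), fits every bright pixel, and prints the
recovered lifetime distribution — the numbers should reproduce the
generating truth within sampling error.
"""

import numpy as np

from dermaflim import phantom as ph
from dermaflim.decayfit import FitConfig, fit_image

truth = ph.default_truths()["capillary_rbc"]
cube = ph.uniform_patch(truth, (20, 20), counts_per_pixel=1500.0, seed=7)
fitmaps = fit_image(cube, FitConfig(threshold_counts=200.0))

v = fitmaps.valid
print(f"fitted {v.sum()}/{v.size} pixels (max-bin threshold 200 counts)")
print(f"tau1 = {np.nanmean(fitmaps.tau1[v]):5.1f} ± {np.nanstd(fitmaps.tau1[v]):4.1f} ps "
      f"(truth {truth.tau1_mean} ± {truth.tau1_sd})")
print(f"tau2 = {np.nanmean(fitmaps.tau2[v]):5.0f} ps (truth {truth.tau2_mean})")
print(f"a1   = {np.nanmean(fitmaps.a1_pct[v]):4.1f} % — the fast component dominates")
print(f"tau_m = {np.nanmean(fitmaps.tau_m[v]):5.0f} ps (amplitude-weighted mean lifetime)")
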