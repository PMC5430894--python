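"""Simulate a synthetic dermal-papilla FLIM dataset and describe it.

Builds the default forearm-papilla phantom: a TCSPC photon-count cube
(y, x, time-bin) plus co-registered SHG and TPEAF intensity channels,
with known per-region decay parameters.
"""

import numpy as np

from dermaflim import phantom as ph

cfg = ph.PhantomConfig(rng_seed=0)
cube, channels, truth_maps, labels = ph.simulate_dataset(cfg)

print(f"cube: {cube.counts.shape} counts, bin width {cube.bin_width:.2f} ps "
      f"({cube.n_bins * cube.bin_width / 1e3:.1f} ns window)")
print(f"total photons: {cube.counts.sum():,}")
print("region areas (pixels):")
for code, name in ph.LABEL_NAMES.items():
    sel = labels == code
    print(f"  {name:12s} {sel.sum():6d}   "
          f"truth tau1 ~ {np.nanmean(truth_maps.tau1[sel]):6.0f} ps, "
          f"a1/a2 ~ {np.nanmean(truth_maps.amp_ratio[sel]):4.1f}")
print("SHG is bright only on the collagen ring; the inner area is SHG-void:")
inner = labels == ph.LABEL_CODES["inner_ecm"]
outer = labels == ph.LABEL_CODES["collagen_I"]
print(f"  mean SHG outer {channels.shg[outer].mean():7.1f} vs inner {channels.shg[inner].mean():5.1f}")
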