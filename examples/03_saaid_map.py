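"""Compute the SAAID collagen/elastin index map of a papilla phantom.

SAAID = (SHG − TPEAF)/(SHG + TPEAF) after per-channel normalization:
positive where fibrillar collagen I dominates, negative on elastin-rich
pixels.
"""

import numpy as np

from dermaflim import phantom as ph
from dermaflim.maps import compute_saaid, normalize_channels

cfg = ph.PhantomConfig(rng_seed=0)
_, channels, _, labels = ph.simulate_dataset(cfg)

saaid = compute_saaid(normalize_channels(channels, "percentile99"))

for name in ("collagen_I", "elastin", "inner_ecm"):
    sel = (labels == ph.LABEL_CODES[name]) & saaid.defined
    print(f"{name:12s} SAAID = {np.nanmean(saaid.saaid[sel]):+.2f} "
          f"± {np.nanstd(saaid.saaid[sel]):.2f}")
print("collagen pixels sit above the +0.15 collagen threshold; elastin fibers")
print("fall in the negative band — the index separates the two ECM components.")
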