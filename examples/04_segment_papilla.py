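"""Segment a papilla phantom into its anatomical regions.

Papilla footprint from SHG/TPEAF, inner area by SHG absence, brightest-15%
TPEAF intensity mask (elastin proxy), capillary cross-sections by fast
decay (tau1 < 200 ps, a1 > 80 %), and the melanin rim outside the papilla.
"""

import numpy as np

import dermaflim as dm
from dermaflim import phantom as ph
from dermaflim.segment import SEG_LABELS

cfg = ph.PhantomConfig(image_size=96, papilla_radius=36.0, inner_radius=15.0,
                       capillary_spot_radius=4.0, rng_seed=3)
cube, channels, _, truth = ph.simulate_dataset(cfg)
fitmaps = dm.fit_image(cube)
saaid = dm.compute_saaid(dm.normalize_channels(channels))
labelmap = dm.segment_image(channels, fitmaps, saaid)

print("segmented region sizes (pixels):")
for name, code in SEG_LABELS.items():
    print(f"  {name:15s} {(labelmap.labels == code).sum():6d}")
print(f"capillary components found: {len(labelmap.capillary_report)} "
      f"(the two limbs of the U-shaped loop)")
for comp in labelmap.capillary_report:
    print(f"  component {comp['component']}: centroid {comp['centroid']}, area {comp['area']} px")

cap = labelmap.labels == SEG_LABELS["capillary"]
cap_truth = truth == ph.LABEL_CODES["capillary"]
jacc = (cap & cap_truth).sum() / (cap | cap_truth).sum()
print(f"capillary mask vs ground truth: Jaccard = {jacc:.2f}")
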