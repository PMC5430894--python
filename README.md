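# dermaflim

Multiphoton FLIM analysis of human papillary dermis: per-pixel
biexponential fluorescence-decay fitting, SAAID collagen/elastin mapping,
SHG- and decay-guided segmentation of dermal papillae, and region-wise
lifetime statistics — with a synthetic phantom generator so the whole
pipeline can be validated end to end without in vivo data.

## The problem

Two-photon tomography of skin records, in each pixel, a TCSPC histogram of
photon arrival times (here: 256 bins over the 12.5 ns period of an 80 MHz
laser) together with second-harmonic-generation (SHG) and two-photon
autofluorescence (TPEAF) intensity channels. In papillary dermis the decay
in each pixel is well described by a two-component exponential

    f(t) = a1·exp(−t/τ1) + a2·exp(−t/τ2),   τ1 < τ2,

convolved with the instrument response. The fitted parameters separate the
tissue's components: collagen I and elastin fibers differ in (τ1, τ2,
a1/a2), capillary blood shows a very fast hemoglobin decay (τ1 ≲ 150 ps at
a1 ≳ 80 %), and melanin-containing cells at the papilla rim share that fast
signature but sit outside the papilla. The amplitude-weighted mean lifetime

    τm = (a1·τ1 + a2·τ2) / (a1 + a2)

summarizes each pixel, and the SAAID index

    SAAID = (SHG − TPEAF) / (SHG + TPEAF)

maps the local collagen-to-elastin balance.

The package is for researchers analysing multiphoton FLIM of skin (or
building such analyses) who need a tested, scriptable implementation of
this pipeline plus a ground-truth phantom for validating fitters and
segmenters.

## What's inside

| module | contents |
| --- | --- |
| `dermaflim.phantom` | papilla geometry, per-region decay truths, SHG/TPEAF rendering, Poisson TCSPC simulation |
| `dermaflim.decayfit` | IRF-convolved biexponential fitting (Poisson MLE + weighted LS), τm |
| `dermaflim.maps` | channel normalization and SAAID maps |
| `dermaflim.segment` | papilla mask, inner/outer split, brightest-15 % intensity mask, SAAID bands, capillary and melanin-rim detection |
| `dermaflim.stats` | per-region histograms and mean ± SD summary tables |
| `dermaflim.io` / `dermaflim.cli` | dataset container I/O, YAML run configs, `dermaflim` command-line pipeline |

## Worked example

Fit a simulated red-blood-cell smear (fast hemoglobin decay, 1500 photons
per pixel) and recover its lifetime signature:

```python
import numpy as np
from dermaflim import phantom as ph
from dermaflim.decayfit import FitConfig, fit_image

truth = ph.default_truths()["capillary_rbc"]      # tau1 = 100 ± 20 ps
cube = ph.uniform_patch(truth, (20, 20), counts_per_pixel=1500.0, seed=7)
fm = fit_image(cube, FitConfig(threshold_counts=200.0))
v = fm.valid
print(np.nanmean(fm.tau1[v]), np.nanmean(fm.tau2[v]), np.nanmean(fm.a1_pct[v]))
```

prints (see `examples/02_fit_decays.py`):

```
fitted 385/400 pixels (max-bin threshold 200 counts)
tau1 =  99.7 ± 21.0 ps (truth 100 ± 20)
tau2 =   499 ps (truth 500)
a1   = 89.7 % — the fast component dominates
```

i.e. the fitter recovers the fast hemoglobin lifetime and the ~500 ps
minor component from Poisson-noisy 1500-count histograms. The full
pipeline on the default 128×128 papilla phantom
(`examples/05_region_report.py`) produces the region report

```
                n_pixels  tau1_mean  tau2_mean  amp_ratio_mean  tau_m_mean  tau_m_sd
outer               5071      303.3     2497.4             1.8      1094.0     109.7
inner               1098      248.7     2288.1             3.0       761.3     112.7
intensity_mask       892      403.4     2294.9             1.2      1269.5     130.0
capillary            137      151.3     1693.8             9.2       304.6      32.0
melanin_rim          921      118.5      808.2             9.1       188.1      33.4
```

where the intensity-mask row reproduces the elastin signature (τm ≈
1300 ps), the outer ring the collagen-dominated mixture, the inner area
the loose-ECM signature (τm ≈ 800 ps, a1/a2 ≈ 3), and exactly two
capillary components are found inside the inner area.

The same pipeline runs from the shell:

```bash
dermaflim simulate --seed 0 --out ds/
dermaflim fit --input ds/ --threshold 200 --estimator poisson_mle --out fitmaps/
dermaflim saaid --input ds/ --out saaid.tif
dermaflim segment --input ds/ --fitmaps fitmaps/ --out labels.tif
dermaflim report --fitmaps fitmaps/ --labels labels.tif --out report/
# or everything at once:
dermaflim run-all --seed 0 --out run/
```

`examples/` holds one short narrative script per capability.

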