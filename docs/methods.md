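# Methods

## Decay model and fitting

Each pixel's TCSPC histogram is modelled as a two-component exponential

    f(t) = a1·exp(−t/τ1) + a2·exp(−t/τ2),   τ1 ≤ τ2,

sampled at bin centers and convolved (discretely, causally) with the
normalized instrument response function on the same time axis. A fixed
time shift of the IRF is supported but defaults to 0 and is never fitted.
Pixels whose maximum bin holds fewer counts than `threshold_counts`
(default 200) are excluded before fitting; the threshold is deliberately
per-image configurable, since the appropriate value depends on sample
brightness (e.g. 500 for dim plasma drops), and no auto-selection
heuristic is attempted.

Two estimators are implemented:

* **Poisson MLE** (default): bounded L-BFGS-B minimization of the Poisson
  negative log-likelihood Σ(m − y·ln m) over (τ1, τ2, a1, a2), with the
  analytic gradient propagated through the IRF convolution. Photon counts
  are Poisson, so this is the statistically appropriate objective at the
  low-count budgets typical of in vivo FLIM.
* **Weighted least squares**: variable projection — the two lifetimes are
  optimized by trust-region least squares on (ln τ1, ln τ2) while the
  non-negative amplitudes are solved exactly by NNLS at every step. It
  serves as an independent cross-check of the MLE in the test suite.

Initialization is deterministic and seed-free: a two-segment log-linear
fit of the lightly smoothed histogram (tail slope → τ2, early residual
slope → τ1) is pooled with a coarse logarithmic (τ1, τ2) grid, and the
candidate with the lowest weighted-LS cost (NNLS amplitudes) starts the
optimizer. The grid step makes the fit robust for decays whose tail
leaves the log-linear window (e.g. τ2 ≈ 500 ps hemoglobin).

Lifetimes are bounded to [20, 10000] ps and amplitudes to [0, ∞).
Components are sorted after fitting so τ1 ≤ τ2; an exact tie assigns all
amplitude to component 1. Per-pixel non-convergence sets a diagnostic
status and the validity mask — it never raises. Fit quality is a reduced
χ² with Poisson variance approximated by max(model, 1). Incomplete-decay
wrap-around from the 80 MHz repetition is ignored: the slowest modelled
components (≈2.5 ns) decay to e⁻⁵ within the 12.5 ns window.

The mean lifetime is the amplitude-weighted average
τm = (a1τ1 + a2τ2)/(a1 + a2), undefined (NaN) where a1 + a2 = 0.

## SAAID

SAAID = (SHG − TPEAF)/(SHG + TPEAF) is computed per pixel after channel
normalization (99th percentile by default, configurable to max or none).
Fixed numeric SAAID thresholds (collagen > 0.15; elastin band
[−0.40, −0.35]) are only meaningful if both channels are on comparable
scales; whether the original analysis used raw detector counts or
rescaled intensities is not stated, so normalization is explicit and
configurable. Pixels with SHG + TPEAF = 0 are flagged undefined, never
zero-filled.

## Segmentation

* **Papilla mask** — union of SHG-positive pixels (above 5 % of the image
  SHG maximum) and bright TPEAF pixels (above 60 % of the 99th
  percentile), small objects removed, morphologically closed (disk radius
  3), hole-filled, largest connected component kept. The in vivo analysis
  outlined papillae manually; this reproduces that outline algorithmically
  on phantom-like data.
* **Inner area** — largest connected SHG-absent component interior to the
  papilla (at most 10 % of its pixels on the papilla's boundary ring);
  "SHG absent" means below 5 % of the image SHG maximum, since no numeric
  criterion accompanies the qualitative description. Outer = papilla −
  inner.
* **Intensity mask** — the ⌈0.15·|outer|⌉ brightest TPEAF pixels of the
  outer area (a deliberately arbitrary cutoff retained as the default;
  ties at the cutoff are all included and the excess logged). It serves
  as an elastin-fiber proxy.
* **Capillary** — valid-fit pixels with τ1 < 200 ps and a1 > 80 % inside
  the inner area; connected components under `min_region_pixels`
  (default 10) are dropped as noise.
* **Melanin rim** — the same fast-decay criterion restricted to a thin
  band (default 4 px) just outside the papilla boundary. Melanin and
  blood overlap in decay signature, so the two labels are disambiguated
  purely by geometry (exterior band vs. interior).

Label precedence makes the six output labels pairwise disjoint: the
intensity mask is carved out of the outer area and the capillary out of
the inner area.

## Region statistics

Per region, the package reports n_pixels and mean ± SD of τ1, τ2, a1/a2,
a1 % and τm over valid pixels, plus normalized histograms (unit sum) with
bin edges shared across regions (default 50 bins, 0–3000 ps for
lifetimes). The ± values are SDs of the pixel distributions — consistent
with the widths of published per-region lifetime distributions — not
standard errors of the mean. Mean τm is the pixel-wise formula averaged
over the region, never the formula applied to region-mean parameters.

## The phantom

The generator emulates one transverse papilla cross-section:

* geometry: collagen I outer ring (papilla radius 48 px at 0.5 µm/px)
  crossed by elastin-like fiber chords (drawn until ≈16 % coverage of the
  outer ring), an SHG-void inner disk (radius 20 px) containing two
  capillary disks (the limbs of the U-shaped loop), a 3 px melanin rim,
  and background;
* decay truths: per-pixel (τ1, τ2, a1/a2) drawn from truncated normals
  around the region means/SDs — truncation at zero and at τ1 < τ2
  enforces physical ordering that plain normals around the printed
  mean ± SD would occasionally violate. Defaults: collagen I 300 ± 50 /
  2500 ± 200 ps, a1/a2 1.8 ± 0.2; elastin 400 ± 70 / 2300 ± 200, 1.2 ±
  0.2; inner ECM 250 ± 70 / 2300 ± 300, 3.0 ± 0.4; RBC 100 ± 20 /
  500 ± 50, a1/a2 9 ± 1; plasma 170 ± 20 (200 selectable via
  `plasma_variant`, since both values are reported) / 1500 ± 250 ps at
  ~10 % slow amplitude (the reported "~500 ns" distribution width is
  treated as a ps-scale typo); melanin 120 ± 30 / 800 ± 200, 9 ± 1.
* capillary truth: the default (`capillary_mode="empirical"`) uses the
  in vivo capillary signature directly — 150 ± 20 ps fast at ~90 %
  amplitude with a 1700 ± 200 ps slow component. An explicit RBC/plasma
  amplitude mixture (`capillary_mode="mixture"`, default weight 0.85 on
  RBC) is also provided; note that a biexponential fit of that mixture
  yields τ1 ≈ 110 ps (the amplitude-weighted blend of 100 and 170 ps),
  noticeably faster than the measured in vivo capillary value, which is
  why the empirical mode is the default.
* channels: region brightness levels times multiplicative lognormal
  speckle (σ = 0.15). Elastin pixels keep a partial collagen SHG
  background (level 0.45) so their SAAID falls in the moderately negative
  elastin band rather than at −1, as real fiber-scale mixing produces.
* timing: 256 bins over the 12.5 ns period of 80 MHz excitation
  (Δt ≈ 48.8 ps); Gaussian IRF, FWHM 150 ps (the instrument's IRF is not
  characterized publicly; configurable), peak at 300 ps.
* photon budgets (expected total counts per pixel): collagen/elastin
  8000, inner 6000, melanin 3000, capillary 2500, background 300. At
  256-bin resolution the histogram peak of a slow-ECM biexponential holds
  only ≈ Δt/(a1τ1 + a2τ2) ≈ 4–6 % of the total counts, so budgets are
  set high enough that tissue regions clear the 200-count peak threshold
  while the background stays below it.
* noise: independent per-bin Poisson sampling of the IRF-convolved,
  budget-scaled expected decay. Everything is deterministic given the
  configuration seed.

What the phantom does **not** emulate: optical blur (PSF), depth
attenuation and scattering, scanning-motion blur of flowing erythrocytes,
detector afterpulsing or dead-time, dark counts, and 3-D structure.
Passing the recovery tests therefore demonstrates correctness of the
fitting/segmentation/statistics chain under ideal-optics Poisson
statistics, not robustness to all instrumental artifacts of in vivo data.

## Problem sizes and numerical choices

The default phantom is 128×128 (≈ 8 000 fitted pixels, ~2–3 ms per pixel);
tests use 96×96 and 48×48 variants and 20×20 patches (400 pixels) for
single-substance experiments — large enough that region means are
estimated to a few ps. Patch budgets in the reproduction script: RBC 1500
counts/pixel with the 200-count threshold, plasma 8000 with the 500-count
threshold (its peak fraction is ≈ 8 %, so 8000 places typical peaks
comfortably above 500), capillary 2500 with the 200-count threshold.

Degenerate inputs: an all-zero histogram or one below threshold is
flagged invalid; an all-zero IRF is rejected; an all-zero channel cannot
be normalized; an empty papilla mask raises; an empty region yields an
empty histogram with a warning, never an exception.

## Known limitations

* The commercial fitter used for the original in vivo analysis is a black
  box; estimator differences are absorbed by testing two independent
  estimators against each other and against the forward model.
* Capillary detection assumes the fast-decay pixels form components of at
  least `min_region_pixels`; very low budgets fragment the spots.
* The SAAID elastin band is narrow ([−0.40, −0.35]); with realistic
  speckle only a minority of elastin pixels fall inside it, so the
  intensity mask — not the SAAID band — is the robust elastin proxy, and
  the band masks are reported but not used for the region table.
* No vendor TCSPC file import; datasets use the package's own NPZ/TIFF
  container.
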