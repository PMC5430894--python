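import numpy as np
import pytest
from skimage import measure

import dermaflim as dm
from dermaflim import phantom as ph
from dermaflim.decayfit import FitMaps, mean_lifetime
from dermaflim.maps import SAAIDMap
from dermaflim.segment import (
    SEG_LABELS,
    SegmentConfig,
    detect_capillary,
    detect_melanin_rim,
    inner_outer_partition,
    intensity_mask,
    papilla_mask,
    saaid_regions,
    segment_image,
)


def jaccard(a, b):
    return (a & b).sum() / max((a | b).sum(), 1)


def synthetic_fitmaps(tau1, a1_pct, valid=None):
    """Hand-built FitMaps with the fields the classifiers consume."""
    tau1 = np.asarray(tau1, float)
    a1_pct = np.asarray(a1_pct, float)
    a1 = a1_pct / 100.0
    a2 = 1.0 - a1
    tau2 = np.full_like(tau1, 2000.0)
    if valid is None:
        valid = np.isfinite(tau1)
    return FitMaps(
        tau1=tau1, tau2=tau2, a1=a1, a2=a2, a1_pct=a1_pct,
        amp_ratio=np.where(a2 > 0, a1 / np.where(a2 > 0, a2, 1), np.nan),
        tau_m=mean_lifetime(a1, tau1, a2, tau2),
        chi2=np.ones_like(tau1), valid=valid,
    )


class TestPapillaMask:
    def test_recovers_truth_papilla(self, phantom_data, fitmaps):
        channels, truth_labels = phantom_data[1], phantom_data[3]
        mask = papilla_mask(channels, fitmaps)
        truth = np.isin(truth_labels, [1, 2, 3, 4])  # collagen+elastin+inner+capillary
        assert jaccard(mask, truth) >= 0.9

    def test_single_connected_component(self, phantom_data, fitmaps):
        mask = papilla_mask(phantom_data[1], fitmaps)
        assert measure.label(mask).max() == 1

    def test_blank_image_rejected(self):
        blank = ph.ChannelMaps(shg=np.zeros((32, 32)), tpeaf=np.zeros((32, 32)))
        with pytest.raises(ValueError):
            papilla_mask(blank)


class TestInnerOuter:
    def test_recovers_truth_inner_disk(self, phantom_data, fitmaps):
        channels, truth_labels = phantom_data[1], phantom_data[3]
        mask = papilla_mask(channels, fitmaps)
        inner, outer = inner_outer_partition(mask, channels.shg)
        truth_inner = np.isin(truth_labels, [3, 4])  # inner ECM + capillary disks
        assert jaccard(inner, truth_inner) >= 0.85

    def test_partitions_the_papilla(self, phantom_data, fitmaps):
        channels = phantom_data[1]
        mask = papilla_mask(channels, fitmaps)
        inner, outer = inner_outer_partition(mask, channels.shg)
        assert not (inner & outer).any()
        assert np.array_equal(inner | outer, mask)

    def test_shg_everywhere_gives_empty_inner(self):
        mask = np.ones((20, 20), bool)
        shg = np.full((20, 20), 100.0)
        with pytest.warns(UserWarning, match="inner area is empty"):
            inner, outer = inner_outer_partition(mask, shg)
        assert not inner.any() and outer.all()


class TestIntensityMask:
    def test_exact_count_on_distinct_intensities(self, rng):
        outer = np.zeros((10, 10), bool)
        outer.ravel()[:100] = True  # all pixels
        tpeaf = rng.permutation(100.0 + np.arange(100)).reshape(10, 10)
        mask = intensity_mask(tpeaf, outer, SegmentConfig(intensity_mask_fraction=0.15))
        assert mask.sum() == 15
        # Selected pixels are exactly the 15 brightest.
        assert tpeaf[mask].min() > tpeaf[outer & ~mask].max()

    def test_ties_at_cutoff_all_included(self):
        outer = np.ones((1, 10), bool)
        tpeaf = np.array([[5.0, 5.0, 5.0, 1, 1, 1, 1, 1, 1, 1]])
        mask = intensity_mask(tpeaf, outer, SegmentConfig(intensity_mask_fraction=0.2))
        assert mask.sum() == 3  # ceil(2) -> cutoff 5.0, all three ties kept

    def test_fraction_one_selects_whole_outer_area(self, rng):
        outer = rng.random((12, 12)) > 0.5
        tpeaf = rng.random((12, 12))
        mask = intensity_mask(tpeaf, outer, SegmentConfig(intensity_mask_fraction=1.0))
        assert np.array_equal(mask, outer)

    def test_mask_lifetimes_match_elastin_truth(self, labelmap, summary):
        # The brightest-TPEAF mask is an elastin proxy: its mean lifetime
        # must sit within one SD of the elastin truth-derived value
        # (a1/a2=1.2, tau1=400, tau2=2300 -> 1263.6 ps).
        row = summary.table.loc["intensity_mask"]
        expected = mean_lifetime(1.2, 400.0, 1.0, 2300.0)
        assert abs(row["tau_m_mean"] - expected) < row["tau_m_sd"]


class TestSAAIDRegions:
    def test_threshold_bands(self):
        saaid = np.array([[0.2, -0.37, -0.2, np.nan]])
        smap = SAAIDMap(saaid=saaid, defined=~np.isnan(saaid))
        papilla = np.ones((1, 4), bool)
        regions = saaid_regions(smap, papilla)
        assert regions["collagen_like"].tolist() == [[True, False, False, False]]
        assert regions["elastin_like"].tolist() == [[False, True, False, False]]

    def test_restricted_to_papilla(self):
        saaid = np.full((2, 2), 0.5)
        smap = SAAIDMap(saaid=saaid, defined=np.ones((2, 2), bool))
        papilla = np.array([[True, False], [False, False]])
        regions = saaid_regions(smap, papilla)
        assert regions["collagen_like"].sum() == 1


class TestCapillary:
    def test_two_components_in_phantom_inner_area(self, labelmap):
        assert len(labelmap.capillary_report) == 2

    def test_pixel_criterion(self):
        tau1 = np.array([[150.0, 300.0, 150.0]])
        a1p = np.array([[90.0, 90.0, 70.0]])
        fm = synthetic_fitmaps(tau1, a1p)
        inner = np.ones((1, 3), bool)
        cap, _ = detect_capillary(fm, inner, SegmentConfig(min_region_pixels=1))
        assert cap.tolist() == [[True, False, False]]

    def test_small_components_dropped(self):
        tau1 = np.full((10, 10), 500.0)
        tau1[0, 0] = 150.0  # single fast pixel
        fm = synthetic_fitmaps(tau1, np.full((10, 10), 90.0))
        cap, report = detect_capillary(fm, np.ones((10, 10), bool), SegmentConfig())
        assert not cap.any() and report == []

    def test_shrinking_tau1_threshold_never_grows_mask(self, fitmaps, labelmap):
        inner = np.isin(labelmap.labels, [SEG_LABELS["inner"], SEG_LABELS["capillary"]])
        wide, _ = detect_capillary(fitmaps, inner, SegmentConfig(capillary_tau1_max=200.0))
        narrow, _ = detect_capillary(fitmaps, inner, SegmentConfig(capillary_tau1_max=150.0))
        assert (narrow <= wide).all()

    def test_recovers_truth_spots(self, phantom_data, labelmap):
        truth_labels = phantom_data[3]
        cap = labelmap.labels == SEG_LABELS["capillary"]
        assert jaccard(cap, truth_labels == ph.LABEL_CODES["capillary"]) >= 0.7


class TestMelaninRim:
    def test_recovers_truth_rim(self, phantom_data, labelmap):
        truth_labels = phantom_data[3]
        rim = labelmap.labels == SEG_LABELS["melanin_rim"]
        assert jaccard(rim, truth_labels == ph.LABEL_CODES["melanin"]) >= 0.7

    def test_no_exterior_fast_pixels_gives_empty_rim(self):
        fm = synthetic_fitmaps(np.full((20, 20), 500.0), np.full((20, 20), 90.0))
        papilla = np.zeros((20, 20), bool)
        papilla[5:15, 5:15] = True
        assert not detect_melanin_rim(fm, papilla).any()

    def test_rim_and_capillary_disjoint(self, labelmap):
        rim = labelmap.labels == SEG_LABELS["melanin_rim"]
        cap = labelmap.labels == SEG_LABELS["capillary"]
        assert not (rim & cap).any()


class TestFullSegmentation:
    def test_labels_reproducible(self, phantom_data, fitmaps, saaid_map, labelmap):
        again = segment_image(phantom_data[1], fitmaps, saaid_map)
        assert np.array_equal(again.labels, labelmap.labels)

    def test_every_truth_region_recovered(self, phantom_data, labelmap):
        truth = phantom_data[3]
        seg = labelmap.labels
        pairs = [
            (np.isin(seg, [1, 2, 3, 4]), np.isin(truth, [1, 2, 3, 4])),  # papilla
            (np.isin(seg, [2, 4]), np.isin(truth, [3, 4])),  # inner disk
            (seg == SEG_LABELS["intensity_mask"], truth == ph.LABEL_CODES["elastin"]),
            (seg == SEG_LABELS["capillary"], truth == ph.LABEL_CODES["capillary"]),
            (seg == SEG_LABELS["melanin_rim"], truth == ph.LABEL_CODES["melanin"]),
        ]
        for got, want in pairs:
            assert jaccard(got, want) >= 0.7
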