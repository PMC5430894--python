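import dataclasses

import numpy as np
import pytest
from skimage import measure

from dermaflim import phantom as ph
from dermaflim.decayfit import model_decay


def small_cfg(**kw):
    base = dict(
        image_size=64, papilla_radius=24.0, inner_radius=10.0,
        capillary_spot_radius=3.0, rng_seed=7,
    )
    base.update(kw)
    return ph.PhantomConfig(**base)


class TestGeometry:
    def test_labels_partition_image(self):
        labels = ph.make_geometry(small_cfg())
        areas = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
        assert sum(areas.values()) == 64 * 64
        assert set(areas) == set(ph.LABEL_NAMES)

    def test_degenerate_inner_radius_gives_outer_ring_only(self):
        labels = ph.make_geometry(small_cfg(inner_radius=0.0))
        assert not np.isin(labels, [ph.LABEL_CODES["inner_ecm"], ph.LABEL_CODES["capillary"]]).any()
        assert (labels == ph.LABEL_CODES["collagen_I"]).any()

    def test_two_capillary_components_inside_inner(self):
        labels = ph.make_geometry(small_cfg())
        cap = labels == ph.LABEL_CODES["capillary"]
        assert measure.label(cap).max() == 2
        # Capillary disks sit where the inner disk would otherwise be.
        cfg = small_cfg()
        cy = cx = (cfg.image_size - 1) / 2
        yy, xx = np.mgrid[0:64, 0:64]
        inner_disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.inner_radius**2
        assert (cap <= inner_disk).all()

    def test_capillary_spot_outside_inner_rejected(self):
        cfg = small_cfg(capillary_centers=((31.5, 31.5), (31.5, 45.0)))
        with pytest.raises(ValueError, match="outside the inner area"):
            ph.make_geometry(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(inner_radius=30.0).validate()  # inner >= papilla
        with pytest.raises(ValueError):
            small_cfg(time_bins=2048).validate()  # exceeds 12.5 ns window


class TestSampleTruth:
    def test_sd_zero_gives_exact_region_means(self):
        labels = ph.make_geometry(small_cfg())
        truths = {
            name: dataclasses.replace(t, tau1_sd=0.0, tau2_sd=0.0, amp_ratio_sd=0.0)
            for name, t in ph.default_truths().items()
        }
        maps = ph.sample_truth(labels, truths, seed=0)
        for name, code in ph.LABEL_CODES.items():
            sel = labels == code
            assert np.allclose(maps.tau1[sel], truths[name].tau1_mean)
            assert np.allclose(maps.amp_ratio[sel], truths[name].amp_ratio_mean)

    def test_elastin_sample_mean_converges_to_400ps(self):
        # One large elastin-only field: the truncated-normal draw keeps the
        # region mean at its nominal 400 ps within sampling error.
        labels = np.full((100, 100), ph.LABEL_CODES["elastin"], dtype=np.int32)
        maps = ph.sample_truth(labels, ph.default_truths(), seed=11)
        se = 70.0 / 100.0
        assert abs(maps.tau1.mean() - 400.0) < 4 * se

    def test_fast_component_never_exceeds_slow(self):
        labels = ph.make_geometry(small_cfg())
        maps = ph.sample_truth(labels, ph.default_truths(), seed=2)
        assert (maps.tau1 < maps.tau2).all()
        assert (maps.tau1 > 0).all() and (maps.amp_ratio > 0).all()

    def test_same_seed_reproduces_maps(self):
        labels = ph.make_geometry(small_cfg())
        a = ph.sample_truth(labels, ph.default_truths(), seed=5)
        b = ph.sample_truth(labels, ph.default_truths(), seed=5)
        assert np.array_equal(a.tau1, b.tau1) and np.array_equal(a.amp_ratio, b.amp_ratio)

    def test_missing_region_truth_names_the_label(self):
        labels = ph.make_geometry(small_cfg())
        truths = {k: v for k, v in ph.default_truths().items() if k != "elastin"}
        with pytest.raises(KeyError, match="elastin"):
            ph.sample_truth(labels, truths, seed=0)


class TestChannels:
    def test_inner_area_is_shg_absent(self):
        labels = ph.make_geometry(small_cfg())
        channels = ph.render_channels(labels, ph.default_truths(), speckle_sigma=0.15, seed=1)
        inner = labels == ph.LABEL_CODES["inner_ecm"]
        assert (channels.shg[inner] < 0.05 * channels.shg.max()).all()

    def test_elastin_fibers_brightest_in_outer_area(self):
        labels = ph.make_geometry(small_cfg())
        channels = ph.render_channels(labels, ph.default_truths(), speckle_sigma=0.15, seed=1)
        outer = np.isin(labels, [ph.LABEL_CODES["collagen_I"], ph.LABEL_CODES["elastin"]])
        elastin = labels == ph.LABEL_CODES["elastin"]
        cutoff = np.quantile(channels.tpeaf[outer], 1.0 - elastin.sum() / outer.sum())
        assert (channels.tpeaf[elastin] > cutoff).mean() > 0.95

    def test_equal_channel_levels_give_zero_saaid(self):
        from dermaflim.maps import compute_saaid

        labels = ph.make_geometry(small_cfg())
        truths = {
            name: dataclasses.replace(t, shg_level=0.5, tpeaf_level=0.5)
            for name, t in ph.default_truths().items()
        }
        channels = ph.render_channels(labels, truths, speckle_sigma=0.0, seed=1)
        smap = compute_saaid(channels)
        assert np.allclose(smap.saaid[smap.defined], 0.0)


class TestSimulateTCSPC:
    def test_monoexponential_limit_recovers_tau_by_loglinear_fit(self):
        # a2 -> 0, delta IRF: expected counts are a pure exponential whose
        # log is linear in t with slope -1/tau1 to <0.1 %.
        nt, bw = 256, 12500.0 / 256.0
        t = (np.arange(nt) + 0.5) * bw
        irf = ph.gaussian_irf(nt, bw, fwhm=0.0, t0=0.0)
        expected = model_decay(tau1=400.0, tau2=2500.0, a1=1.0, a2=0.0, irf=irf, bin_axis=t)
        slope = np.polyfit(t, np.log(expected), 1)[0]
        assert abs(-1.0 / slope - 400.0) / 400.0 < 1e-3

    def test_counts_conserved_in_expectation(self):
        # Law of large numbers over >=1000 pixels: mean total counts per
        # pixel matches the region budget within 3 sigma.
        truth = ph.default_truths()["collagen_I"]
        cube = ph.uniform_patch(truth, (40, 40), counts_per_pixel=2000.0, seed=9)
        totals = cube.counts.sum(axis=2)
        n = totals.size
        sigma = np.sqrt(2000.0 / n)
        assert abs(totals.mean() - 2000.0) < 3 * sigma

    def test_identical_config_and_seed_give_bitwise_identical_cube(self):
        cfg = small_cfg()
        a = ph.simulate_dataset(cfg)[0]
        b = ph.simulate_dataset(cfg)[0]
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.irf, b.irf)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(bin_width=-1.0).validate()
        with pytest.raises(ValueError):
            small_cfg(irf_fwhm=-5.0).validate()

    def test_mixture_mode_blends_rbc_and_plasma(self):
        cfg = small_cfg(capillary_mode="mixture", mixture_rbc_weight=0.85)
        labels = ph.make_geometry(cfg)
        maps = ph.sample_truth(labels, ph.default_truths(), seed=1,
                               capillary_mode="mixture", mixture_rbc_weight=0.85)
        cap = labels == ph.LABEL_CODES["capillary"]
        assert np.isfinite(maps.tau1_b[cap]).all()
        assert (maps.mix_weight[cap] == 0.85).all()
        assert (maps.mix_weight[~cap] == 1.0).all()
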