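"""Tissue segmentation against phantom ground truth, BPF, paired tests, profiles."""

import numpy as np
import pytest
from scipy import special

from latentmorph import morphometry as mm
from latentmorph.phantom import AttributeRecord, analytic_bpf, make_phantom, sample_cohort
from latentmorph.semantics import ManipulationSeries


@pytest.fixture(scope="module")
def clean_phantom():
    return make_phantom(AttributeRecord(seed=0), size=64, noise_std=0.0)


class TestSegmentTissues:
    def test_exact_intensities_recover_ground_truth(self, clean_phantom):
        seg = mm.segment_tissues(clean_phantom.channels[0], seed=0, contrast="t1w")
        for tissue in ("background", "csf", "gm", "wm"):
            np.testing.assert_array_equal(seg.mask(tissue), clean_phantom.tissue_masks[tissue])

    def test_noisy_phantom_agreement_above_98_percent(self):
        p = make_phantom(AttributeRecord(seed=1), size=64, noise_std=0.02)
        seg = mm.segment_tissues(p.channels[0], seed=0, contrast="t1w")
        agree = np.mean([
            (seg.mask(t) == p.tissue_masks[t]).mean()
            for t in ("background", "csf", "gm", "wm")])
        assert agree >= 0.98

    def test_adc_contrast_uses_reversed_intensity_order(self):
        p = make_phantom(AttributeRecord(contrast="adc", seed=2), size=64, noise_std=0.0)
        seg = mm.segment_tissues(p.channels[0], seed=0, contrast="adc")
        for tissue in ("csf", "gm", "wm"):
            np.testing.assert_array_equal(seg.mask(tissue), p.tissue_masks[tissue])

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mm.segment_tissues(np.full((32, 32), 0.5))

    def test_assignment_invariant_to_kmeans_seed(self, clean_phantom):
        a = mm.segment_tissues(clean_phantom.channels[0], seed=0)
        b = mm.segment_tissues(clean_phantom.channels[0], seed=99)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestBpf:
    def test_counts_formula(self):
        labels = np.array([["gm"] * 10, ["wm"] * 10, ["csf"] * 5 + ["background"] * 5])
        seg = mm.TissueSegmentation(labels=labels, centroids={}, assignment_rule={})
        # 20 parenchyma / 25 intracranial
        assert mm.bpf_from_labels(seg) == pytest.approx(0.8)

    def test_zero_csf_gives_one(self):
        labels = np.array([["gm", "wm"], ["wm", "background"]])
        seg = mm.TissueSegmentation(labels=labels, centroids={}, assignment_rule={})
        assert mm.bpf_from_labels(seg) == 1.0

    def test_empty_intracranial_rejected(self):
        labels = np.full((4, 4), "background")
        seg = mm.TissueSegmentation(labels=labels, centroids={}, assignment_rule={})
        with pytest.raises(ValueError, match="intracranial"):
            mm.bpf_from_labels(seg)

    def test_matches_analytic_bpf_on_clean_cohort(self):
        for p in sample_cohort(20, "MS", seed=3, size=64, noise_std=0.0):
            seg = mm.segment_tissues(p.channels[0], seed=0, contrast="t1w")
            assert abs(mm.bpf_from_labels(seg) - analytic_bpf(p)) <= 0.02

    def test_segmented_bpf_decreasing_in_ventricle_scale(self):
        scales = [0.6, 0.9, 1.2, 1.5, 1.8]
        bpfs = []
        for s in scales:
            p = make_phantom(AttributeRecord(ventricle_scale=s, seed=4), size=64, noise_std=0.0)
            bpfs.append(mm.bpf_from_labels(mm.segment_tissues(p.channels[0], seed=0)))
        assert all(a > b for a, b in zip(bpfs, bpfs[1:]))


class TestPairedTtest:
    def test_known_differences_against_t_cdf_oracle(self):
        t, p = mm.paired_ttest([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert t == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-4)
        # independent oracle: p = I_{df/(df+t^2)}(df/2, 1/2) via the incomplete beta
        df = 2
        p_oracle = special.betainc(df / 2, 0.5, df / (df + t**2))
        assert p == pytest.approx(p_oracle, abs=1e-12)
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_identical_samples_flagged_undefined(self):
        t, p = mm.paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(t) and np.isnan(p)

    def test_swapping_negates_t_and_preserves_p(self):
        x, y = [2.0, 3.5, 4.0, 5.0], [1.0, 2.0, 4.5, 3.0]
        t1, p1 = mm.paired_ttest(x, y)
        t2, p2 = mm.paired_ttest(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mm.paired_ttest([1.0], [1.0, 2.0])


def series_from_images(images, grid):
    grid = np.asarray(grid, float)
    return ManipulationSeries(alpha_grid=grid, images=list(images),
                              wplus_series=[None] * len(grid),
                              baseline_index=int(np.nonzero(grid == 0)[0][0]))


class TestBpfCurve:
    def test_growing_ventricles_lower_bpf_and_reach_significance(self):
        grid = [0.0, 1.0, 2.0]
        scale_of = {0.0: 1.0, 1.0: 1.4, 2.0: 1.9}
        subjects = []
        for s in range(8):
            base = 1.0 + 0.03 * s  # inter-subject anatomical variation
            imgs = [make_phantom(AttributeRecord(ventricle_scale=base * scale_of[a],
                                                 seed=10 + s),
                                 size=64, noise_std=0.0).channels
                    for a in grid]
            subjects.append(series_from_images(imgs, grid))
        curve = mm.bpf_curve(subjects, contrast="t1w")
        assert curve.bpf.shape == (8, 3)
        assert curve.bpf[:, 2].mean() < curve.bpf[:, 0].mean()
        assert np.isnan(curve.p_values[curve.baseline_index])
        assert curve.significant[2]

    def test_constant_series_is_degenerate_not_significant(self):
        img = make_phantom(AttributeRecord(seed=11), size=64, noise_std=0.0).channels
        subjects = [series_from_images([img, img], [0.0, 1.0]) for _ in range(4)]
        curve = mm.bpf_curve(subjects)
        assert np.isnan(curve.p_values[1])
        assert not curve.significant.any()

    def test_single_subject_returns_curve_without_p_values(self):
        img = make_phantom(AttributeRecord(seed=12), size=64, noise_std=0.0).channels
        curve = mm.bpf_curve([series_from_images([img, img], [0.0, 1.0])])
        assert curve.bpf.shape == (1, 2)
        assert np.isnan(curve.p_values).all()

    def test_mismatched_grids_rejected(self):
        img = make_phantom(AttributeRecord(seed=13), size=64, noise_std=0.0).channels
        a = series_from_images([img, img], [0.0, 1.0])
        b = series_from_images([img, img], [0.0, 2.0])
        with pytest.raises(ValueError, match="alpha grid"):
            mm.bpf_curve([a, b])


class TestProfilesAndMaps:
    def test_profile_lengths_and_constant_image(self):
        img = np.full((16, 24), 0.3)
        row, col = mm.intensity_profile(img, 4, 5)
        assert row.shape == (24,) and col.shape == (16,)
        assert np.all(row == 0.3) and np.all(col == 0.3)

    def test_profile_through_ventricle_dips_in_csf(self, clean_phantom):
        ys, xs = np.nonzero(clean_phantom.tissue_masks["csf"])
        r = int(np.median(ys))
        row, _ = mm.intensity_profile(clean_phantom.channels, r, xs[0])
        dark = clean_phantom.tissue_masks["csf"][r] | clean_phantom.tissue_masks["background"][r]
        assert dark[np.argmin(row)]

    def test_profile_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            mm.intensity_profile(np.zeros((8, 8)), 8, 0)

    def test_difference_map_antisymmetric_and_zero_on_identity(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((3, 16, 16)), rng.random((3, 16, 16))
        assert np.all(mm.difference_map(a, a) == 0)
        np.testing.assert_allclose(mm.difference_map(a, b), -mm.difference_map(b, a))

    def test_enlarged_ventricle_shows_negative_mass_in_ventricle_region(self):
        base = make_phantom(AttributeRecord(ventricle_scale=1.0, seed=14), 64, noise_std=0.0)
        big = make_phantom(AttributeRecord(ventricle_scale=1.8, seed=14), 64, noise_std=0.0)
        diff = mm.difference_map(big.channels[0], base.channels[0])
        grown = big.tissue_masks["csf"] & ~base.tissue_masks["csf"]
        assert diff[grown].sum() < 0
        assert diff[grown].sum() < 0.5 * diff.sum()  # negative mass concentrated there
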