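"""Segmentation: FCM oracle equivalence, masking algebra, volumetry."""

import numpy as np
import pytest

from mipscsf.segmentation import (
    SegmentationConfig,
    apply_template,
    fcm_mrf_segment,
    preprocess,
    quantify_volume,
    segment_pipeline,
)
from mipscsf.synthetic import LABELS, generate_phantom, generate_template
from mipscsf.volume import MRVolume


def plain_fcm_oracle(x, v0, m=2.0, tol=1e-4, max_iter=100):
    """Textbook fuzzy c-means on 1D intensities, written independently
    of the package's implementation: membership update
    u_ik = 1 / sum_l (d_ik / d_il)^(2/(m-1)), centroid update
    v_k = sum u^m x / sum u^m, sorted centroids, stop on centroid shift."""
    v = np.sort(np.asarray(v0, dtype=float))
    for _ in range(max_iter):
        d2 = (x[None, :] - v[:, None]) ** 2 + 1e-12
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=0, keepdims=True)
        um = u**m
        v_new = np.sort((um * x[None, :]).sum(axis=1) / um.sum(axis=1))
        if np.max(np.abs(v_new - v)) < tol:
            v = v_new
            break
        v = v_new
    d2 = (x[None, :] - v[:, None]) ** 2 + 1e-12
    inv = d2 ** (-1.0 / (m - 1.0))
    return v, inv / inv.sum(axis=0, keepdims=True)


@pytest.fixture(scope="module")
def two_class_volume():
    """32^3 masked volume, two well-separated Gaussian intensity classes.

    Class assignment is voxelwise random, so spatial regularization has
    no systematic side to take and labels are intensity-driven.
    """
    rng = np.random.default_rng(5)
    shape = (32, 32, 32)
    hi = rng.random(shape) < 0.5
    x = np.where(hi, 0.8, 0.2) + rng.normal(0, 0.02, shape)
    vol = MRVolume(intensity=x, spacing=(1.0, 1.0, 1.0), mask=np.ones(shape, dtype=bool))
    return vol, hi


class TestPreprocess:
    def test_two_intensity_phantom_mask_is_exact(self):
        x = np.zeros((24, 24, 24))
        x[6:18, 6:18, 6:18] = 0.8
        pre = preprocess(MRVolume(intensity=x, spacing=(1, 1, 1)))
        assert np.array_equal(pre.mask, x > 0)

    def test_rescale_is_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 500, (12, 12, 12))
        pre = preprocess(MRVolume(intensity=x, spacing=(1, 1, 1)))
        flat, pflat = x.ravel(), pre.intensity.ravel()
        order = np.argsort(flat)
        assert np.all(np.diff(pflat[order]) >= 0)
        assert pre.intensity.min() == 0.0 and pre.intensity.max() == 1.0

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            preprocess(MRVolume(intensity=np.ones((8, 8, 8)), spacing=(1, 1, 1)))


class TestFCM:
    def test_beta_zero_matches_plain_fcm_oracle(self, two_class_volume):
        vol, hi = two_class_volume
        init = np.array([0.25, 0.7])
        cfg = SegmentationConfig(n_classes=2, mrf_beta=0.0, seed=0)
        fuzzy, _ = fcm_mrf_segment(vol, cfg, initial_centroids=init)
        x = vol.intensity[vol.mask]
        v_o, u_o = plain_fcm_oracle(x, init)
        np.testing.assert_allclose(fuzzy.centroids, v_o, atol=1e-6)
        np.testing.assert_allclose(fuzzy.membership[:, vol.mask], u_o, atol=1e-6)

    def test_well_separated_classes_match_threshold_oracle(self, two_class_volume):
        vol, hi = two_class_volume
        cfg = SegmentationConfig(n_classes=2, seed=0)
        fuzzy, labels = fcm_mrf_segment(vol, cfg)
        mid = fuzzy.centroids.mean()
        oracle = (vol.intensity > mid)[vol.mask]
        got = labels.labels[vol.mask] == 1
        assert (oracle == got).mean() >= 0.999

    def test_memberships_sum_to_one(self, two_class_volume):
        vol, _ = two_class_volume
        fuzzy, _ = fcm_mrf_segment(vol, SegmentationConfig(n_classes=3, seed=1, max_iter=30))
        sums = fuzzy.membership[:, vol.mask].sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_objective_nonincreasing_at_beta_zero(self, two_class_volume):
        vol, _ = two_class_volume
        cfg = SegmentationConfig(n_classes=2, mrf_beta=0.0, seed=0)
        fuzzy, _ = fcm_mrf_segment(vol, cfg)
        assert np.all(np.diff(fuzzy.objective_trace) <= 1e-9)

    def test_memberships_approach_uniform_as_fuzzifier_grows(self, two_class_volume):
        vol, _ = two_class_volume
        spread = []
        for m in (2.0, 10.0, 50.0, 250.0):
            cfg = SegmentationConfig(n_classes=2, fuzzifier=m, mrf_beta=0.0, seed=0, max_iter=5)
            fuzzy, _ = fcm_mrf_segment(vol, cfg)
            spread.append(float(np.abs(fuzzy.membership[:, vol.mask] - 0.5).max()))
        assert np.all(np.diff(spread) < 0)
        assert spread[-1] < 0.05

    def test_too_many_classes_rejected(self):
        x = np.zeros((10, 10, 10))
        x[3:7, 3:7, 3:7] = 1.0
        pre = preprocess(MRVolume(intensity=x, spacing=(1, 1, 1)))
        with pytest.raises(ValueError):
            fcm_mrf_segment(pre, SegmentationConfig(n_classes=4, seed=0))


class TestMaskingAndVolumetry:
    def test_all_ones_template_is_identity(self):
        cand = np.random.default_rng(0).random((8, 8, 8)) > 0.5
        assert np.array_equal(apply_template(cand, np.ones_like(cand)), cand)

    def test_all_zeros_template_empties_mask(self):
        cand = np.ones((4, 4, 4), dtype=bool)
        assert apply_template(cand, np.zeros_like(cand)).sum() == 0

    def test_intersection_bounded_by_operands(self):
        rng = np.random.default_rng(1)
        cand = rng.random((10, 10, 10)) > 0.4
        tpl = rng.random((10, 10, 10)) > 0.6
        final = apply_template(cand, tpl)
        assert final.sum() <= min(cand.sum(), tpl.sum())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_template(np.ones((4, 4, 4), bool), np.ones((4, 4, 5), bool))

    def test_scanner_geometry_voxel_arithmetic(self):
        q = quantify_volume(np.ones((10, 10, 10), bool), (0.5, 0.5, 0.582))
        assert q.voxel_volume_mm3 == pytest.approx(0.1455)
        assert q.volume_ml == pytest.approx(0.1455)
        assert q.voxel_count == 1000

    def test_empty_mask_is_zero_ml(self):
        assert quantify_volume(np.zeros((5, 5, 5), bool), (1, 1, 1)).volume_ml == 0.0

    def test_volume_linear_in_spacing(self):
        mask = np.ones((6, 6, 6), bool)
        a = quantify_volume(mask, (0.5, 0.5, 0.5)).volume_ml
        b = quantify_volume(mask, (1.0, 0.5, 0.5)).volume_ml
        assert b == pytest.approx(2 * a)


class TestPipeline:
    def test_recovers_known_volume_and_is_deterministic(self, small_phantom_spec):
        vol, truth = generate_phantom(small_phantom_spec, 0.8, 1.0)
        tpl = generate_template(small_phantom_spec, dilation_mm=1.5)
        res1 = segment_pipeline(vol, tpl)
        res2 = segment_pipeline(vol, tpl)
        assert res1.quantification == res2.quantification
        assert abs(res1.quantification.volume_ml - 0.8) / 0.8 <= 0.10

    def test_candidate_covers_true_csf_core(self, small_phantom_spec):
        vol, truth = generate_phantom(small_phantom_spec, 0.8, 1.0)
        res = segment_pipeline(vol, generate_template(small_phantom_spec, 1.5))
        csf = truth.mask_of(LABELS["CSF"])
        # interior CSF voxels (all 6 neighbours CSF) must be in the candidate
        from scipy import ndimage

        core = ndimage.binary_erosion(csf)
        assert (res.candidate_mask & core).sum() / core.sum() >= 0.99

    def test_mrf_regularization_reduces_boundary_noise(self, small_phantom_spec):
        from dataclasses import replace

        # noise-dominated regime: misclassified boundary voxels are what
        # the spatial prior is there to clean up
        spec = replace(small_phantom_spec, noise_sd=0.15, smoothing_fwhm=0.0, seed=21)
        vol, truth = generate_phantom(spec, 0.8, 1.0)
        tpl = generate_template(spec, 1.5)
        csf = truth.mask_of(LABELS["CSF"])
        errors = []
        for beta in (0.0, 0.5, 1.0, 2.0):
            cfg = SegmentationConfig(mrf_beta=beta, seed=0)
            res = segment_pipeline(vol, tpl, cfg)
            errors.append(int((res.csf_mask ^ csf).sum()))
        assert np.all(np.diff(errors) <= 0)
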