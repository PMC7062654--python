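from __future__ import annotations

import math

import numpy as np
import pytest

from dwiradiomics import (
    AnnotatedImage,
    GlcmSpec,
    TextureConfig,
    arm_fit,
    extract_all,
    feature_catalogue,
    feature_map,
    geometry_features,
    glcm,
    glcm_features,
    gradient_features,
    haar_features,
    his_features,
    normalize_roi,
    rlm,
    rlm_features,
)
from dwiradiomics.errors import ContractViolationError, UnknownFeatureError

import _oracles as orc
from conftest import random_blob_mask, random_connected_mask


def quantized(img, mask, ng=8):
    return normalize_roi(np.asarray(img, float), np.asarray(mask, bool), ng)


# ---------------------------------------------------------------------------
# Closed-form fixtures
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_his_two_level(self):
        q = quantized([[1, 1], [2, 2]], np.ones((2, 2), bool), 2)
        # levels are {1,1,2,2} after quantization to 2 levels
        f = his_features(q)
        assert f["mean"] == pytest.approx(1.5)
        assert f["variance"] == pytest.approx(0.25)
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_his_constant(self):
        q = quantized(np.full((3, 3), 5.0), np.ones((3, 3), bool), 8)
        f = his_features(q)
        assert f["mean"] == 1.0 and f["variance"] == 0.0
        assert math.isnan(f["skewness"]) and math.isnan(f["kurtosis"])

    def test_glcm_two_stripe(self):
        q = quantized([[0, 0], [9, 9]], np.ones((2, 2), bool), 2)
        P = glcm(q, GlcmSpec(1, 0))
        expected = np.array([[0.5, 0.0], [0.0, 0.5]])
        np.testing.assert_allclose(P, expected)
        f = glcm_features(P)
        assert f["asm"] == pytest.approx(0.5)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["entropy"] == pytest.approx(math.log(2))

    def test_glcm_single_entry(self):
        q = quantized(np.full((3, 3), 2.0), np.ones((3, 3), bool), 4)
        P = glcm(q, GlcmSpec(1, 0))
        f = glcm_features(P)
        assert f["asm"] == 1.0 and f["entropy"] == 0.0 and f["contrast"] == 0.0
        assert math.isnan(f["correlation"])  # zero-variance marginal

    def test_glcm_rejects_unnormalized(self):
        with pytest.raises(ContractViolationError):
            glcm_features(np.ones((3, 3)))

    def test_glcm_no_pairs_is_missing(self):
        # a 1-pixel-high strip has no vertical pairs at d=2
        m = np.zeros((4, 4), bool)
        m[0, :] = True
        q = normalize_roi(np.arange(16.0).reshape(4, 4), m, 4)
        assert glcm(q, GlcmSpec(2, 90)) is None

    def test_rlm_constant_roi(self):
        q = quantized(np.full((4, 4), 3.0), np.ones((4, 4), bool), 8)
        R = rlm(q, 0)
        assert R[0, 3] == 4 and R.sum() == 4  # one run of length 4 per row
        f = rlm_features(R, 16)
        assert f["sre"] == pytest.approx(1 / 16)
        assert f["lre"] == pytest.approx(16)
        assert f["fraction"] == pytest.approx(0.25)

    def test_rlm_checkerboard(self):
        img = np.indices((4, 4)).sum(axis=0) % 2 * 10.0
        q = quantized(img, np.ones((4, 4), bool), 2)
        R = rlm(q, 0)
        assert R[:, 0].sum() == 16  # all runs length 1
        f = rlm_features(R, 16)
        assert f["sre"] == 1.0 and f["lre"] == 1.0 and f["fraction"] == 1.0

    def test_gradient_constant_and_ramp(self):
        mask = np.ones((6, 6), bool)
        f = gradient_features(np.full((6, 6), 3.0), mask)
        assert f["mean"] == 0.0 and f["variance"] == 0.0 and f["nonzero_fraction"] == 0.0
        ramp = np.tile(np.arange(6.0), (6, 1))
        f = gradient_features(ramp, mask)
        assert f["mean"] == pytest.approx(1.0)
        assert f["variance"] == pytest.approx(0.0)
        assert f["nonzero_fraction"] == 1.0

    def test_arm_constant_roi(self):
        q = quantized(np.full((8, 8), 4.0), np.ones((8, 8), bool), 8)
        f = arm_fit(q)
        for k in ("theta1", "theta2", "theta3", "theta4", "sigma"):
            assert f[k] == pytest.approx(0.0)

    def test_haar_constant_details_vanish(self):
        mask = np.ones((8, 8), bool)
        f = haar_features(np.full((8, 8), 2.5), mask, 3)
        for s in (1, 2, 3):
            for band in ("LH", "HL", "HH"):
                assert f[f"s{s}_{band}"] == pytest.approx(0.0, abs=1e-18)

    def test_haar_two_row_block(self):
        a, b = 7.0, 3.0
        img = np.array([[a, a], [b, b]])
        f = haar_features(img, np.ones((2, 2), bool), 1)
        assert f["s1_HL"] == pytest.approx((a - b) ** 2)  # vertical difference
        assert f["s1_LH"] == pytest.approx(0.0, abs=1e-18)
        assert f["s1_HH"] == pytest.approx(0.0, abs=1e-18)

    def test_haar_parseval_on_dyadic_box(self, rng):
        img = rng.normal(size=(16, 16))
        mask = np.ones((16, 16), bool)
        max_scale = 4
        f = haar_features(img, mask, max_scale)
        w = img - img.mean()
        total = 0.0
        for s in range(1, max_scale + 1):
            count = (16 // 2**s) ** 2
            total += sum(f[f"s{s}_{b}"] * count for b in ("LH", "HL", "HH"))
        total += f[f"s{max_scale}_LL"] * (16 // 2**max_scale) ** 2
        assert total == pytest.approx((w**2).sum(), abs=1e-9)

    def test_haar_matches_pywavelets_on_dyadic_box(self, rng):
        """Cross-check the separable Haar cascade against PyWavelets."""
        pywt = pytest.importorskip("pywt")
        img = rng.normal(size=(16, 16))
        mask = np.ones((16, 16), bool)
        f = haar_features(img, mask, 2)
        w = img - img.mean()
        coeffs = pywt.wavedec2(w, "haar", level=2)
        # wavedec2 returns (cA2, (cH2, cV2, cD2), (cH1, cV1, cD1));
        # cH is horizontal *detail* = high-pass along rows = our HL.
        (cH1, cV1, cD1) = coeffs[2]
        (cH2, cV2, cD2) = coeffs[1]
        assert f["s1_HL"] == pytest.approx(np.mean(cH1**2))
        assert f["s1_LH"] == pytest.approx(np.mean(cV1**2))
        assert f["s1_HH"] == pytest.approx(np.mean(cD1**2))
        assert f["s2_HL"] == pytest.approx(np.mean(cH2**2))

    def test_geometry_square(self):
        m = np.zeros((12, 12), bool)
        m[1:11, 1:11] = True
        f = geometry_features(m, (1.0, 1.0))
        assert f["area"] == pytest.approx(100.0)
        assert f["feret"] == pytest.approx(9 * math.sqrt(2))
        assert f["perimeter"] == pytest.approx(36.0)
        assert f["elongation"] == pytest.approx(1.0)

    def test_geometry_rotation_invariance(self, rng):
        m = random_blob_mask(rng, (12, 12))
        f0 = geometry_features(m, (1.0, 1.0))
        f90 = geometry_features(np.rot90(m).copy(), (1.0, 1.0))
        for k in f0:
            assert f0[k] == pytest.approx(f90[k], abs=1e-9), k

    def test_circularity_bounded_by_disk(self, rng):
        """Isoperimetric direction: no shape beats the disk of equal area.

        Chain-code perimeters carry a sub-pixel discretization bias, so the
        comparison allows a small rasterization slack.
        """
        from dwiradiomics import make_lesion_mask

        yy, xx = np.mgrid[0:41, 0:41]
        for _ in range(5):
            m = make_lesion_mask(rng, (8, 12), (41, 41)).mask
            c_blob = geometry_features(m)["circularity"]
            # rasterized disk of equal area
            r = math.sqrt(m.sum() / math.pi)
            disk = (yy - 20.0) ** 2 + (xx - 20.0) ** 2 <= r**2
            c_disk = geometry_features(disk)["circularity"]
            assert 0 < c_blob <= c_disk + 0.05


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence on random small ROIs
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    N_ROIS = 25  # per family here; the acceptance suite runs 100

    def _roi(self, rng, ng=6):
        shape = (int(rng.integers(5, 9)), int(rng.integers(5, 9)))
        mask = random_connected_mask(rng, shape, n_pixels=int(rng.integers(16, 30)))
        img = rng.normal(size=shape)
        return img, mask, quantized(img, mask, ng)

    def test_his_oracle(self, rng):
        for _ in range(self.N_ROIS):
            _, _, q = self._roi(rng)
            got = his_features(q)
            want = orc.oracle_his(q.levels)
            for k in want:
                np.testing.assert_allclose(got[k], want[k], atol=1e-9, err_msg=k)

    def test_glcm_and_features_oracle(self, rng):
        for _ in range(self.N_ROIS):
            _, mask, q = self._roi(rng)
            d = int(rng.integers(1, 4))
            ang = [0, 45, 90, 135][rng.integers(0, 4)]
            P = glcm(q, GlcmSpec(d, ang))
            P_ref = orc.oracle_glcm(q.level_image, mask, d, ang, q.n_levels)
            if P is None:
                assert P_ref is None
                continue
            np.testing.assert_allclose(P, P_ref, atol=1e-12)
            got, want = glcm_features(P), orc.oracle_glcm_features(P_ref)
            for k in want:
                np.testing.assert_allclose(got[k], want[k], atol=1e-9, err_msg=k)

    def test_rlm_oracle(self, rng):
        for _ in range(self.N_ROIS):
            _, mask, q = self._roi(rng)
            for ang in (0, 45, 90, 135):
                R = rlm(q, ang)
                R_ref = orc.oracle_rlm(q.level_image, mask, ang, q.n_levels)
                np.testing.assert_allclose(R, R_ref)
                got = rlm_features(R, q.n_pixels)
                want = orc.oracle_rlm_features(R_ref, q.n_pixels)
                for k in want:
                    np.testing.assert_allclose(got[k], want[k], atol=1e-9, err_msg=k)

    def test_rlm_total_run_conservation(self, rng):
        for _ in range(self.N_ROIS):
            _, _, q = self._roi(rng)
            for ang in (0, 45, 90, 135):
                R = rlm(q, ang)
                assert (R * np.arange(1, R.shape[1] + 1)).sum() == q.n_pixels

    def test_gradient_oracle(self, rng):
        for _ in range(self.N_ROIS):
            img, mask, _ = self._roi(rng)
            got = gradient_features(img, mask)
            want = orc.oracle_gradient(img, mask)
            for k in want:
                if math.isnan(want[k]):
                    assert math.isnan(got[k]), k
                else:
                    np.testing.assert_allclose(got[k], want[k], atol=1e-9, err_msg=k)

    def test_arm_oracle(self, rng):
        for _ in range(self.N_ROIS):
            shape = (int(rng.integers(6, 9)), int(rng.integers(6, 9)))
            mask = np.ones(shape, bool)  # full box guarantees usable pixels
            img = rng.normal(size=shape)
            q = quantized(img, mask, 6)
            got = arm_fit(q)
            want = orc.oracle_arm(q.level_image, mask)
            for k in want:
                np.testing.assert_allclose(got[k], want[k], atol=1e-9, err_msg=k)

    def test_haar_oracle(self, rng):
        for _ in range(self.N_ROIS):
            img, mask, _ = self._roi(rng)
            got = haar_features(img, mask, 2)
            want = orc.oracle_haar(img, mask, 2)
            for k in want:
                if math.isnan(want[k]):
                    assert math.isnan(got[k]), k
                else:
                    np.testing.assert_allclose(got[k], want[k], atol=1e-9, err_msg=k)

    def test_geometry_oracle(self, rng):
        for _ in range(self.N_ROIS):
            mask = random_blob_mask(rng, (int(rng.integers(7, 9)), int(rng.integers(7, 9))))
            spacing = (float(rng.uniform(0.5, 2)), float(rng.uniform(0.5, 2)))
            got = geometry_features(mask, spacing)
            want = orc.oracle_geometry(mask, spacing)
            for k in want:
                np.testing.assert_allclose(got[k], want[k], atol=1e-9, err_msg=k)


# ---------------------------------------------------------------------------
# ARM parameter recovery
# ---------------------------------------------------------------------------

class TestArmRecovery:
    def test_known_process_recovered(self):
        from dwiradiomics.synthetic_data import _causal_ar_field

        rng = np.random.default_rng(7)
        field = _causal_ar_field((64, 64), (0.4, 0.4, 0.0, 0.0), rng)
        # map the field onto many levels so quantization noise is negligible
        q = normalize_roi(field, np.ones((64, 64), bool), 256)
        f = arm_fit(q)
        assert f["theta1"] == pytest.approx(0.4, abs=0.1)
        assert f["theta2"] == pytest.approx(0.4, abs=0.1)

    def test_white_noise_thetas_near_zero(self):
        rng = np.random.default_rng(8)
        img = rng.normal(size=(64, 64))
        q = normalize_roi(img, np.ones((64, 64), bool), 256)
        f = arm_fit(q)
        bound = 3 / math.sqrt(62 * 62)
        for k in ("theta1", "theta2", "theta3", "theta4"):
            assert abs(f[k]) < bound


# ---------------------------------------------------------------------------
# extract_all and feature maps
# ---------------------------------------------------------------------------

class TestExtractAll:
    def test_catalogue_schema_and_determinism(self, small_cohort):
        les = small_cohort.lesions[0]
        cfg = TextureConfig()
        fv1 = extract_all(les.images.adc, les.true_mask, cfg)
        fv2 = extract_all(les.images.adc, les.true_mask, cfg)
        assert tuple(fv1.values) == feature_catalogue(cfg)
        a = np.array(list(fv1.values.values()))
        b = np.array(list(fv2.values.values()))
        np.testing.assert_array_equal(a, b)

    def test_storage_order_independence(self, small_cohort):
        les = small_cohort.lesions[0]
        img = les.images.adc
        f_contig = extract_all(img, les.true_mask)
        img_f = AnnotatedImage(
            np.asfortranarray(img.pixels), img.spacing, img.modality, img.id
        )
        f_fortran = extract_all(img_f, les.true_mask)
        np.testing.assert_array_equal(
            np.array(list(f_contig.values.values())),
            np.array(list(f_fortran.values.values())),
        )

    def test_intensity_rescaling_invariance_of_quantized_families(self, small_cohort):
        les = small_cohort.lesions[0]
        img = les.images.adc
        scaled = AnnotatedImage(3.7 * img.pixels + 11.0, img.spacing, img.modality, img.id)
        f1 = extract_all(img, les.true_mask)
        f2 = extract_all(scaled, les.true_mask)
        for name in f1.values:
            if name.split("_")[0] in ("HIS", "COM", "RLM", "ARM", "GEO"):
                np.testing.assert_allclose(f1[name], f2[name], atol=1e-9, err_msg=name)

    def test_runtime_budget_64x64(self):
        import time

        rng = np.random.default_rng(0)
        img = AnnotatedImage(rng.normal(size=(64, 64)))
        mask = np.zeros((64, 64), bool)
        mask[4:60, 4:60] = True
        t0 = time.perf_counter()
        extract_all(img, mask)
        assert time.perf_counter() - t0 < 3.0

    def test_feature_map_constant_entropy_zero(self):
        img = AnnotatedImage(np.full((12, 12), 2.0))
        mask = np.zeros((12, 12), bool)
        mask[2:10, 2:10] = True
        fmap = feature_map(img, mask, "COM_d1_0deg_entropy", window=5)
        inside = fmap.pixels[mask]
        np.testing.assert_allclose(inside[np.isfinite(inside)], 0.0, atol=1e-12)
        assert np.all(np.isnan(fmap.pixels[~mask]))

    def test_feature_map_matches_window_extraction(self, rng):
        img = AnnotatedImage(rng.normal(size=(12, 12)))
        mask = np.zeros((12, 12), bool)
        mask[2:10, 2:10] = True
        name = "HIS_mean"
        fmap = feature_map(img, mask, name, window=5)
        r, c = 5, 6
        sub_px = img.pixels[r - 2 : r + 3, c - 2 : c + 3]
        sub_m = mask[r - 2 : r + 3, c - 2 : c + 3]
        expected = his_features(normalize_roi(sub_px, sub_m, 64))["mean"]
        assert fmap.pixels[r, c] == pytest.approx(expected)

    def test_feature_map_separates_two_textures(self, rng):
        left = rng.normal(0.0, 1.0, size=(16, 8))
        right = rng.normal(8.0, 1.0, size=(16, 8))
        img = AnnotatedImage(np.hstack([left, right]))
        mask = np.ones((16, 16), bool)
        fmap = feature_map(img, mask, "HIS_mean", window=5)
        assert np.nanmean(fmap.pixels[:, :6]) < np.nanmean(fmap.pixels[:, 10:])

    def test_unknown_feature_rejected(self):
        img = AnnotatedImage(np.zeros((8, 8)))
        with pytest.raises(UnknownFeatureError):
            feature_map(img, np.ones((8, 8), bool), "NOT_A_FEATURE", 5)
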