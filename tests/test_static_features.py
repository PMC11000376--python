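import numpy as np
import pytest

from dynrad.preprocess import quantize_gray_levels
from dynrad.static_features import (
    N_STATIC,
    WAVELET_BANDS,
    default_roster,
    extract_static_vector,
    intensity_features,
    static_feature_names,
    texture_features,
    wavelet_decompose,
)
from dynrad.texture import (
    DIRECTIONS_13,
    glcm,
    glcm_features,
    glrlm,
    glszm,
    ngtdm,
    texture_features_from_labels,
)
from oracles import bf_glcm, bf_glrlm, bf_glszm, bf_ngtdm


class TestIntensityFeatures:
    def test_closed_form_moments(self):
        f = intensity_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Variance"] == pytest.approx(1.25)
        assert f["Range"] == pytest.approx(3.0)
        assert len(f) == 7

    def test_symmetric_sample_has_zero_skewness(self):
        f = intensity_features(np.array([-2.0, -1.0, 1.0, 2.0]))
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_roi_convention(self):
        f = intensity_features(np.full(10, 5.0))
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0
        assert f["Variance"] == 0.0


class TestMatrixOracles:
    """The spatial matrices must match exhaustive brute-force enumeration."""

    @pytest.mark.parametrize("offset", DIRECTIONS_13)
    def test_glcm_counts(self, masked_roi, offset):
        ours = glcm(masked_roi, 4, offset, normalize=False)
        np.testing.assert_allclose(ours, bf_glcm(masked_roi, 4, offset), atol=1e-10)

    @pytest.mark.parametrize("offset", DIRECTIONS_13)
    def test_glrlm_runs(self, masked_roi, offset):
        ours = glrlm(masked_roi, 4, offset)
        expected = bf_glrlm(masked_roi, 4, offset)
        for (lv, ln), c in expected.items():
            assert ours[lv - 1, ln - 1] == c
        assert ours.sum() == sum(expected.values())

    def test_glszm_zones(self, masked_roi):
        ours = glszm(masked_roi, 4)
        expected = bf_glszm(masked_roi)
        for (lv, sz), c in expected.items():
            assert ours[lv - 1, sz - 1] == c
        assert ours.sum() == sum(expected.values())

    def test_ngtdm_arrays(self, masked_roi):
        s, p, n = ngtdm(masked_roi, 4)
        s2, p2, n2 = bf_ngtdm(masked_roi, 4)
        assert n == n2
        np.testing.assert_allclose(s, s2, atol=1e-10)
        np.testing.assert_allclose(p, p2, atol=1e-12)

    def test_small_flat_roi_2x2x1(self):
        # two rows of levels 1 and 2: hand-enumerable co-occurrences
        lab = np.array([[[1], [1]], [[2], [2]]], dtype=np.int32)  # (2,2,1)
        along_y = glcm(lab, 2, (0, 1, 0), normalize=False)
        np.testing.assert_array_equal(along_y, [[2, 0], [0, 2]])
        along_z = glcm(lab, 2, (1, 0, 0), normalize=False)
        np.testing.assert_array_equal(along_z, [[0, 2], [2, 0]])


class TestTextureFeatures:
    def test_uniform_roi_max_probability_one(self):
        lab = np.ones((3, 3, 3), dtype=np.int32)
        feats = texture_features_from_labels(lab, 64)
        assert feats["Maximum probability"] == pytest.approx(1.0)
        assert feats["Contrast"] == pytest.approx(0.0)
        assert len(feats) == 53

    def test_glcm_matrices_normalised_and_symmetric(self, masked_roi):
        for off in DIRECTIONS_13:
            P = glcm(masked_roi, 4, off)
            if P.sum():
                assert P.sum() == pytest.approx(1.0, abs=1e-12)
                np.testing.assert_allclose(P, P.T, atol=1e-15)

    def test_single_voxel_roi_no_exception(self):
        lab = np.zeros((3, 3, 3), dtype=np.int32)
        lab[1, 1, 1] = 2
        feats = texture_features_from_labels(lab, 4)
        assert np.isfinite(list(feats.values())).all()
        assert feats["Maximum probability"] == pytest.approx(1.0)

    def test_correlation_forms_agree(self, masked_roi):
        # Haralick and normalized-covariance correlations are algebraically equal
        from dynrad.texture import glcm_all_directions
        for P in glcm_all_directions(masked_roi, 4):
            f = glcm_features(P)
            assert f["Correlation1"] == pytest.approx(f["Correlation2"], abs=1e-10)

    def test_monotone_affine_invariance(self, rng):
        vol = rng.normal(0, 1, (6, 6, 6))
        mask = np.ones(vol.shape, dtype=np.uint8)
        a = texture_features(quantize_gray_levels(vol, mask, 16))
        b = texture_features(quantize_gray_levels(3.0 * vol + 11.0, mask, 16))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)


class TestWaveletDecompose:
    def test_returns_eight_named_bands(self, rng):
        bands = wavelet_decompose(rng.normal(0, 1, (12, 12, 12)))
        assert tuple(bands) == WAVELET_BANDS
        for b in bands.values():
            assert b.shape == (12, 12, 12)

    def test_constant_volume_high_pass_zero(self):
        bands = wavelet_decompose(np.full((8, 8, 8), 3.0))
        for name, b in bands.items():
            if "H" in name:
                np.testing.assert_allclose(b, 0.0, atol=1e-10)

    def test_parseval_energy_decimated_orthogonal(self, rng):
        vol = rng.normal(0, 1, (16, 16, 16))
        bands = wavelet_decompose(vol, wavelet="db2", stationary=False)
        total = sum(float((b ** 2).sum()) for b in bands.values())
        assert total == pytest.approx(float((vol ** 2).sum()), rel=1e-6)

    def test_odd_shape_supported(self, rng):
        bands = wavelet_decompose(rng.normal(0, 1, (9, 10, 11)))
        assert bands["LLL"].shape == (9, 10, 11)

    def test_too_small_volume_raises(self):
        with pytest.raises(ValueError, match="too small"):
            wavelet_decompose(np.zeros((3, 3, 3)))


class TestStaticVector:
    def test_feature_accounting(self, phantom_volume):
        vol, mask = phantom_volume
        sv = extract_static_vector(vol, mask, "arterial")
        assert len(sv.values) == N_STATIC == 484
        counts = {c: sv.categories.count(c) for c in ("intensity", "texture", "wavelet")}
        assert counts == {"intensity": 7, "texture": 53, "wavelet": 424}
        assert len(set(sv.names)) == 484

    def test_deterministic(self, phantom_volume):
        vol, mask = phantom_volume
        a = extract_static_vector(vol, mask, "plain")
        b = extract_static_vector(vol, mask, "plain")
        np.testing.assert_array_equal(a.values, b.values)

    def test_wavelet_names_carry_subband_suffix(self):
        names, cats = static_feature_names()
        for n, c in zip(names, cats):
            if c == "wavelet":
                assert n.rsplit(".", 1)[-1] in WAVELET_BANDS

    def test_constant_volume_high_band_features_match_flat_roi(self):
        # H-containing sub-bands of a constant volume are 0 everywhere, so
        # their texture features equal those of an all-equal quantised ROI.
        vol = np.full((10, 10, 10), 5.0)
        mask = np.zeros(vol.shape, dtype=np.uint8)
        mask[3:7, 3:7, 3:7] = 1
        sv = extract_static_vector(vol, mask, "plain")
        flat = texture_features_from_labels(np.ones((4, 4, 4), dtype=np.int32), 64)
        d = sv.as_dict()
        for k, v in flat.items():
            assert d[f"{k}_wavelet.HHH"] == pytest.approx(v, rel=1e-10)

    def test_roster_contains_named_signature_features(self):
        roster = default_roster()
        required = {
            "Skewness", "Variance", "Maximum probability", "Cluster prominence",
            "Correlation1", "Correlation2", "Autocorrelation",
            "Long run low gray-level emphasis", "Long run emphasis",
            "Gray-level variance", "Small zone emphasis", "Contrast",
        }
        assert required <= set(roster.names)
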