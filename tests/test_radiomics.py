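"""Radiomics extraction: degenerate regions, brute-force texture oracles,
shape limits, filters, invariances and cohort bookkeeping."""

import numpy as np
import pytest

import habitatomics as hb
from habitatomics.preprocess import Volume
from habitatomics.radiomics import (
    ExtractionConfig,
    discretise,
    extract_cohort,
    extract_region,
    filter_images,
)
from habitatomics.radiomics._shape import shape_features
from habitatomics.radiomics._texture import _DIRECTIONS, glcm_features

FAST = ExtractionConfig(families=("firstorder", "glcm", "gldm"), filters=("original",))


@pytest.fixture(scope="module")
def phantom_volume(default_phantom):
    volume, mask, truth, spec = default_phantom
    return Volume(volume, spec.voxel_spacing), mask, truth


class TestDegenerate:
    def test_constant_region(self):
        data = np.full((6, 6, 4), 80.0)
        mask = np.zeros(data.shape, np.uint8)
        mask[1:5, 1:5, 1:3] = 1
        feats = extract_region(Volume(data, (1, 1, 1)), mask, FAST)
        assert feats["original_firstorder_Variance"] == 0.0
        assert feats["original_firstorder_Entropy"] == 0.0
        assert feats["original_glcm_Contrast"] == 0.0
        assert feats["original_glcm_Correlation"] == 1.0  # degenerate convention

    def test_too_small_region_raises(self, phantom_volume):
        vol, mask, _ = phantom_volume
        tiny = np.zeros_like(mask)
        tiny[24, 24, 8] = 1
        with pytest.raises(ValueError, match="min_region_voxels"):
            extract_region(vol, tiny, FAST)

    def test_empty_region_raises(self, phantom_volume):
        vol, mask, _ = phantom_volume
        with pytest.raises(ValueError, match="empty"):
            extract_region(vol, np.zeros_like(mask), FAST)


class TestGLCMOracle:
    def test_joint_entropy_matches_pair_enumeration(self):
        # printed 3x3x1 fixture
        data = np.array(
            [[[10.0], [35.0], [35.0]], [[60.0], [10.0], [85.0]], [[35.0], [60.0], [10.0]]]
        )
        mask = np.ones(data.shape, np.uint8)
        cfg = ExtractionConfig(
            bin_width=25.0, families=("glcm",), filters=("original",), min_region_voxels=1
        )
        feats = extract_region(Volume(data, (1, 1, 1)), mask, cfg)

        # brute-force co-occurrence enumeration over the 13 directions
        levels, n_levels = discretise(data[mask.astype(bool)], 25.0)
        g = np.zeros(data.shape, dtype=int)
        g[mask.astype(bool)] = levels
        entropies = []
        shape = data.shape
        for off in _DIRECTIONS:
            pairs = {}
            count = 0
            for i in range(shape[0]):
                for j in range(shape[1]):
                    for k in range(shape[2]):
                        i2, j2, k2 = i + off[0], j + off[1], k + off[2]
                        if not (0 <= i2 < shape[0] and 0 <= j2 < shape[1] and 0 <= k2 < shape[2]):
                            continue
                        a, b = g[i, j, k], g[i2, j2, k2]
                        if a and b:
                            for key in ((a, b), (b, a)):  # symmetric
                                pairs[key] = pairs.get(key, 0) + 1
                            count += 2
            if count:
                ps = np.array(list(pairs.values())) / count
                entropies.append(-(ps * np.log2(ps)).sum())
        assert feats["original_glcm_JointEntropy"] == pytest.approx(
            np.mean(entropies), abs=1e-10
        )

    def test_contrast_matches_pair_enumeration(self):
        rng = np.random.default_rng(8)
        data = rng.uniform(0, 255, (4, 4, 3))
        mask = (rng.random((4, 4, 3)) > 0.25).astype(np.uint8)
        mask[0, 0, 0] = 1
        levels, n_levels = discretise(data[mask.astype(bool)], 25.0)
        g = np.zeros(data.shape, dtype=int)
        g[mask.astype(bool)] = levels
        per_dir = []
        for off in _DIRECTIONS:
            total, acc = 0, 0.0
            for i in range(4):
                for j in range(4):
                    for k in range(3):
                        i2, j2, k2 = i + off[0], j + off[1], k + off[2]
                        if not (0 <= i2 < 4 and 0 <= j2 < 4 and 0 <= k2 < 3):
                            continue
                        a, b = g[i, j, k], g[i2, j2, k2]
                        if a and b:
                            acc += 2 * (a - b) ** 2
                            total += 2
            if total:
                per_dir.append(acc / total)
        expected = np.mean(per_dir)
        out = glcm_features(g, n_levels)
        assert out["Contrast"] == pytest.approx(expected, abs=1e-10)


class TestShape:
    def test_sphere_sphericity_near_one(self):
        spec = hb.PhantomSpec(
            tumour_axes=(14.0, 14.0, 14.0),
            grid_shape=(40, 40, 40),
            voxel_spacing=(1.0, 1.0, 1.0),
            n_habitats=1,
            habitat_fractions=(1.0,),
            habitat_intensity_means=(100.0,),
            habitat_intensity_sds=(0.0,),
            habitat_smoothness=(0.0,),
        )
        _, mask, _ = hb.generate_phantom(spec)
        feats = shape_features(mask, spec.voxel_spacing)
        assert feats["Sphericity"] == pytest.approx(1.0, abs=0.05)
        analytic = 4.0 / 3.0 * np.pi * 14.0**3
        assert feats["MeshVolume"] == pytest.approx(analytic, rel=0.05)
        assert feats["Maximum3DDiameter"] == pytest.approx(28.0, rel=0.08)

    def test_axis_lengths_ordered(self, phantom_volume):
        _, mask, _ = phantom_volume
        feats = shape_features(mask, (1.0, 1.0, 3.0))
        assert (
            feats["MajorAxisLength"]
            >= feats["MinorAxisLength"]
            >= feats["LeastAxisLength"]
        )
        assert 0 < feats["Flatness"] <= feats["Elongation"] <= 1.0


class TestInvariances:
    def test_firstorder_matches_direct_computation(self, phantom_volume):
        vol, mask, _ = phantom_volume
        feats = extract_region(vol, mask, FAST)
        values = vol.data[mask.astype(bool)]
        assert feats["original_firstorder_Mean"] == pytest.approx(values.mean(), abs=1e-9)
        assert feats["original_firstorder_Median"] == pytest.approx(
            np.median(values), abs=1e-9
        )
        assert feats["original_firstorder_Minimum"] == values.min()
        assert feats["original_firstorder_Maximum"] == values.max()

    def test_texture_invariant_to_constant_shift(self, phantom_volume):
        vol, mask, _ = phantom_volume
        shifted = Volume(vol.data + 37.0, vol.spacing)
        a = extract_region(vol, mask, FAST)
        b = extract_region(shifted, mask, FAST)
        for name in a:
            if "_glcm_" in name or "_gldm_" in name:
                assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_wavelet_level1_has_eight_subbands(self, phantom_volume):
        vol, _, _ = phantom_volume
        images = filter_images(vol.data, vol.spacing, filters=("wavelet",))
        assert len(images) == 8
        assert {n[:8] for n in images} == {"wavelet-"}
        assert all(img.shape == vol.data.shape for img in images.values())

    def test_extra_log_sigma_adds_fixed_column_count(self, phantom_volume):
        vol, mask, _ = phantom_volume
        cfg2 = ExtractionConfig(
            families=("firstorder", "glcm"), filters=("original", "log"), log_sigmas=(2.0,)
        )
        cfg3 = ExtractionConfig(
            families=("firstorder", "glcm"),
            filters=("original", "log"),
            log_sigmas=(2.0, 3.0),
        )
        a = extract_region(vol, mask, cfg2)
        b = extract_region(vol, mask, cfg3)
        assert len(b) - len(a) == 18 + 24  # one more filter image x non-shape families


class TestCohort:
    def test_matrix_shapes_and_determinism(self, small_cohort, cohort_scaler):
        from habitatomics.clustering import segment_patient

        tables, masks, scaler = cohort_scaler
        cases = small_cohort[:5]
        hmaps = {
            c.patient_id: segment_patient(
                tables[c.patient_id], masks[c.patient_id], 3, scaler, seed=17
            )
            for c in cases
        }
        mats1 = extract_cohort(cases, hmaps, FAST)
        mats2 = extract_cohort(cases, hmaps, FAST)
        assert set(mats1) == {"whole", "habitat1", "habitat2", "habitat3"}
        for region in mats1:
            assert mats1[region].shape[0] == 5
            assert list(mats1[region].index) == [c.patient_id for c in cases]
            assert mats1[region].equals(mats2[region])
            assert mats1[region].columns.is_unique

    def test_provenance_in_names(self, phantom_volume):
        vol, mask, _ = phantom_volume
        feats = extract_region(
            vol, mask, ExtractionConfig(families=("firstorder", "shape"), log_sigmas=(2.0,))
        )
        for name in feats:
            image, family, _ = name.split("_", 2)
            assert family in {"firstorder", "shape"}
            assert image == "original" or image.startswith(("log-sigma", "wavelet-"))
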