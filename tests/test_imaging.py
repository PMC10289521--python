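"""MRI preprocessing and native feature extraction.

Texture features are validated against brute-force enumeration oracles
written independently in this file (explicit loops over voxel pairs,
neighbourhoods and zones), not against the vectorized implementation.
"""

import itertools
import math

import numpy as np
import pytest

from srsradiomics.imaging import (
    ImageVolume,
    MaskVolume,
    discretize,
    extract_features,
    glcm_features,
    ngtdm_features,
    resample_isotropic,
    zscore_normalize,
)


def _img(arr, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(arr, dtype=float), spacing)


def _mask(arr, spacing=(1.0, 1.0, 1.0), role="gtv"):
    return MaskVolume(np.asarray(arr, dtype=bool), spacing, role=role)


def _full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return _mask(np.ones(shape), spacing)


# ---------------------------------------------------------------------------
# normalization

class TestZscoreNormalize:
    def _setup(self, brain_vals, gtv_val):
        # brain voxels in one row, a GTV voxel appended on its own row
        arr = np.zeros((1, 2, max(len(brain_vals), 1)))
        arr[0, 0, :len(brain_vals)] = brain_vals
        arr[0, 1, 0] = gtv_val
        brain = np.zeros_like(arr, dtype=bool)
        brain[0, 0, :len(brain_vals)] = True
        brain[0, 1, 0] = True
        gtv = np.zeros_like(arr, dtype=bool)
        gtv[0, 1, 0] = True
        return _img(arr), _mask(brain, role="brain"), _mask(gtv)

    def test_constant_brain_region_rejected(self):
        img, brain, gtv = self._setup([5.0, 5.0, 5.0, 5.0], 9.0)
        with pytest.raises(ValueError, match="zero intensity SD"):
            zscore_normalize(img, brain, gtv)

    def test_voxel_at_mean_maps_to_zero(self):
        vals = [0.0, 2.0, 4.0, 6.0]
        img, brain, gtv = self._setup(vals, np.mean(vals))
        out = zscore_normalize(img, brain, gtv)
        assert out.voxels[0, 1, 0] == pytest.approx(0.0)

    def test_extreme_gtv_voxel_clipped_to_three(self):
        vals = [0.0, 2.0, 4.0, 6.0, 8.0]
        mu, sigma = np.mean(vals), np.std(vals)
        img, brain, gtv = self._setup(vals, mu + 10 * sigma)
        out = zscore_normalize(img, brain, gtv)
        assert out.voxels[0, 1, 0] == 3.0
        # hand-computed z for a brain voxel
        assert out.voxels[0, 0, 0] == pytest.approx((vals[0] - mu) / sigma)

    def test_intensity_shift_invariance(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(50, 10, (6, 7, 8))
        brain = np.zeros(arr.shape, dtype=bool)
        brain[1:5, 1:6, 1:7] = True
        gtv = np.zeros(arr.shape, dtype=bool)
        gtv[2:4, 2:4, 2:4] = True
        f0 = extract_features(zscore_normalize(_img(arr), _mask(brain),
                                               _mask(gtv)), _mask(gtv))
        f1 = extract_features(zscore_normalize(_img(arr + 123.4), _mask(brain),
                                               _mask(gtv)), _mask(gtv))
        for name in f0.computed_mask:
            assert f0[name] == pytest.approx(f1[name], abs=1e-9), name


# ---------------------------------------------------------------------------
# resampling

class TestResample:
    def test_identity_when_already_isotropic(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(4, 5, 6))
        img, mask = _img(arr, (0.5, 0.5, 0.5)), _full_mask((4, 5, 6), (0.5, 0.5, 0.5))
        out_img, out_mask = resample_isotropic(img, mask)
        np.testing.assert_allclose(out_img.voxels, arr, atol=1e-6)
        assert out_img.spacing == (0.5, 0.5, 0.5)

    def test_linear_ramp_resampled_exactly(self):
        # intensity = x-coordinate in mm; trilinear interpolation of a ramp
        # is the ramp evaluated at the new coordinates
        nx = 11
        arr = np.tile(np.arange(nx, dtype=float), (4, 4, 1))
        img = _img(arr, (1.0, 1.0, 1.0))
        out_img, _ = resample_isotropic(img, _full_mask(arr.shape))
        x_coords = np.arange(out_img.voxels.shape[2]) * 0.5
        interior = x_coords <= nx - 1
        expected = np.clip(x_coords, 0, nx - 1)
        np.testing.assert_allclose(out_img.voxels[2, 2, interior],
                                   expected[interior], atol=1e-5)

    def test_cube_mask_volume_preserved(self):
        # 10 mm cube on a 1 mm grid -> resampled volume within 5% of 1000 mm^3
        arr = np.zeros((14, 14, 14))
        m = np.zeros_like(arr, dtype=bool)
        m[2:12, 2:12, 2:12] = True
        _, out_mask = resample_isotropic(_img(arr), _mask(m))
        vol = out_mask.voxels.sum() * 0.5 ** 3
        assert vol == pytest.approx(1000.0, rel=0.05)


# ---------------------------------------------------------------------------
# discretization

class TestDiscretize:
    def test_uniform_roi_maps_to_bin_one(self):
        arr = np.full((2, 2, 2), 7.0)
        levels = discretize(_img(arr), _full_mask(arr.shape))
        assert set(levels.ravel()) == {1}

    def test_linear_span_occupancy_uniform(self):
        vals = np.linspace(0.0, 1.0, 64 * 4, endpoint=False)
        arr = vals.reshape(1, 16, 16)
        levels = discretize(_img(arr), _full_mask(arr.shape), n_bins=64)
        counts = np.bincount(levels.ravel())[1:]
        assert counts.max() - counts.min() <= 1

    def test_two_valued_roi_hits_extreme_bins(self):
        arr = np.array([[[0.0, 100.0, 0.0, 100.0]]])
        levels = discretize(_img(arr), _full_mask(arr.shape), n_bins=64)
        assert set(levels.ravel()) == {1, 64}


# ---------------------------------------------------------------------------
# texture oracles

def _oracle_glcm(levels, n_levels):
    """Brute-force GLCM features: loop over voxels and the 13 +directions,
    count symmetric co-occurrences, compute features per direction."""
    dirs = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
    shape = levels.shape
    feats = []
    for d in dirs:
        mat = np.zeros((n_levels, n_levels))
        for idx in np.ndindex(shape):
            jdx = tuple(i + o for i, o in zip(idx, d))
            if all(0 <= j < s for j, s in zip(jdx, shape)):
                a, b = levels[idx], levels[jdx]
                if a > 0 and b > 0:
                    mat[a - 1, b - 1] += 1
                    mat[b - 1, a - 1] += 1
        if mat.sum() == 0:
            continue
        p = mat / mat.sum()
        i_idx = np.arange(1, n_levels + 1)
        contrast = sum(p[i, j] * (i - j) ** 2
                       for i in range(n_levels) for j in range(n_levels))
        ent = -sum(p[i, j] * math.log2(p[i, j])
                   for i in range(n_levels) for j in range(n_levels) if p[i, j] > 0)
        idn = sum(p[i, j] / (1 + abs(i - j) / n_levels)
                  for i in range(n_levels) for j in range(n_levels))
        px = p.sum(axis=1)
        mu = sum((i + 1) * px[i] for i in range(n_levels))
        shade = sum(p[i, j] * ((i + 1) + (j + 1) - 2 * mu) ** 3
                    for i in range(n_levels) for j in range(n_levels))
        hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                    for i in range(n_levels) for j in range(n_levels)
                    if px[i] * px[j] > 0)
        imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - ent))))
        feats.append({"Contrast": contrast, "JointEntropy": ent, "Idn": idn,
                      "ClusterShade": shade, "Imc2": imc2})
    return {k: np.mean([f[k] for f in feats]) for k in feats[0]}


def _oracle_ngtdm(levels):
    """Brute-force NGTDM: explicit 26-neighbourhood loops."""
    shape = levels.shape
    gmax = int(levels.max())
    s = np.zeros(gmax + 1)
    n_i = np.zeros(gmax + 1)
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        neigh = []
        for d in itertools.product((-1, 0, 1), repeat=3):
            if d == (0, 0, 0):
                continue
            jdx = tuple(i + o for i, o in zip(idx, d))
            if all(0 <= j < sh for j, sh in zip(jdx, shape)) and levels[jdx] > 0:
                neigh.append(levels[jdx])
        if neigh:
            n_i[g] += 1
            s[g] += abs(g - np.mean(neigh))
    n_tot = n_i.sum()
    p = n_i / n_tot
    present = [g for g in range(1, gmax + 1) if n_i[g] > 0]
    ngp = len(present)
    sum_ps = sum(p[g] * s[g] for g in present)
    coarseness = 1 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        contrast = (sum(p[g1] * p[g2] * (g1 - g2) ** 2
                        for g1 in present for g2 in present)
                    / (ngp * (ngp - 1))) * (sum(s[g] for g in present) / n_tot)
        busy_den = sum(abs(g1 * p[g1] - g2 * p[g2])
                       for g1 in present for g2 in present)
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        complexity = sum(abs(g1 - g2) * (p[g1] * s[g1] + p[g2] * s[g2])
                         / (p[g1] + p[g2])
                         for g1 in present for g2 in present) / n_tot
        s_sum = sum(s[g] for g in present)
        strength = (sum((p[g1] + p[g2]) * (g1 - g2) ** 2
                        for g1 in present for g2 in present) / s_sum
                    if s_sum > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}


class TestTextureFeatures:
    def test_glcm_matches_enumeration_oracle(self):
        levels = np.array([[[1, 2], [2, 1]]], dtype=np.int32).reshape(1, 2, 2)
        ours = glcm_features(levels, 2)
        oracle = _oracle_glcm(levels, 2)
        for k, v in oracle.items():
            assert ours[k] == pytest.approx(v, abs=1e-12), k

    def test_glcm_oracle_on_random_volumes(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            levels = rng.integers(0, 4, size=(3, 3, 3)).astype(np.int32)
            levels[1, 1, 1] = 2  # ensure a nonempty ROI
            ours = glcm_features(levels, 3)
            oracle = _oracle_glcm(levels, 3)
            for k, v in oracle.items():
                assert ours[k] == pytest.approx(v, abs=1e-10), k

    def test_ngtdm_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        levels = rng.integers(1, 5, size=(3, 4, 3)).astype(np.int32)
        ours = ngtdm_features(levels)
        oracle = _oracle_ngtdm(levels)
        for k, v in oracle.items():
            assert ours[k] == pytest.approx(v, rel=1e-10), k

    def test_uniform_roi_degenerate_conventions(self):
        arr = np.full((3, 3, 3), 2.5)
        fv = extract_features(_img(arr), _full_mask(arr.shape))
        assert fv["original_glcm_Idn"] == pytest.approx(1.0)
        assert fv["original_glcm_ClusterShade"] == pytest.approx(0.0)
        assert fv["original_glszm_ZoneEntropy"] == pytest.approx(0.0)
        assert fv["original_ngtdm_Strength"] == pytest.approx(0.0)

    def test_rotation_invariance_of_direction_averaged_textures(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(5, 5, 5))
        mask = np.zeros(arr.shape, dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[2, 2, 2] = False  # non-trivial shape
        fv0 = extract_features(_img(arr), _mask(mask))
        arr_r = np.rot90(arr, k=1, axes=(1, 2)).copy()
        mask_r = np.rot90(mask, k=1, axes=(1, 2)).copy()
        fv1 = extract_features(_img(arr_r), _mask(mask_r))
        for name in fv0.computed_mask:
            if "shape" in name:
                continue
            assert fv0[name] == pytest.approx(fv1[name], abs=1e-9), name


class TestFirstOrderAndShape:
    def test_kurtosis_and_skewness_moment_ratios(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 9.0])
        arr = vals.reshape(1, 1, 6)
        fv = extract_features(_img(arr), _full_mask(arr.shape))
        m = vals - vals.mean()
        m2, m3, m4 = (m ** 2).mean(), (m ** 3).mean(), (m ** 4).mean()
        assert fv["original_firstorder_Kurtosis"] == pytest.approx(m4 / m2 ** 2)
        assert fv["original_firstorder_Skewness"] == pytest.approx(m3 / m2 ** 1.5)
        assert fv["original_firstorder_Energy"] == pytest.approx((vals ** 2).sum())
        assert fv["original_firstorder_Range"] == pytest.approx(8.0)

    def test_voxel_volume_and_surface_of_cube(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:5, 1:5, 1:5] = True
        arr = np.random.default_rng(0).normal(size=(6, 6, 6))
        fv = extract_features(_img(arr), _mask(m))
        assert fv["original_shape_VoxelVolume"] == pytest.approx(64.0)
        assert fv["original_shape_SurfaceArea"] == pytest.approx(6 * 16.0)

    def test_single_voxel_roi_flags_textures_undefined(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        arr = np.random.default_rng(0).normal(size=(3, 3, 3))
        fv = extract_features(_img(arr), _mask(m))
        assert "original_glcm_Idn" in fv.undefined
        assert math.isnan(fv["original_glcm_Idn"])
        assert fv["original_firstorder_Mean"] == pytest.approx(arr[1, 1, 1])

    def test_empty_roi_rejected(self):
        arr = np.zeros((2, 2, 2))
        with pytest.raises(ValueError):
            MaskVolume(np.zeros((2, 2, 2), dtype=bool), role="gtv")
        brain = _mask(np.ones((2, 2, 2)), role="brain")
        with pytest.raises(ValueError):
            extract_features(_img(arr), brain.__class__(
                np.zeros((2, 2, 2), dtype=bool), role="brain"))

    def test_merge_external_fills_only_missing_names(self):
        arr = np.random.default_rng(1).normal(size=(3, 3, 3))
        fv = extract_features(_img(arr), _full_mask(arr.shape))
        native_mean = fv["original_firstorder_Mean"]
        merged = fv.merge_external({"original_glrlm_RunEntropy": 1.23,
                                    "original_firstorder_Mean": -99.0})
        assert merged["original_glrlm_RunEntropy"] == 1.23
        assert merged["original_firstorder_Mean"] == native_mean
        with pytest.raises(ValueError, match="unknown feature"):
            fv.merge_external({"not_a_feature": 0.0})

    def test_nifti_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        img = _img(rng.normal(size=(4, 5, 6)), spacing=(1.0, 1.0, 2.0))
        path = tmp_path / "vol.nii.gz"
        img.write(path)
        back = ImageVolume.read(path)
        np.testing.assert_allclose(back.voxels, img.voxels, atol=1e-6)
        assert back.spacing == pytest.approx(img.spacing)
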