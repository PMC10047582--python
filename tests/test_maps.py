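import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from perirec.features import FeatureConfig, VoxelFeatureExtractor, build_manifest
from perirec.features.filters import FilteredImage
from perirec.features.maps import voxelwise_feature_maps
from perirec.io import MaskVolume, VoxelGrid


def _fimg(data, modality="t1ce"):
    return FilteredImage(modality, "original",
                         VoxelGrid(np.asarray(data, float), np.eye(4)))


def _full_mask(shape):
    return MaskVolume(data=np.ones(shape, dtype=np.uint8))


class TestManifest:
    def test_firstorder_only_count(self):
        cfg = FeatureConfig(filters=("original",), families=("firstorder",))
        assert len(build_manifest(cfg)) == 5 * 19  # five modalities

    def test_full_family_block_is_94_per_modality_filter(self):
        cfg = FeatureConfig(filters=("original",),
                            families=("firstorder", "glcm", "glrlm", "glszm",
                                      "ngtdm", "gldm"))
        assert len(build_manifest(cfg)) == 5 * 94

    def test_filter_bank_expansion(self):
        cfg = FeatureConfig(filters=("original", "log", "wavelet", "lbp3d"),
                            families=("firstorder",))
        # 1 + 3 LoG scales + 8 wavelet bands + 1 LBP = 13 channels
        assert len(build_manifest(cfg)) == 5 * 13 * 19

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(families=("fractal",))


class TestVoxelwiseMaps:
    def test_mean_map_equals_box_filter(self, rng):
        """First-order mean map == normalized box filter (convolution oracle)."""
        data = rng.standard_normal((12, 12, 12))
        mask = np.zeros((12, 12, 12), dtype=np.uint8)
        mask[3:9, 3:9, 3:9] = 1
        df = voxelwise_feature_maps(_fimg(data), MaskVolume(data=mask),
                                    kernel_radius_vox=2)
        oracle = ndimage.uniform_filter(data, size=5, mode="constant")
        # interior voxels have full kernels; compare there
        got = df["t1ce|original|firstorder|mean"].to_numpy()
        idx = MaskVolume(data=mask).indices
        inner = (idx.min(axis=1) >= 5) & (idx.max(axis=1) <= 6)
        ref = oracle[tuple(idx[inner].T)]
        np.testing.assert_allclose(got[inner], ref, rtol=1e-6)

    def test_translation_equivariance(self, rng):
        data = rng.standard_normal((10, 10, 10))
        shifted = np.roll(data, 1, axis=0)
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask[4:6, 4:6, 4:6] = 1
        mask_shifted = np.roll(mask, 1, axis=0)
        a = voxelwise_feature_maps(_fimg(data), MaskVolume(data=mask),
                                   kernel_radius_vox=1)
        b = voxelwise_feature_maps(_fimg(shifted), MaskVolume(data=mask_shifted),
                                   kernel_radius_vox=1)
        np.testing.assert_allclose(a.to_numpy()[:, :-1].astype(float),
                                   b.to_numpy()[:, :-1].astype(float), atol=1e-12)

    def test_radius_zero_mean_is_identity(self, rng):
        data = rng.standard_normal((6, 6, 6))
        mask = _full_mask((6, 6, 6))
        df = voxelwise_feature_maps(_fimg(data), mask, kernel_radius_vox=0)
        np.testing.assert_allclose(df["t1ce|original|firstorder|mean"].to_numpy(),
                                   data[tuple(mask.indices.T)], rtol=1e-12)

    def test_texture_families_on_small_mask(self, rng):
        data = rng.standard_normal((9, 9, 9))
        mask = np.zeros((9, 9, 9), dtype=np.uint8)
        mask[4, 4, 4] = 1
        mask[4, 4, 5] = 1
        df = voxelwise_feature_maps(_fimg(data), MaskVolume(data=mask),
                                    kernel_radius_vox=2,
                                    families=("firstorder", "glcm", "ngtdm"))
        assert df.shape[0] == 2
        vals = df[[c for c in df.columns if "qc" not in c]].to_numpy()
        assert np.isfinite(vals.astype(float)).all()

    def test_small_support_flagged_in_qc(self, rng):
        data = rng.standard_normal((9, 9, 9))
        mask = np.zeros((9, 9, 9), dtype=np.uint8)
        mask[4, 4, 4] = 1
        support = MaskVolume(data=mask.copy())  # kernel sees only the center
        df = voxelwise_feature_maps(_fimg(data), MaskVolume(data=mask),
                                    support=support, kernel_radius_vox=2)
        assert bool(df["t1ce|original|qc_small_kernel"].iloc[0])


class TestExtractor:
    def test_row_count_and_labels(self, small_case):
        ext = VoxelFeatureExtractor(kernel_radius_vox=1).fit()
        df = ext.transform(small_case)
        assert len(df) == small_case.peritumor_mask.n_voxels
        assert set(df["label"].unique()) <= {0, 1}
        feature_cols = [c for c in df.columns if c not in ("label", "qc_small_kernel")]
        assert feature_cols == ext.manifest_
        assert np.isfinite(df[feature_cols].to_numpy()).all()

    def test_indices_subset_matches_full(self, small_case):
        ext = VoxelFeatureExtractor(kernel_radius_vox=1)
        full = ext.transform(small_case)
        sub_idx = small_case.peritumor_mask.indices[::500]
        sub = ext.transform(small_case, indices=sub_idx)
        pd.testing.assert_frame_equal(sub, full.iloc[::500])

    def test_missing_modality_error(self, small_case):
        from dataclasses import replace

        broken = replace(small_case)
        broken.modalities = {k: v for k, v in small_case.modalities.items()
                             if k != "adc"}
        with pytest.raises(ValueError, match="adc"):
            VoxelFeatureExtractor().transform(broken)

    def test_sklearn_params_round_trip(self):
        ext = VoxelFeatureExtractor(kernel_radius_vox=3, n_bins=8)
        params = ext.get_params()
        clone = VoxelFeatureExtractor(**params)
        assert clone.get_params() == params


class TestFeatureMapExport:
    def test_round_trip_feature_map(self, tmp_path, small_case):
        from perirec.features.maps import export_feature_map
        from perirec.io import read_volume

        ext = VoxelFeatureExtractor(kernel_radius_vox=1).fit()
        idx = small_case.peritumor_mask.indices[::50]
        df = ext.transform(small_case, indices=idx)
        col = "t1ce|original|firstorder|mean"
        path = tmp_path / "mean_map.nii.gz"
        export_feature_map(df, col, small_case.peritumor_mask, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.data[tuple(idx.T)],
                                   df[col].to_numpy(), rtol=1e-6)
        assert back.data.sum() == pytest.approx(df[col].sum(), rel=1e-5)
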