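"""Voxelwise feature-map extraction over the peritumoral support.

For every peritumoral voxel, features are computed on the cubic kernel of
edge ``2r + 1`` centered there, intersected with the brain support.  First-
order maps run fully vectorized over all kernels at once; texture families
fall back to a per-voxel loop over patches.  Results are independent of voxel
execution order by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from ..io import MaskVolume
from ..labeling import derive_labels
from ..phantom import CaseBundle
from .filters import FilteredImage, filter_bank
from .firstorder import FIRST_ORDER_NAMES, discretize, first_order_features_batch
from .manifest import FeatureConfig, build_manifest, family_feature_names
from .texture import texture_features_of_patch

QC_COLUMN = "qc_small_kernel"
MIN_KERNEL_VOXELS = 8


def _gather_windows(data: np.ndarray, support: np.ndarray, idx: np.ndarray,
                    radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Kernel neighbourhoods at ``idx`` as (n, k^3) values and validity masks."""
    k = 2 * radius + 1
    pad = [(radius, radius)] * 3
    dpad = np.pad(data.astype(np.float64), pad, mode="constant")
    spad = np.pad(support.astype(bool), pad, mode="constant")
    dview = sliding_window_view(dpad, (k, k, k))
    sview = sliding_window_view(spad, (k, k, k))
    ix, iy, iz = idx.T
    vals = dview[ix, iy, iz].reshape(len(idx), -1)
    valid = sview[ix, iy, iz].reshape(len(idx), -1)
    return vals, valid


def voxelwise_feature_maps(filtered: FilteredImage, mask: MaskVolume,
                           support: MaskVolume | None = None,
                           kernel_radius_vox: int = 2,
                           families: tuple[str, ...] = ("firstorder",),
                           n_bins: int = 16,
                           indices: np.ndarray | None = None) -> pd.DataFrame:
    """Feature columns of one filtered channel over the mask's voxels.

    Kernels with fewer than ``MIN_KERNEL_VOXELS`` in-support voxels are still
    computed on what is available and flagged in the QC column.
    """
    grid = filtered.grid
    if mask.n_voxels == 0:
        raise ValueError("empty extraction mask")
    if min(grid.shape) < 2 * kernel_radius_vox + 1:
        raise ValueError("kernel does not fit in the grid")
    sup = np.ones(grid.shape, bool) if support is None else support.data.astype(bool)
    idx = mask.indices if indices is None else np.asarray(indices)
    vals, valid = _gather_windows(grid.data, sup, idx, kernel_radius_vox)
    # the center voxel always participates, whatever the support says
    center = vals.shape[1] // 2
    valid[:, center] = True
    n_valid = valid.sum(axis=1)

    voxvol = float(np.prod(grid.spacing_mm))
    columns: dict[str, np.ndarray] = {}
    prefix = f"{filtered.source_modality}|{filtered.filter_id}"

    if "firstorder" in families:
        full = n_valid == vals.shape[1]
        feats = np.empty((len(idx), len(FIRST_ORDER_NAMES)))
        if full.any():
            feats[full] = first_order_features_batch(vals[full], n_bins=n_bins,
                                                     voxel_volume_mm3=voxvol)
        for r in np.nonzero(~full)[0]:
            feats[r] = first_order_features_batch(
                vals[r, valid[r]][np.newaxis, :], n_bins=n_bins,
                voxel_volume_mm3=voxvol)[0]
        for j, name in enumerate(FIRST_ORDER_NAMES):
            columns[f"{prefix}|firstorder|{name}"] = feats[:, j]

    texture_fams = [f for f in families if f != "firstorder"]
    if texture_fams:
        k = 2 * kernel_radius_vox + 1
        shape3 = (k, k, k)
        fam_names = {f: family_feature_names(f) for f in texture_fams}
        buf = {f: np.empty((len(idx), len(fam_names[f]))) for f in texture_fams}
        for r in range(len(idx)):
            v = vals[r]
            m3 = valid[r].reshape(shape3)
            levels = np.ones(v.shape, dtype=np.int64)
            levels[valid[r]] = discretize(v[valid[r]], n_bins=n_bins)
            levels3 = levels.reshape(shape3)
            for fam in texture_fams:
                feats = texture_features_of_patch(levels3, fam, n_bins, mask=m3)
                buf[fam][r] = [feats[n] for n in fam_names[fam]]
        for fam in texture_fams:
            for j, name in enumerate(fam_names[fam]):
                columns[f"{prefix}|{fam}|{name}"] = buf[fam][:, j]

    df = pd.DataFrame(columns, index=pd.RangeIndex(len(idx)))
    df[f"{prefix}|{QC_COLUMN}"] = n_valid < MIN_KERNEL_VOXELS
    return df


class VoxelFeatureExtractor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: CaseBundle(s) -> voxel x feature DataFrame.

    ``transform`` returns one row per peritumoral voxel, indexed by
    ``(case_id, i, j, k)``, with a ``label`` column attached when the case
    carries a follow-up mask.  Stateless (``fit`` is a no-op) but fitted
    metadata (``manifest_``, ``n_features_``) is recorded for inspection.
    """

    def __init__(self, kernel_radius_vox: int = 2,
                 filters: tuple[str, ...] = ("original",),
                 log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0),
                 wavelet: str = "haar",
                 families: tuple[str, ...] = ("firstorder",),
                 n_bins: int = 16):
        self.kernel_radius_vox = kernel_radius_vox
        self.filters = filters
        self.log_sigmas_mm = log_sigmas_mm
        self.wavelet = wavelet
        self.families = families
        self.n_bins = n_bins

    def _config(self) -> FeatureConfig:
        return FeatureConfig(kernel_radius_vox=self.kernel_radius_vox,
                             filters=tuple(self.filters),
                             log_sigmas_mm=tuple(self.log_sigmas_mm),
                             wavelet=self.wavelet, families=tuple(self.families),
                             n_bins=self.n_bins)

    def fit(self, X=None, y=None):
        self.manifest_ = build_manifest(self._config())
        self.n_features_ = len(self.manifest_)
        return self

    def transform(self, X, indices: np.ndarray | None = None) -> pd.DataFrame:
        """Extract features; ``indices`` optionally restricts extraction to a
        subset of peritumoral voxels (single-case input only)."""
        bundles = [X] if isinstance(X, CaseBundle) else list(X)
        if indices is not None and len(bundles) != 1:
            raise ValueError("indices subsetting requires a single case")
        self.fit()
        return pd.concat([self._transform_case(b, indices) for b in bundles], axis=0)

    def _transform_case(self, bundle: CaseBundle,
                        indices: np.ndarray | None = None) -> pd.DataFrame:
        config = self._config()
        missing = [m for m in config.modalities if m not in bundle.modalities]
        if missing:
            raise ValueError(f"case {bundle.case_id!r}: missing modalities {missing}")
        mask = bundle.peritumor_mask
        idx = mask.indices if indices is None else np.asarray(indices)
        parts = []
        for mod in config.modalities:
            for fimg in filter_bank(bundle.modalities[mod], mod,
                                    filters=tuple(config.filters),
                                    log_sigmas_mm=tuple(config.log_sigmas_mm),
                                    wavelet=config.wavelet):
                parts.append(voxelwise_feature_maps(
                    fimg, mask, support=bundle.brain_mask,
                    kernel_radius_vox=config.kernel_radius_vox,
                    families=tuple(config.families), n_bins=config.n_bins,
                    indices=idx))
        df = pd.concat(parts, axis=1)
        qc_cols = [c for c in df.columns if c.endswith(QC_COLUMN)]
        qc = df[qc_cols].any(axis=1)
        df = df[self.manifest_].astype(np.float32)
        if not np.isfinite(df.to_numpy()).all():
            raise ValueError(f"non-finite feature values in case {bundle.case_id!r}")
        df[QC_COLUMN] = qc.to_numpy()
        df.index = pd.MultiIndex.from_arrays(
            [np.repeat(bundle.case_id, len(idx)), idx[:, 0], idx[:, 1], idx[:, 2]],
            names=("case_id", "i", "j", "k"))
        if bundle.followup_enhancing_mask is not None:
            labels = derive_labels(bundle.peritumor_mask, bundle.followup_enhancing_mask)
            df["label"] = labels.labels_at(idx)
        return df


def export_feature_map(table: pd.DataFrame, column: str, mask: MaskVolume,
                       path) -> None:
    """Write one feature column of a single-case table as a NIfTI map
    (zero outside the peritumor) for visual inspection."""
    from ..io import VoxelGrid, write_volume

    case_ids = table.index.get_level_values("case_id").unique()
    if len(case_ids) != 1:
        raise ValueError("feature-map export expects a single-case table")
    vol = np.zeros(mask.shape, dtype=np.float32)
    idx = np.asarray([table.index.get_level_values(a) for a in ("i", "j", "k")]).T
    vol[tuple(idx.T)] = table[column].to_numpy(dtype=np.float32)
    write_volume(VoxelGrid(vol, mask.affine.copy()), path)


def build_feature_table(bundle_or_bundles, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`VoxelFeatureExtractor`."""
    config = config or FeatureConfig()
    ext = VoxelFeatureExtractor(kernel_radius_vox=config.kernel_radius_vox,
                                filters=config.filters,
                                log_sigmas_mm=config.log_sigmas_mm,
                                wavelet=config.wavelet, families=config.families,
                                n_bins=config.n_bins)
    return ext.fit().transform(bundle_or_bundles)
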