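"""First-order (intensity statistics) features, scalar and batched.

The 19 features follow the standard radiomics definitions: entropy and
uniformity are computed on intensities discretized into equal-width bins over
the kernel's own range; everything else uses the raw values.  Population
moments (``ddof=0``) are used throughout.  The batched path computes all
features for thousands of kernels at once and is the workhorse of voxelwise
feature maps.
"""

from __future__ import annotations

import numpy as np

FIRST_ORDER_NAMES = (
    "energy", "total_energy", "entropy", "minimum", "percentile10",
    "percentile90", "maximum", "mean", "median", "interquartile_range",
    "range", "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "root_mean_squared", "skewness", "kurtosis", "variance", "uniformity",
    "standard_deviation",
)


def discretize(values: np.ndarray, n_bins: int = 16) -> np.ndarray:
    """Equal-width discretization into integer levels 1..n_bins.

    The bin width spans the range of ``values`` itself; a constant input maps
    to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    levels = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(levels, 1, n_bins)


def _histogram_probs(levels: np.ndarray, n_bins: int) -> np.ndarray:
    counts = np.bincount(levels - 1, minlength=n_bins).astype(np.float64)
    return counts / counts.sum()


def first_order_features(values, n_bins: int = 16,
                         voxel_volume_mm3: float = 1.0) -> dict[str, float]:
    """The 19 first-order features of one kernel's intensity sample."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty intensity sample")
    out = first_order_features_batch(x[np.newaxis, :], n_bins=n_bins,
                                     voxel_volume_mm3=voxel_volume_mm3)
    return dict(zip(FIRST_ORDER_NAMES, out[0]))


def first_order_features_batch(windows: np.ndarray, n_bins: int = 16,
                               voxel_volume_mm3: float = 1.0) -> np.ndarray:
    """Features for many kernels at once: (n_kernels, k) -> (n_kernels, 19).

    Skewness and kurtosis of a zero-variance sample are defined as 0.
    """
    x = np.asarray(windows, dtype=np.float64)
    n = x.shape[1]
    srt = np.sort(x, axis=1)
    constant = srt[:, 0] == srt[:, -1]
    mean = x.mean(axis=1)
    dev = x - mean[:, None]
    d2 = dev * dev
    m2 = d2.mean(axis=1)
    m2[constant] = 0.0  # exact zero variance for constant kernels
    m3 = np.einsum("ij,ij->i", d2, dev) / n
    m4 = np.einsum("ij,ij->i", d2, d2) / n
    sd = np.sqrt(m2)

    def pct(q):
        # linear-interpolation percentile on the pre-sorted rows
        pos = q / 100.0 * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return srt[:, lo] * (1 - frac) + srt[:, hi] * frac

    p10, p25, p50, p75, p90 = (pct(q) for q in (10, 25, 50, 75, 90))
    energy = np.einsum("ij,ij->i", x, x)
    mad = np.abs(dev).mean(axis=1)

    # robust MAD on the sorted rows: values in [p10, p90] form a contiguous slice
    inside = (srt >= p10[:, None]) & (srt <= p90[:, None])
    cnt = inside.sum(axis=1)
    safe_cnt = np.maximum(cnt, 1)
    rmean = np.einsum("ij,ij->i", srt, inside) / safe_cnt
    rmad = np.einsum("ij,ij->i", np.abs(srt - rmean[:, None]), inside) / safe_cnt
    rmad[cnt == 0] = 0.0

    denom = np.where(m2 > 0, m2, 1.0)
    skew = np.where(m2 > 0, m3 / (denom * np.sqrt(denom)), 0.0)
    kurt = np.where(m2 > 0, m4 / (denom * denom), 0.0)

    # histogram features on per-kernel equal-width levels
    lo = srt[:, 0]
    hi = srt[:, -1]
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    levels = ((x - lo[:, None]) * (n_bins / safe)[:, None]).astype(np.int64)
    np.clip(levels, 0, n_bins - 1, out=levels)
    levels[span == 0] = 0
    levels += (np.arange(x.shape[0]) * n_bins)[:, None]
    counts = np.bincount(levels.ravel(), minlength=x.shape[0] * n_bins)
    p = counts.reshape(x.shape[0], n_bins).astype(np.float64) / n
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    entropy = -(p * logp).sum(axis=1)
    uniformity = (p ** 2).sum(axis=1)

    feats = np.column_stack([
        energy, energy * voxel_volume_mm3, entropy, srt[:, 0], p10, p90,
        srt[:, -1], mean, p50, p75 - p25, hi - lo, mad, rmad,
        np.sqrt(energy / n), skew, kurt, m2, uniformity, sd,
    ])
    return feats
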