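"""Gray-level texture matrices and their features (GLCM, GLRLM, GLSZM, NGTDM, GLDM).

All five families operate on a 3D patch of integer gray levels in
``1..n_bins`` (see :func:`..firstorder.discretize`) with an optional binary
mask restricting the support.  Conventions:

* GLCM and GLRLM use the 13 unique 3D directions at distance 1; features are
  computed per direction and averaged ("averaged" aggregation).
* GLSZM zones, NGTDM neighbourhoods and GLDM dependencies use 26-connectivity
  at distance 1.
* Degenerate matrices (a single entry) yield the analytic limits of each
  feature, never NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")

#: 13 unique displacement vectors covering all 26 neighbours up to sign.
DIRECTIONS = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

GLCM_NAMES = (
    "autocorrelation", "cluster_prominence", "cluster_shade", "cluster_tendency",
    "contrast", "correlation", "difference_average", "difference_entropy",
    "difference_variance", "inverse_difference", "inverse_difference_moment",
    "idmn", "idn", "imc1", "imc2", "inverse_variance", "joint_average",
    "joint_energy", "joint_entropy", "maximum_probability", "mcc",
    "sum_average", "sum_entropy", "sum_squares",
)
GLRLM_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
)
GLSZM_NAMES = (
    "small_area_emphasis", "large_area_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
)
NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")
GLDM_NAMES = (
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_nonuniformity", "dependence_nonuniformity",
    "dependence_nonuniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy", "low_gray_level_emphasis",
    "high_gray_level_emphasis", "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)

FAMILY_FEATURE_NAMES = {
    "glcm": GLCM_NAMES, "glrlm": GLRLM_NAMES, "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES, "gldm": GLDM_NAMES,
}


def _check_patch(levels: np.ndarray, n_bins: int, mask):
    levels = np.asarray(levels)
    if levels.ndim != 3:
        raise ValueError("patch must be 3D")
    mask = np.ones(levels.shape, bool) if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty patch")
    inside = levels[mask]
    if inside.min() < 1 or inside.max() > n_bins:
        raise ValueError("levels must lie in 1..n_bins")
    return levels.astype(np.int64), mask


# ---------------------------------------------------------------- matrices

def glcm_matrix(levels, n_bins, mask=None) -> np.ndarray:
    """Symmetric co-occurrence counts, shape (n_bins, n_bins, 13)."""
    levels, mask = _check_patch(levels, n_bins, mask)
    out = np.zeros((n_bins, n_bins, len(DIRECTIONS)))
    for k, d in enumerate(DIRECTIONS):
        src = tuple(slice(max(0, -di), levels.shape[a] - max(0, di))
                    for a, di in enumerate(d))
        dst = tuple(slice(max(0, di), levels.shape[a] + min(0, di))
                    for a, di in enumerate(d))
        valid = mask[src] & mask[dst]
        i = levels[src][valid] - 1
        j = levels[dst][valid] - 1
        np.add.at(out[:, :, k], (i, j), 1.0)
        np.add.at(out[:, :, k], (j, i), 1.0)
    return out


def glrlm_matrix(levels, n_bins, mask=None) -> np.ndarray:
    """Run-length counts, shape (n_bins, max_run, 13); mask gaps break runs."""
    levels, mask = _check_patch(levels, n_bins, mask)
    shape = levels.shape
    max_run = int(np.ceil(np.linalg.norm(shape))) + 1
    out = np.zeros((n_bins, max_run, len(DIRECTIONS)))
    idx = np.argwhere(np.ones(shape, bool))
    for k, d in enumerate(DIRECTIONS):
        d = np.asarray(d)
        prev = idx - d
        starts = idx[~((prev >= 0).all(1) & (prev < shape).all(1))]
        for s in starts:
            pos = s.copy()
            run_level, run_len = None, 0
            while (pos >= 0).all() and (pos < shape).all():
                p = tuple(pos)
                if mask[p]:
                    lev = levels[p]
                    if lev == run_level:
                        run_len += 1
                    else:
                        if run_level is not None:
                            out[run_level - 1, run_len - 1, k] += 1
                        run_level, run_len = lev, 1
                else:
                    if run_level is not None:
                        out[run_level - 1, run_len - 1, k] += 1
                    run_level, run_len = None, 0
                pos += d
            if run_level is not None:
                out[run_level - 1, run_len - 1, k] += 1
    return out


def glszm_matrix(levels, n_bins, mask=None) -> np.ndarray:
    """Zone-size counts (26-connected zones), shape (n_bins, max_zone_size)."""
    levels, mask = _check_patch(levels, n_bins, mask)
    max_size = int(mask.sum())
    out = np.zeros((n_bins, max_size))
    for lev in np.unique(levels[mask]):
        lab, n = ndimage.label((levels == lev) & mask, structure=_STRUCT26)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            for s in sizes:
                out[lev - 1, s - 1] += 1
    return out


def _neighbor_sums(levels, mask):
    """26-neighbour level sums and counts within the mask."""
    kern = _STRUCT26.astype(float).copy()
    kern[1, 1, 1] = 0.0
    s = ndimage.correlate((levels * mask).astype(float), kern, mode="constant")
    c = ndimage.correlate(mask.astype(float), kern, mode="constant")
    return s, c


def ngtdm_matrix(levels, n_bins, mask=None) -> np.ndarray:
    """Rows (n_i, p_i, s_i) per gray level, shape (n_bins, 3).

    ``s_i`` sums |level - mean of valid 26-neighbours| over voxels of level i
    that have at least one in-mask neighbour.
    """
    levels, mask = _check_patch(levels, n_bins, mask)
    s, c = _neighbor_sums(levels, mask)
    valid = mask & (c > 0)
    nvp = valid.sum()
    out = np.zeros((n_bins, 3))
    if nvp == 0:
        return out
    avg = np.zeros_like(s)
    avg[valid] = s[valid] / c[valid]
    diff = np.abs(levels - avg)
    for lev in range(1, n_bins + 1):
        sel = valid & (levels == lev)
        out[lev - 1, 0] = sel.sum()
        out[lev - 1, 2] = diff[sel].sum()
    out[:, 1] = out[:, 0] / nvp
    return out


def gldm_matrix(levels, n_bins, mask=None, alpha: int = 0) -> np.ndarray:
    """Dependence counts, shape (n_bins, 27): D[i, j-1] voxels of level i with
    dependence j = 1 + #{26-neighbours with |level difference| <= alpha}."""
    levels, mask = _check_patch(levels, n_bins, mask)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS:
        for sign in (1, -1):
            dd = tuple(sign * x for x in d)
            src = tuple(slice(max(0, -di), levels.shape[a] - max(0, di))
                        for a, di in enumerate(dd))
            dst = tuple(slice(max(0, di), levels.shape[a] + min(0, di))
                        for a, di in enumerate(dd))
            hit = mask[src] & mask[dst] & (np.abs(levels[src] - levels[dst]) <= alpha)
            dep[src] += hit
    out = np.zeros((n_bins, 27))
    i = levels[mask] - 1
    j = dep[mask]  # dependence size j+1, stored at column j
    np.add.at(out, (i, j), 1.0)
    return out


def texture_matrix(levels, family: str, n_bins: int, mask=None, **params):
    """Dispatch to the family's matrix builder."""
    builders = {"glcm": glcm_matrix, "glrlm": glrlm_matrix, "glszm": glszm_matrix,
                "ngtdm": ngtdm_matrix, "gldm": gldm_matrix}
    if family not in builders:
        raise ValueError(f"unknown texture family {family!r}")
    return builders[family](levels, n_bins, mask, **params)


# ---------------------------------------------------------------- features

def _safe_log2(p):
    return np.log2(p, out=np.zeros_like(p), where=p > 0)


def glcm_features_single(counts: np.ndarray) -> np.ndarray:
    """The 24 co-occurrence features of one direction's count matrix."""
    total = counts.sum()
    if total == 0:
        return np.full(len(GLCM_NAMES), np.nan)
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    var_x = ((i - mu_x) ** 2 * px).sum()
    var_y = ((i - mu_y) ** 2 * py).sum()

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    autocorr = (ii * jj * p).sum()
    cterm = ii + jj - mu_x - mu_y
    contrast = ((ii - jj) ** 2 * p).sum()
    corr = 1.0 if var_x * var_y == 0 else (autocorr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    da = (k_diff * p_diff).sum()
    dent = -(p_diff * _safe_log2(p_diff)).sum()
    dvar = ((k_diff - da) ** 2 * p_diff).sum()
    idc = (p / (1 + np.abs(ii - jj))).sum()
    idm = (p / (1 + (ii - jj) ** 2)).sum()
    idmn = (p / (1 + ((ii - jj) / ng) ** 2)).sum()
    idn = (p / (1 + np.abs(ii - jj) / ng)).sum()
    hxy = -(p * _safe_log2(p)).sum()
    pxy = px[:, None] * py[None, :]
    hxy1 = -(p * _safe_log2(pxy)).sum()
    hxy2 = -(pxy * _safe_log2(pxy)).sum()
    hx = -(px * _safe_log2(px)).sum()
    hy = -(py * _safe_log2(py)).sum()
    div = max(hx, hy)
    imc1 = 0.0 if div == 0 else (hxy - hxy1) / div
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    off = np.abs(ii - jj) > 0
    inv_var = (p[off] / (ii - jj)[off] ** 2).sum()
    joint_energy = (p ** 2).sum()
    max_prob = p.max()

    nz = px > 0
    if nz.sum() <= 1:
        mcc = 1.0
    else:
        q = np.zeros((ng, ng))
        pk = p[:, nz]
        denom = px[:, None] * py[None, nz]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), 0.0)
        # Q(a,b) = sum_k p(a,k) p(b,k) / (px(a) py(k))
        q = (pk[:, None, :] * pk[None, :, :] * w[:, None, :]).sum(axis=2)
        eig = np.sort(np.linalg.eigvals(q).real)
        mcc = np.sqrt(max(0.0, eig[-2])) if len(eig) >= 2 else 1.0

    sa = (k_sum * p_sum).sum()
    sent = -(p_sum * _safe_log2(p_sum)).sum()
    ssq = (((ii - mu_x) ** 2) * p).sum()

    return np.array([
        autocorr, (cterm ** 4 * p).sum(), (cterm ** 3 * p).sum(),
        (cterm ** 2 * p).sum(), contrast, corr, da, dent, dvar, idc, idm,
        idmn, idn, imc1, imc2, inv_var, mu_x, joint_energy, hxy, max_prob,
        mcc, sa, sent, ssq,
    ])


def _rlm_style_features(mat: np.ndarray, n_voxels: int, names, axis1_is_size: bool):
    """Shared form of GLRLM/GLSZM features: rows = gray level, cols = run/zone size."""
    total = mat.sum()
    if total == 0:
        return dict(zip(names, [0.0] * len(names)))
    ng, nl = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    l = np.arange(1, nl + 1)[None, :]
    p = mat / total
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    mu_i = (i * p).sum()
    mu_l = (l * p).sum()
    vals = {
        names[0]: (mat / l ** 2).sum() / total,
        names[1]: (mat * l ** 2).sum() / total,
        names[2]: (row ** 2).sum() / total,
        names[3]: (row ** 2).sum() / total ** 2,
        names[4]: (col ** 2).sum() / total,
        names[5]: (col ** 2).sum() / total ** 2,
        names[6]: total / n_voxels,
        names[7]: (((i - mu_i) ** 2) * p).sum(),
        names[8]: (((l - mu_l) ** 2) * p).sum(),
        names[9]: -(p * _safe_log2(p)).sum(),
        names[10]: (mat / i ** 2).sum() / total,
        names[11]: (mat * i ** 2).sum() / total,
        names[12]: (mat / (i ** 2 * l ** 2)).sum() / total,
        names[13]: (mat * i ** 2 / l ** 2).sum() / total,
        names[14]: (mat * l ** 2 / i ** 2).sum() / total,
        names[15]: (mat * i ** 2 * l ** 2).sum() / total,
    }
    return vals


def ngtdm_features(mat: np.ndarray) -> dict[str, float]:
    n_i, p_i, s_i = mat[:, 0], mat[:, 1], mat[:, 2]
    nvp = n_i.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)
    nz = p_i > 0
    ngp = int(nz.sum())
    sum_ps = (p_i * s_i).sum()
    coarseness = 1e6 if sum_ps == 0 else 1.0 / sum_ps
    if ngp <= 1 or nvp == 0:
        contrast = 0.0
    else:
        pij = p_i[nz][:, None] * p_i[nz][None, :]
        dij2 = (i[nz][:, None] - i[nz][None, :]) ** 2
        contrast = (pij * dij2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / nvp)
    denom = np.abs(i[nz][:, None] * p_i[nz][:, None]
                   - i[nz][None, :] * p_i[nz][None, :]).sum()
    busyness = 0.0 if denom == 0 else sum_ps / denom
    if nvp == 0:
        complexity = 0.0
    else:
        pi, si, iv = p_i[nz], s_i[nz], i[nz]
        num = (np.abs(iv[:, None] - iv[None, :])
               * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
               / (pi[:, None] + pi[None, :]))
        complexity = num.sum() / nvp
    ssum = s_i.sum()
    if ssum == 0:
        strength = 0.0
    else:
        pi, iv = p_i[nz], i[nz]
        strength = ((pi[:, None] + pi[None, :])
                    * (iv[:, None] - iv[None, :]) ** 2).sum() / ssum
    return dict(zip(NGTDM_NAMES, (coarseness, contrast, busyness, complexity, strength)))


def gldm_features(mat: np.ndarray) -> dict[str, float]:
    total = mat.sum()
    if total == 0:
        return dict(zip(GLDM_NAMES, [0.0] * len(GLDM_NAMES)))
    ng, nd = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    p = mat / total
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    vals = (
        (mat / j ** 2).sum() / total,
        (mat * j ** 2).sum() / total,
        (row ** 2).sum() / total,
        (col ** 2).sum() / total,
        (col ** 2).sum() / total ** 2,
        (((i - mu_i) ** 2) * p).sum(),
        (((j - mu_j) ** 2) * p).sum(),
        -(p * _safe_log2(p)).sum(),
        (mat / i ** 2).sum() / total,
        (mat * i ** 2).sum() / total,
        (mat / (i ** 2 * j ** 2)).sum() / total,
        (mat * i ** 2 / j ** 2).sum() / total,
        (mat * j ** 2 / i ** 2).sum() / total,
        (mat * i ** 2 * j ** 2).sum() / total,
    )
    return dict(zip(GLDM_NAMES, vals))


def texture_features(matrix, family: str, n_voxels: int | None = None) -> dict[str, float]:
    """Features of a prebuilt matrix.

    ``n_voxels`` (patch support size) is required for GLRLM run percentage and
    GLSZM zone percentage; directional families accept a stacked
    (..., n_directions) matrix and average features over directions.
    """
    if family == "glcm":
        feats = [glcm_features_single(matrix[:, :, k])
                 for k in range(matrix.shape[2]) if matrix[:, :, k].sum() > 0]
        if not feats:
            raise ValueError("degenerate GLCM: no co-occurring pairs")
        return dict(zip(GLCM_NAMES, np.mean(feats, axis=0)))
    if family == "glrlm":
        if n_voxels is None:
            raise ValueError("GLRLM features need n_voxels")
        per_dir = [_rlm_style_features(matrix[:, :, k], n_voxels, GLRLM_NAMES, False)
                   for k in range(matrix.shape[2]) if matrix[:, :, k].sum() > 0]
        if not per_dir:
            raise ValueError("degenerate GLRLM")
        return {n: float(np.mean([d[n] for d in per_dir])) for n in GLRLM_NAMES}
    if family == "glszm":
        if n_voxels is None:
            raise ValueError("GLSZM features need n_voxels")
        return {k: float(v) for k, v in
                _rlm_style_features(matrix, n_voxels, GLSZM_NAMES, True).items()}
    if family == "ngtdm":
        return {k: float(v) for k, v in ngtdm_features(matrix).items()}
    if family == "gldm":
        return {k: float(v) for k, v in gldm_features(matrix).items()}
    raise ValueError(f"unknown texture family {family!r}")


def texture_features_of_patch(levels, family: str, n_bins: int,
                              mask=None, **params) -> dict[str, float]:
    """Matrix construction + feature computation for one patch.

    A patch too small to form any co-occurring pair takes the constant-patch
    limit of the GLCM (a single diagonal entry at its gray level).
    """
    levels, mask = _check_patch(levels, n_bins, mask)
    mat = texture_matrix(levels, family, n_bins, mask=mask, **params)
    if family == "glcm" and mat.sum() == 0:
        lev = int(levels[mask].min())
        mat[lev - 1, lev - 1, 0] = 1.0
    return texture_features(mat, family, n_voxels=int(mask.sum()))
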