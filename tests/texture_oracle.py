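"""Naive brute-force oracles for texture matrices/features and Otsu.

Everything here is written as literal enumeration — nested Python loops,
explicit flood fill, exhaustive threshold search — deliberately independent
of the vectorized implementations it checks.
"""

import math

import numpy as np

OFFSETS_13 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) > (0, 0, 0)]
OFFSETS_26 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) != (0, 0, 0)]


def _in_bounds(p, shape):
    return all(0 <= p[a] < shape[a] for a in range(3))


def glcm_counts(levels, n_bins, mask):
    shape = levels.shape
    out = np.zeros((n_bins, n_bins, len(OFFSETS_13)))
    for k, d in enumerate(OFFSETS_13):
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    q = (x + d[0], y + d[1], z + d[2])
                    if mask[x, y, z] and _in_bounds(q, shape) and mask[q]:
                        i, j = levels[x, y, z] - 1, levels[q] - 1
                        out[i, j, k] += 1
                        out[j, i, k] += 1
    return out


def glcm_features(counts):
    """Literal-formula co-occurrence features of one direction's counts."""
    p = counts / counts.sum()
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))
    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]

    def ent(probs):
        return -sum(q * math.log2(q) for q in probs if q > 0)

    autoc = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    f = {}
    f["autocorrelation"] = autoc
    for power, name in ((4, "cluster_prominence"), (3, "cluster_shade"),
                        (2, "cluster_tendency")):
        f[name] = sum((i + 1 + j + 1 - mu_x - mu_y) ** power * p[i, j]
                      for i in range(ng) for j in range(ng))
    f["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    f["correlation"] = (1.0 if var_x * var_y == 0
                        else (autoc - mu_x * mu_y) / math.sqrt(var_x * var_y))
    da = sum(k * v for k, v in pdiff.items())
    f["difference_average"] = da
    f["difference_entropy"] = ent(pdiff.values())
    f["difference_variance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    f["inverse_difference"] = sum(p[i, j] / (1 + abs(i - j))
                                  for i in range(ng) for j in range(ng))
    f["inverse_difference_moment"] = sum(p[i, j] / (1 + (i - j) ** 2)
                                         for i in range(ng) for j in range(ng))
    f["idmn"] = sum(p[i, j] / (1 + ((i - j) / ng) ** 2)
                    for i in range(ng) for j in range(ng))
    f["idn"] = sum(p[i, j] / (1 + abs(i - j) / ng)
                   for i in range(ng) for j in range(ng))
    hxy = ent(p.ravel())
    hxy1 = -sum(p[i, j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if p[i, j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if px[i] * py[j] > 0)
    hx, hy = ent(px), ent(py)
    f["imc1"] = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    f["imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    f["inverse_variance"] = sum(p[i, j] / (i - j) ** 2
                                for i in range(ng) for j in range(ng) if i != j)
    f["joint_average"] = mu_x
    f["joint_energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["joint_entropy"] = hxy
    f["maximum_probability"] = p.max()
    nz = [i for i in range(ng) if px[i] > 0]
    if len(nz) <= 1:
        f["mcc"] = 1.0
    else:
        q = np.zeros((ng, ng))
        for a in range(ng):
            for b in range(ng):
                q[a, b] = sum(p[a, k] * p[b, k] / (px[a] * py[k])
                              for k in range(ng) if px[a] > 0 and py[k] > 0)
        eig = sorted(np.linalg.eigvals(q).real)
        f["mcc"] = math.sqrt(max(0.0, eig[-2]))
    f["sum_average"] = sum(k * v for k, v in psum.items())
    f["sum_entropy"] = ent(psum.values())
    f["sum_squares"] = sum((i + 1 - mu_x) ** 2 * p[i, j]
                           for i in range(ng) for j in range(ng))
    return f


def glrlm_counts(levels, n_bins, mask):
    shape = levels.shape
    max_run = int(np.ceil(np.linalg.norm(shape))) + 1
    out = np.zeros((n_bins, max_run, len(OFFSETS_13)))
    for k, d in enumerate(OFFSETS_13):
        seen = set()
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _in_bounds(prev, shape):
                        continue  # not a line start
                    line = []
                    p = (x, y, z)
                    while _in_bounds(p, shape):
                        line.append(p)
                        p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                    run_level, run_len = None, 0
                    for p in line:
                        if mask[p]:
                            if levels[p] == run_level:
                                run_len += 1
                            else:
                                if run_level is not None:
                                    out[run_level - 1, run_len - 1, k] += 1
                                run_level, run_len = levels[p], 1
                        else:
                            if run_level is not None:
                                out[run_level - 1, run_len - 1, k] += 1
                            run_level, run_len = None, 0
                    if run_level is not None:
                        out[run_level - 1, run_len - 1, k] += 1
    return out


def rlm_features(mat, n_voxels, names):
    ng, nl = mat.shape
    total = mat.sum()
    p = mat / total
    mu_i = sum((i + 1) * p[i, l] for i in range(ng) for l in range(nl))
    mu_l = sum((l + 1) * p[i, l] for i in range(ng) for l in range(nl))
    s = lambda fn: sum(fn(i + 1, l + 1, mat[i, l])
                       for i in range(ng) for l in range(nl) if mat[i, l] > 0)
    f = {}
    f[names[0]] = s(lambda i, l, v: v / l ** 2) / total
    f[names[1]] = s(lambda i, l, v: v * l ** 2) / total
    f[names[2]] = sum(mat[i, :].sum() ** 2 for i in range(ng)) / total
    f[names[3]] = sum(mat[i, :].sum() ** 2 for i in range(ng)) / total ** 2
    f[names[4]] = sum(mat[:, l].sum() ** 2 for l in range(nl)) / total
    f[names[5]] = sum(mat[:, l].sum() ** 2 for l in range(nl)) / total ** 2
    f[names[6]] = total / n_voxels
    f[names[7]] = s(lambda i, l, v: (i - mu_i) ** 2 * v / total)
    f[names[8]] = s(lambda i, l, v: (l - mu_l) ** 2 * v / total)
    f[names[9]] = -s(lambda i, l, v: (v / total) * math.log2(v / total))
    f[names[10]] = s(lambda i, l, v: v / i ** 2) / total
    f[names[11]] = s(lambda i, l, v: v * i ** 2) / total
    f[names[12]] = s(lambda i, l, v: v / (i ** 2 * l ** 2)) / total
    f[names[13]] = s(lambda i, l, v: v * i ** 2 / l ** 2) / total
    f[names[14]] = s(lambda i, l, v: v * l ** 2 / i ** 2) / total
    f[names[15]] = s(lambda i, l, v: v * i ** 2 * l ** 2) / total
    return f


def glszm_counts(levels, n_bins, mask):
    """Zones by explicit flood fill (26-connectivity)."""
    shape = levels.shape
    visited = np.zeros(shape, bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or visited[x, y, z]:
                    continue
                lev = levels[x, y, z]
                stack, size = [(x, y, z)], 0
                visited[x, y, z] = True
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in OFFSETS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if (_in_bounds(q, shape) and mask[q] and not visited[q]
                                and levels[q] == lev):
                            visited[q] = True
                            stack.append(q)
                zones.append((lev, size))
    max_size = int(mask.sum())
    out = np.zeros((n_bins, max_size))
    for lev, size in zones:
        out[lev - 1, size - 1] += 1
    return out


def ngtdm_table(levels, n_bins, mask):
    shape = levels.shape
    rows = np.zeros((n_bins, 3))
    nvp = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                nb = [levels[x + d[0], y + d[1], z + d[2]]
                      for d in OFFSETS_26
                      if _in_bounds((x + d[0], y + d[1], z + d[2]), shape)
                      and mask[x + d[0], y + d[1], z + d[2]]]
                if not nb:
                    continue
                nvp += 1
                lev = levels[x, y, z]
                rows[lev - 1, 0] += 1
                rows[lev - 1, 2] += abs(lev - sum(nb) / len(nb))
    if nvp:
        rows[:, 1] = rows[:, 0] / nvp
    return rows


def ngtdm_features(rows):
    ng = rows.shape[0]
    n_i, p_i, s_i = rows[:, 0], rows[:, 1], rows[:, 2]
    nvp = n_i.sum()
    nz = [i for i in range(ng) if p_i[i] > 0]
    sum_ps = sum(p_i[i] * s_i[i] for i in range(ng))
    f = {}
    f["coarseness"] = 1e6 if sum_ps == 0 else 1.0 / sum_ps
    if len(nz) <= 1 or nvp == 0:
        f["contrast"] = 0.0
    else:
        a = sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in nz for j in nz)
        f["contrast"] = a / (len(nz) * (len(nz) - 1)) * (s_i.sum() / nvp)
    denom = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in nz for j in nz)
    f["busyness"] = 0.0 if denom == 0 else sum_ps / denom
    f["complexity"] = (0.0 if nvp == 0 else
                       sum(abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                           / (p_i[i] + p_i[j]) for i in nz for j in nz) / nvp)
    ssum = s_i.sum()
    f["strength"] = (0.0 if ssum == 0 else
                     sum((p_i[i] + p_i[j]) * (i - j) ** 2
                         for i in nz for j in nz) / ssum)
    return f


def gldm_counts(levels, n_bins, mask, alpha=0):
    shape = levels.shape
    out = np.zeros((n_bins, 27))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                dep = 0
                for d in OFFSETS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if (_in_bounds(q, shape) and mask[q]
                            and abs(int(levels[q]) - int(levels[x, y, z])) <= alpha):
                        dep += 1
                out[levels[x, y, z] - 1, dep] += 1
    return out


def gldm_features(mat):
    ng, nd = mat.shape
    total = mat.sum()
    p = mat / total
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(nd))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(nd))
    s = lambda fn: sum(fn(i + 1, j + 1, mat[i, j])
                       for i in range(ng) for j in range(nd) if mat[i, j] > 0)
    return {
        "small_dependence_emphasis": s(lambda i, j, v: v / j ** 2) / total,
        "large_dependence_emphasis": s(lambda i, j, v: v * j ** 2) / total,
        "gray_level_nonuniformity": sum(mat[i, :].sum() ** 2 for i in range(ng)) / total,
        "dependence_nonuniformity": sum(mat[:, j].sum() ** 2 for j in range(nd)) / total,
        "dependence_nonuniformity_normalized":
            sum(mat[:, j].sum() ** 2 for j in range(nd)) / total ** 2,
        "gray_level_variance": s(lambda i, j, v: (i - mu_i) ** 2 * v / total),
        "dependence_variance": s(lambda i, j, v: (j - mu_j) ** 2 * v / total),
        "dependence_entropy": -s(lambda i, j, v: (v / total) * math.log2(v / total)),
        "low_gray_level_emphasis": s(lambda i, j, v: v / i ** 2) / total,
        "high_gray_level_emphasis": s(lambda i, j, v: v * i ** 2) / total,
        "small_dependence_low_gray_level_emphasis":
            s(lambda i, j, v: v / (i ** 2 * j ** 2)) / total,
        "small_dependence_high_gray_level_emphasis":
            s(lambda i, j, v: v * i ** 2 / j ** 2) / total,
        "large_dependence_low_gray_level_emphasis":
            s(lambda i, j, v: v * j ** 2 / i ** 2) / total,
        "large_dependence_high_gray_level_emphasis":
            s(lambda i, j, v: v * i ** 2 * j ** 2) / total,
    }


def oracle_texture_features(levels, family, n_bins, mask=None):
    """Feature dict for one patch by pure enumeration, averaged over directions
    for GLCM/GLRLM exactly as the implementation contract states."""
    from perirec.features.texture import GLRLM_NAMES, GLSZM_NAMES

    levels = np.asarray(levels)
    mask = np.ones(levels.shape, bool) if mask is None else np.asarray(mask, bool)
    n_vox = int(mask.sum())
    if family == "glcm":
        counts = glcm_counts(levels, n_bins, mask)
        per_dir = [glcm_features(counts[:, :, k])
                   for k in range(counts.shape[2]) if counts[:, :, k].sum() > 0]
        return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}
    if family == "glrlm":
        counts = glrlm_counts(levels, n_bins, mask)
        per_dir = [rlm_features(counts[:, :, k], n_vox, GLRLM_NAMES)
                   for k in range(counts.shape[2]) if counts[:, :, k].sum() > 0]
        return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}
    if family == "glszm":
        return rlm_features(glszm_counts(levels, n_bins, mask), n_vox, GLSZM_NAMES)
    if family == "ngtdm":
        return ngtdm_features(ngtdm_table(levels, n_bins, mask))
    if family == "gldm":
        return gldm_features(gldm_counts(levels, n_bins, mask))
    raise ValueError(family)


def oracle_otsu(values, n_bins=256):
    """Exhaustive search over all candidate bin splits maximizing between-class
    variance of the 256-bin histogram.

    Returns ``(threshold, max_variance)``.  The objective can be exactly flat
    across an empty gap between modes (every split of the gap is optimal), so
    equality with an implementation is asserted on the attained objective via
    :func:`oracle_otsu_objective`, not on the threshold position.
    """
    values = np.asarray(values, float).ravel()
    counts, edges = np.histogram(values, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, None
    total = counts.sum()
    for k in range(1, n_bins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var_b = w0 * w1 * (mu0 - mu1) ** 2
        if var_b > best:
            best, best_t = var_b, centers[k - 1]
    return best_t, best


def oracle_otsu_objective(values, threshold, n_bins=256):
    """Between-class variance attained by splitting the binned sample at
    ``threshold`` (same histogram convention as :func:`oracle_otsu`)."""
    values = np.asarray(values, float).ravel()
    counts, edges = np.histogram(values, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    below = centers <= threshold
    w0 = counts[below].sum()
    w1 = counts[~below].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (counts[below] * centers[below]).sum() / w0
    mu1 = (counts[~below] * centers[~below]).sum() / w1
    return w0 * w1 * (mu0 - mu1) ** 2
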