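"""Gray-level texture-matrix feature families (GLCM, GLRLM, GLSZM, GLDM, NGTDM).

All families operate on a 3D volume discretized to a fixed number of gray
levels inside a region mask (level 0 marks voxels outside the region). The
definitions follow the IBSI / pyradiomics conventions:

* GLCM and GLRLM are computed per direction over the 13 unique 3D offsets of
  the 26-neighborhood and the per-direction feature values are averaged.
* GLSZM zones and GLDM dependencies use full 26-connectivity.
* Gray levels absent from the region are dropped from the matrices, so
  level-count-dependent features (Idmn, Idn, NGTDM contrast) use the number
  of levels actually present.
* Degenerate regions (a single gray level) use fixed documented fallbacks
  (GLCM correlation = 1, MCC = 1, Imc1 = Imc2 = 0, NGTDM contrast = 0, ...).

Logarithms are base 2 with machine-epsilon guards, as in pyradiomics.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)

# 13 unique direction offsets of the 26-neighborhood (negatives are the
# same undirected direction)
OFFSETS_13 = [
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
]


def discretize(volume: np.ndarray, mask: np.ndarray, bin_count: int = 32) -> np.ndarray:
    """Fixed-bin-count discretization inside ``mask``.

    Returns an integer volume with levels 1..bin_count inside the region and
    0 outside. A constant region maps entirely to level 1.
    """
    mask = mask.astype(bool)
    vals = volume[mask]
    disc = np.zeros(volume.shape, dtype=np.int32)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        disc[mask] = 1
        return disc
    width = (hi - lo) / bin_count
    lev = np.floor((volume[mask] - lo) / width).astype(np.int32) + 1
    np.clip(lev, 1, bin_count, out=lev)
    disc[mask] = lev
    return disc


def _shift_pair(disc, off):
    """Source/destination co-views of ``disc`` under offset ``off``."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(off):
        if d > 0:
            src[ax] = slice(0, disc.shape[ax] - d)
            dst[ax] = slice(d, disc.shape[ax])
        elif d < 0:
            src[ax] = slice(-d, disc.shape[ax])
            dst[ax] = slice(0, disc.shape[ax] + d)
    return disc[tuple(src)], disc[tuple(dst)]


# --------------------------------------------------------------------------
# GLCM


def glcm_matrices(disc: np.ndarray):
    """Symmetric normalized co-occurrence matrices, one per direction.

    Returns (P, levels): P has shape (13, G, G) over the G gray levels
    present; each direction's matrix sums to 1.
    """
    levels = np.unique(disc[disc > 0])
    nmax = int(disc.max()) + 1
    index = np.full(nmax, -1, dtype=np.int64)
    index[levels] = np.arange(levels.size)
    mats = []
    for off in OFFSETS_13:
        a, b = _shift_pair(disc, off)
        valid = (a > 0) & (b > 0)
        ia, ib = index[a[valid]], index[b[valid]]
        counts = np.bincount(
            ia * levels.size + ib, minlength=levels.size**2
        ).reshape(levels.size, levels.size)
        counts = counts + counts.T
        total = counts.sum()
        mats.append(counts / total if total > 0 else counts.astype(float))
    return np.array(mats, dtype=float), levels.astype(float)


def glcm_features(disc: np.ndarray) -> dict:
    P, iv = glcm_matrices(disc)
    G = iv.size
    na = P.shape[0]
    i = iv[None, :, None]
    j = iv[None, None, :]
    px = P.sum(axis=2)  # (na, G)
    ux = (px * iv[None, :]).sum(axis=1)  # (na,)
    sigx = np.sqrt((px * (iv[None, :] - ux[:, None]) ** 2).sum(axis=1))
    # symmetric matrices: y-margin quantities equal x-margin quantities
    diff = np.abs(i - j)
    ksum = i + j

    def asum(x):  # sum over (G, G) per angle
        return x.reshape(na, -1).sum(axis=1)

    out = {}
    out["Autocorrelation"] = asum(P * i * j)
    out["JointAverage"] = ux
    mu2 = ux[:, None, None] * 2
    out["ClusterProminence"] = asum(P * (ksum - mu2) ** 4)
    out["ClusterShade"] = asum(P * (ksum - mu2) ** 3)
    out["ClusterTendency"] = asum(P * (ksum - mu2) ** 2)
    out["Contrast"] = asum(P * (i - j) ** 2)
    denom = sigx * sigx
    corr = np.where(
        denom > 0,
        (asum(P * i * j) - ux * ux) / np.where(denom > 0, denom, 1.0),
        1.0,
    )
    out["Correlation"] = corr

    # difference and sum distributions
    dlev = np.arange(0, int(iv.max() - iv.min()) + 1, dtype=float)
    pxmy = np.zeros((na, dlev.size))
    for gi in range(G):
        for gj in range(G):
            pxmy[:, int(abs(iv[gi] - iv[gj]))] += P[:, gi, gj]
    da = (pxmy * dlev[None, :]).sum(axis=1)
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -(pxmy * np.log2(pxmy + _EPS)).sum(axis=1)
    out["DifferenceVariance"] = (pxmy * (dlev[None, :] - da[:, None]) ** 2).sum(axis=1)
    out["JointEnergy"] = asum(P**2)
    hxy = -asum(P * np.log2(P + _EPS))
    out["JointEntropy"] = hxy

    pxi = px[:, :, None]  # p_x(i)
    pyj = px[:, None, :]  # p_y(j) = p_x(j) by symmetry
    hxy1 = -asum(P * np.log2(pxi * pyj + _EPS))
    hxy2 = -asum(pxi * pyj * np.log2(pxi * pyj + _EPS))
    hx = -(px * np.log2(px + _EPS)).sum(axis=1)
    maxh = np.maximum(hx, hx)
    imc1 = np.where(maxh > 0, (hxy - hxy1) / np.where(maxh > 0, maxh, 1.0), 0.0)
    out["Imc1"] = imc1
    inner = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["Imc2"] = np.sqrt(np.clip(inner, 0.0, None))
    out["Idm"] = asum(P / (1.0 + (i - j) ** 2))
    out["Idmn"] = asum(P / (1.0 + ((i - j) / G) ** 2))
    out["Id"] = asum(P / (1.0 + diff))
    out["Idn"] = asum(P / (1.0 + diff / G))
    offdiag = diff > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        iv_term = np.where(offdiag, P / np.where(offdiag, (i - j) ** 2, 1.0), 0.0)
    out["InverseVariance"] = asum(iv_term)
    out["MaximumProbability"] = P.reshape(na, -1).max(axis=1)
    slev = np.arange(2 * iv.min(), 2 * iv.max() + 1, dtype=float)
    pxpy = np.zeros((na, slev.size))
    base = int(2 * iv.min())
    for gi in range(G):
        for gj in range(G):
            pxpy[:, int(iv[gi] + iv[gj]) - base] += P[:, gi, gj]
    out["SumAverage"] = (pxpy * slev[None, :]).sum(axis=1)
    out["SumEntropy"] = -(pxpy * np.log2(pxpy + _EPS)).sum(axis=1)
    out["SumSquares"] = asum(P * (i - ux[:, None, None]) ** 2)

    # maximal correlation coefficient: sqrt of second-largest eigenvalue of Q
    mcc = np.ones(na)
    if G > 1:
        for a in range(na):
            p = P[a]
            pxa = p.sum(axis=1)
            pya = p.sum(axis=0)
            nz = (pxa > 0) & (pya > 0)
            psub = p[np.ix_(nz, nz)]
            if psub.shape[0] < 2:
                mcc[a] = 1.0
                continue
            A = psub / psub.sum(axis=1, keepdims=True)
            B = psub / psub.sum(axis=0, keepdims=True)
            Q = A @ B.T
            eig = np.sort(np.abs(np.linalg.eigvals(Q)))
            mcc[a] = np.sqrt(max(float(eig[-2]), 0.0))
    out["MCC"] = mcc

    return {k: float(np.mean(v)) for k, v in out.items()}


# --------------------------------------------------------------------------
# entry-list feature helpers (GLRLM / GLSZM / GLDM share their formula set)


def _size_zone_formulas(iv, jv, cv, n_voxels, prefix_small, prefix_large, kind):
    """The 16 run-length/size-zone style features from matrix entries.

    iv: gray-level values, jv: run-length/zone-size values, cv: counts.
    ``kind`` selects the naming family.
    """
    nz = cv.sum()
    p = cv / nz
    out = {}
    small = ((cv / jv**2).sum()) / nz
    large = ((cv * jv**2).sum()) / nz
    # gray-level / size marginals
    lev_tot = {}
    for lv, c in zip(iv, cv):
        lev_tot[lv] = lev_tot.get(lv, 0.0) + c
    size_tot = {}
    for sv, c in zip(jv, cv):
        size_tot[sv] = size_tot.get(sv, 0.0) + c
    gln = sum(c**2 for c in lev_tot.values()) / nz
    glnn = sum(c**2 for c in lev_tot.values()) / nz**2
    szn = sum(c**2 for c in size_tot.values()) / nz
    sznn = sum(c**2 for c in size_tot.values()) / nz**2
    mu_i = (p * iv).sum()
    mu_j = (p * jv).sum()
    glv = (p * (iv - mu_i) ** 2).sum()
    jv_var = (p * (jv - mu_j) ** 2).sum()
    entropy = -(p * np.log2(p + _EPS)).sum()
    lglre = ((cv / iv**2).sum()) / nz
    hglre = ((cv * iv**2).sum()) / nz
    srlgl = ((cv / (iv**2 * jv**2)).sum()) / nz
    srhgl = ((cv * iv**2 / jv**2).sum()) / nz
    lrlgl = ((cv * jv**2 / iv**2).sum()) / nz
    lrhgl = ((cv * iv**2 * jv**2).sum()) / nz

    if kind == "glrlm":
        out["ShortRunEmphasis"] = small
        out["LongRunEmphasis"] = large
        out["GrayLevelNonUniformity"] = gln
        out["GrayLevelNonUniformityNormalized"] = glnn
        out["RunLengthNonUniformity"] = szn
        out["RunLengthNonUniformityNormalized"] = sznn
        out["RunPercentage"] = nz / n_voxels
        out["GrayLevelVariance"] = glv
        out["RunVariance"] = jv_var
        out["RunEntropy"] = entropy
        out["LowGrayLevelRunEmphasis"] = lglre
        out["HighGrayLevelRunEmphasis"] = hglre
        out["ShortRunLowGrayLevelEmphasis"] = srlgl
        out["ShortRunHighGrayLevelEmphasis"] = srhgl
        out["LongRunLowGrayLevelEmphasis"] = lrlgl
        out["LongRunHighGrayLevelEmphasis"] = lrhgl
    else:  # glszm
        out["SmallAreaEmphasis"] = small
        out["LargeAreaEmphasis"] = large
        out["GrayLevelNonUniformity"] = gln
        out["GrayLevelNonUniformityNormalized"] = glnn
        out["SizeZoneNonUniformity"] = szn
        out["SizeZoneNonUniformityNormalized"] = sznn
        out["ZonePercentage"] = nz / n_voxels
        out["GrayLevelVariance"] = glv
        out["ZoneVariance"] = jv_var
        out["ZoneEntropy"] = entropy
        out["LowGrayLevelZoneEmphasis"] = lglre
        out["HighGrayLevelZoneEmphasis"] = hglre
        out["SmallAreaLowGrayLevelEmphasis"] = srlgl
        out["SmallAreaHighGrayLevelEmphasis"] = srhgl
        out["LargeAreaLowGrayLevelEmphasis"] = lrlgl
        out["LargeAreaHighGrayLevelEmphasis"] = lrhgl
    return out


# --------------------------------------------------------------------------
# GLRLM


def glrlm_entries(disc: np.ndarray, off) -> tuple:
    """(levels, lengths, counts) of maximal runs along one direction.

    Forward run length f(v) = 1 + f(v + off) when the successor holds the
    same in-region level, computed by fix-point propagation (one step per
    iteration, so the loop runs at most max-run-length times).
    """
    region = disc > 0
    a_src, a_dst = _shift_pair(disc, off)
    # eq_next[v]: v and v+off both in region with equal level
    eq_next = np.zeros(disc.shape, dtype=bool)
    eq_view, _ = _shift_pair(eq_next, off)
    eq_view[...] = (a_src == a_dst) & (a_src > 0)
    f = region.astype(np.int64)
    while True:
        succ = np.zeros_like(f)
        succ_view, _ = _shift_pair(succ, off)
        _, f_dst = _shift_pair(f, off)
        succ_view[...] = f_dst
        fn = region.astype(np.int64) + np.where(eq_next, succ, 0)
        if np.array_equal(fn, f):
            break
        f = fn
    # run starts: in-region voxels with no equal predecessor at -off
    neg = tuple(-d for d in off)
    pred_eq = np.zeros(disc.shape, dtype=bool)
    p_view, _ = _shift_pair(pred_eq, neg)
    b_src, b_dst = _shift_pair(disc, neg)
    p_view[...] = (b_src == b_dst) & (b_src > 0)
    starts = region & ~pred_eq
    levels = disc[starts]
    lengths = f[starts]
    key = levels.astype(np.int64) * (int(lengths.max()) + 1) + lengths
    uk, counts = np.unique(key, return_counts=True)
    lmax = int(lengths.max()) + 1
    return (uk // lmax).astype(float), (uk % lmax).astype(float), counts.astype(float)


def glrlm_features(disc: np.ndarray) -> dict:
    n_vox = int((disc > 0).sum())
    per_dir = []
    for off in OFFSETS_13:
        iv, jv, cv = glrlm_entries(disc, off)
        per_dir.append(_size_zone_formulas(iv, jv, cv, n_vox, "", "", "glrlm"))
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


# --------------------------------------------------------------------------
# GLSZM

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


def glszm_entries(disc: np.ndarray) -> tuple:
    iv, jv, cv = [], [], []
    for level in np.unique(disc[disc > 0]):
        lab, n = ndimage.label(disc == level, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        us, uc = np.unique(sizes, return_counts=True)
        iv.extend([float(level)] * us.size)
        jv.extend(us.astype(float))
        cv.extend(uc.astype(float))
    return np.array(iv), np.array(jv), np.array(cv)


def glszm_features(disc: np.ndarray) -> dict:
    iv, jv, cv = glszm_entries(disc)
    n_vox = int((disc > 0).sum())
    return _size_zone_formulas(iv, jv, cv, n_vox, "", "", "glszm")


# --------------------------------------------------------------------------
# GLDM


def gldm_entries(disc: np.ndarray, alpha: int = 0) -> tuple:
    """Dependence entries: j = 1 + number of 26-neighbors within ``alpha`` levels."""
    region = disc > 0
    dep = np.zeros(disc.shape, dtype=np.int64)
    for off in OFFSETS_13:
        for o in (off, tuple(-d for d in off)):
            contrib = np.zeros(disc.shape, dtype=bool)
            src_view, _ = _shift_pair(contrib, o)
            a, b = _shift_pair(disc, o)
            src_view[...] = (np.abs(a - b) <= alpha) & (a > 0) & (b > 0)
            dep += contrib
    levels = disc[region].astype(np.int64)
    j = dep[region] + 1
    key = levels * (int(j.max()) + 1) + j
    uk, counts = np.unique(key, return_counts=True)
    jmax = int(j.max()) + 1
    return (uk // jmax).astype(float), (uk % jmax).astype(float), counts.astype(float)


def gldm_features(disc: np.ndarray) -> dict:
    iv, jv, cv = gldm_entries(disc)
    nz = cv.sum()
    p = cv / nz
    lev_tot = {}
    for lv, c in zip(iv, cv):
        lev_tot[lv] = lev_tot.get(lv, 0.0) + c
    dep_tot = {}
    for dv, c in zip(jv, cv):
        dep_tot[dv] = dep_tot.get(dv, 0.0) + c
    mu_i = (p * iv).sum()
    mu_j = (p * jv).sum()
    return {
        "SmallDependenceEmphasis": float(((cv / jv**2).sum()) / nz),
        "LargeDependenceEmphasis": float(((cv * jv**2).sum()) / nz),
        "GrayLevelNonUniformity": float(sum(c**2 for c in lev_tot.values()) / nz),
        "DependenceNonUniformity": float(sum(c**2 for c in dep_tot.values()) / nz),
        "DependenceNonUniformityNormalized": float(
            sum(c**2 for c in dep_tot.values()) / nz**2
        ),
        "GrayLevelVariance": float((p * (iv - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (jv - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelEmphasis": float(((cv / iv**2).sum()) / nz),
        "HighGrayLevelEmphasis": float(((cv * iv**2).sum()) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            ((cv / (iv**2 * jv**2)).sum()) / nz
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            ((cv * iv**2 / jv**2).sum()) / nz
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            ((cv * jv**2 / iv**2).sum()) / nz
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            ((cv * iv**2 * jv**2).sum()) / nz
        ),
    }


# --------------------------------------------------------------------------
# NGTDM

_KERNEL26 = np.ones((3, 3, 3), dtype=float)
_KERNEL26[1, 1, 1] = 0.0


def ngtdm_features(disc: np.ndarray) -> dict:
    region = disc > 0
    nsum = ndimage.correlate(
        (disc * region).astype(float), _KERNEL26, mode="constant", cval=0.0
    )
    ncnt = ndimage.correlate(region.astype(float), _KERNEL26, mode="constant", cval=0.0)
    valid = region & (ncnt > 0)
    nv = int(valid.sum())
    abar = np.zeros(disc.shape)
    abar[valid] = nsum[valid] / ncnt[valid]
    levels = np.unique(disc[valid])
    n_i = np.array([(disc[valid] == lv).sum() for lv in levels], dtype=float)
    s_i = np.array(
        [np.abs(lv - abar[valid & (disc == lv)]).sum() for lv in levels], dtype=float
    )
    p_i = n_i / nv
    lv = levels.astype(float)
    ngp = levels.size
    out = {}
    denom = (p_i * s_i).sum()
    out["Coarseness"] = float(1.0 / denom) if denom > 0 else 1e6
    if ngp > 1:
        pij = p_i[:, None] * p_i[None, :]
        dij2 = (lv[:, None] - lv[None, :]) ** 2
        out["Contrast"] = float(
            (pij * dij2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nv
        )
    else:
        out["Contrast"] = 0.0
    busy_den = np.abs(lv[:, None] * p_i[:, None] - lv[None, :] * p_i[None, :]).sum()
    out["Busyness"] = float(denom / busy_den) if busy_den > 0 else 0.0
    # complexity / strength over pairs with p > 0 (all retained levels qualify)
    psum = p_i[:, None] + p_i[None, :]
    ps = p_i[:, None] * s_i[:, None] + p_i[None, :] * s_i[None, :]
    out["Complexity"] = float(
        (np.abs(lv[:, None] - lv[None, :]) * ps / psum).sum() / nv
    )
    s_tot = s_i.sum()
    out["Strength"] = (
        float((psum * (lv[:, None] - lv[None, :]) ** 2).sum() / s_tot)
        if s_tot > 0
        else 0.0
    )
    return out
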