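"""Gray-level discretization and the five texture-matrix families.

Conventions (IBSI-style):

* intensities are discretized into ``n_bins`` equal-width bins over the
  in-mask [min, max] range, so all texture features are invariant to
  adding a constant to the image;
* GLCM and GLRLM are computed per in-plane direction (0, 45, 90, 135
  degrees) at distance 1 and feature values are averaged over directions;
* GLSZM zones are 8-connected; NGTDM uses the 8-neighborhood at distance 1;
* GLDM uses distance 1 and similarity threshold alpha = 0, with the
  dependence size of a pixel defined as 1 + the number of in-mask
  neighbors whose level matches within alpha.

Pixels outside the mask never contribute: they break runs, are excluded
from co-occurrence pairs, zones, and neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

TEXTURE_KINDS = ("glcm", "glszm", "glrlm", "ngtdm", "gldm")

#: distance-1 directions: 0, 45, 90, 135 degrees as (dr, dc) offsets
DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class QuantizedRoi:
    """Discretized ROI: integer levels in [1, n_bins] on in-mask pixels."""

    levels: np.ndarray  # int array, 0 outside mask
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray


def discretize(image: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> QuantizedRoi:
    """Equal-width binning of in-mask intensities into [1, n_bins].

    A constant ROI maps entirely to level 1. Bin edges span the in-mask
    [min, max]; the top edge is inclusive.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = image[mask]
    lo, hi = float(x.min()), float(x.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    levels = np.zeros(image.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
    else:
        width = (hi - lo) / n_bins
        lv = np.floor((image[mask] - lo) / width).astype(np.int64) + 1
        levels[mask] = np.clip(lv, 1, n_bins)
    return QuantizedRoi(levels=levels, mask=mask, n_bins=n_bins, bin_edges=edges)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def glcm_matrices(q: QuantizedRoi) -> np.ndarray:
    """Symmetric co-occurrence counts, one (Ng, Ng) matrix per direction."""
    ng = q.n_bins
    out = np.zeros((len(DIRECTIONS), ng, ng), dtype=np.float64)
    lv, mk = q.levels, q.mask
    h, w = lv.shape
    for d, (dr, dc) in enumerate(DIRECTIONS):
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        a = lv[r0s:r0e, c0s:c0e]
        b = lv[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        valid = mk[r0s:r0e, c0s:c0e] & mk[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        ai, bi = a[valid] - 1, b[valid] - 1
        np.add.at(out[d], (ai, bi), 1.0)
        np.add.at(out[d], (bi, ai), 1.0)  # symmetrize
    return out


def _lines(arr: np.ndarray, direction: tuple[int, int]):
    """Yield the 1D scan lines of ``arr`` along a direction offset."""
    h, w = arr.shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        yield from arr
    elif (dr, dc) == (-1, 0):
        yield from arr.T
    elif (dr, dc) == (-1, -1):  # 135 deg: runs along main diagonals
        for off in range(-(h - 1), w):
            yield np.diagonal(arr, offset=off)
    elif (dr, dc) == (-1, 1):  # 45 deg: anti-diagonals
        f = np.fliplr(arr)
        for off in range(-(h - 1), w):
            yield np.diagonal(f, offset=off)
    else:  # pragma: no cover
        raise ValueError(f"unsupported direction {direction}")


def _run_lengths(line: np.ndarray) -> list[tuple[int, int]]:
    """(level, run length) for maximal runs; level 0 (out of mask) breaks runs."""
    runs = []
    prev, count = 0, 0
    for v in line:
        if v == prev and v != 0:
            count += 1
        else:
            if prev != 0:
                runs.append((int(prev), count))
            prev, count = int(v), (1 if v != 0 else 0)
    if prev != 0:
        runs.append((prev, count))
    return runs


def glrlm_matrices(q: QuantizedRoi) -> list[np.ndarray]:
    """Run-length counts P(g, l), one (Ng, Lmax) matrix per direction."""
    ng = q.n_bins
    lmax = max(q.levels.shape)
    arr = np.where(q.mask, q.levels, 0)
    out = []
    for d in DIRECTIONS:
        mat = np.zeros((ng, lmax), dtype=np.float64)
        for line in _lines(arr, d):
            for g, length in _run_lengths(np.asarray(line)):
                mat[g - 1, length - 1] += 1.0
        out.append(mat)
    return out


def glszm_matrix(q: QuantizedRoi) -> np.ndarray:
    """Zone-size counts P(g, s) with 8-connected zones."""
    ng = q.n_bins
    smax = int(q.mask.sum())
    mat = np.zeros((ng, smax), dtype=np.float64)
    structure = np.ones((3, 3), dtype=int)
    for g in range(1, ng + 1):
        binary = q.mask & (q.levels == g)
        if not binary.any():
            continue
        lab, nz = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            mat[g - 1, s - 1] += 1.0
    return mat


def ngtdm_table(q: QuantizedRoi) -> np.ndarray:
    """NGTDM: per level i, rows (n_i, s_i) stacked as an (Ng, 2) array.

    n_i counts in-mask pixels of level i that have at least one in-mask
    neighbor; s_i sums |i - mean neighbor level| over those pixels.
    """
    ng = q.n_bins
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    lv = np.where(q.mask, q.levels, 0).astype(np.float64)
    mk = q.mask.astype(np.float64)
    nb_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mk, kernel, mode="constant", cval=0.0)
    valid = q.mask & (nb_cnt > 0)
    diffs = np.zeros_like(lv)
    diffs[valid] = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    out = np.zeros((ng, 2), dtype=np.float64)
    for g in range(1, ng + 1):
        sel = valid & (q.levels == g)
        out[g - 1, 0] = sel.sum()
        out[g - 1, 1] = diffs[sel].sum()
    return out


def gldm_matrix(q: QuantizedRoi, alpha: int = 0) -> np.ndarray:
    """Dependence counts P(g, d): d = 1 + similar in-mask 8-neighbors."""
    ng = q.n_bins
    h, w = q.levels.shape
    dep = np.zeros((h, w), dtype=np.int64)
    for dr, dc in ((0, 1), (-1, 1), (-1, 0), (-1, -1),
                   (0, -1), (1, -1), (1, 0), (1, 1)):
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        a = q.levels[r0s:r0e, c0s:c0e]
        b = q.levels[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        both = (
            q.mask[r0s:r0e, c0s:c0e]
            & q.mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
            & (np.abs(a - b) <= alpha)
        )
        dep[r0s:r0e, c0s:c0e] += both
    dmax = 9
    mat = np.zeros((ng, dmax), dtype=np.float64)
    rr, cc = np.nonzero(q.mask)
    np.add.at(mat, (q.levels[rr, cc] - 1, dep[rr, cc]), 1.0)
    return mat


def texture_matrix(kind: str, q: QuantizedRoi, **params):
    """Dispatch to the count structure for one family."""
    if kind == "glcm":
        return glcm_matrices(q)
    if kind == "glszm":
        return glszm_matrix(q)
    if kind == "glrlm":
        return glrlm_matrices(q)
    if kind == "ngtdm":
        return ngtdm_table(q)
    if kind == "gldm":
        return gldm_matrix(q, alpha=params.get("alpha", 0))
    raise ValueError(f"unknown texture kind {kind!r}")


# ---------------------------------------------------------------------------
# features from matrices
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def glcm_features_single(counts: np.ndarray) -> dict[str, float]:
    """The 24 co-occurrence features from one symmetric count matrix."""
    total = counts.sum()
    ng = counts.shape[0]
    if total == 0:
        return {k: 0.0 for k in _GLCM_KEYS}
    p = counts / total
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * i).sum())  # symmetric: mu_x = mu_y
    sigma2 = float((px * (i - mu) ** 2).sum())
    sigma = np.sqrt(sigma2)

    # diagonal (|i-j|) and cross (i+j) marginals
    k_d = np.arange(0, ng)
    p_d = np.array([p[np.abs(ii - jj) == k].sum() for k in k_d])
    k_s = np.arange(2, 2 * ng + 1)
    p_s = np.array([p[(ii + jj) == k].sum() for k in k_s])

    da = float((k_d * p_d).sum())
    hx = _entropy(px)
    hxy = _entropy(p)
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-np.sum(p * lg))
    hxy2 = float(-np.sum(pxpy * lg))

    present = px > 0
    if present.sum() > 1:
        ps = p[np.ix_(present, present)]
        pxs = px[present]
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        q_mat = np.einsum("ik,jk->ij", ps / pxs[:, None], ps / pxs[None, :])
        eig = np.sort(np.real(np.linalg.eigvals(q_mat)))[::-1]
        mcc = float(np.sqrt(max(eig[1], 0.0))) if eig.size > 1 else 1.0
    else:
        mcc = 1.0

    corr = 1.0 if sigma2 == 0 else float(
        ((p * ii * jj).sum() - mu * mu) / (sigma * sigma)
    )
    offdiag = ii != jj
    denom_max = max(hx, hx)  # HX = HY by symmetry
    imc1 = 0.0 if denom_max == 0 else float((hxy - hxy1) / denom_max)
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(p_d),
        "DifferenceVariance": float(((k_d - da) ** 2 * p_d).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p[offdiag] / (ii - jj)[offdiag] ** 2).sum()),
        "JointAverage": float((p * ii).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_s * p_s).sum()),
        "SumEntropy": _entropy(p_s),
        "SumSquares": float((p * (ii - mu) ** 2).sum()),
    }


_GLCM_KEYS = tuple(glcm_features_single(np.ones((2, 2))).keys())


def _size_family_features(mat: np.ndarray, n_pixels: int, prefix: dict) -> dict:
    """Shared machinery for GLRLM / GLSZM / GLDM style (level x size) counts.

    ``prefix`` maps the generic feature roles onto family-specific names.
    """
    ns = mat.sum()
    ng_dim, smax = mat.shape
    g = np.arange(1, ng_dim + 1, dtype=np.float64)
    s = np.arange(1, smax + 1, dtype=np.float64)
    out = {}
    if ns == 0:
        return {v: 0.0 for v in prefix.values()}
    p = mat / ns
    pg = mat.sum(axis=1)
    psz = mat.sum(axis=0)
    mu_g = float((p.sum(axis=1) * g).sum())
    mu_s = float((p.sum(axis=0) * s).sum())
    gg, ss = np.meshgrid(g, s, indexing="ij")
    out[prefix["small"]] = float((mat / ss**2).sum() / ns)
    out[prefix["large"]] = float((mat * ss**2).sum() / ns)
    out[prefix["gln"]] = float((pg**2).sum() / ns)
    if "glnn" in prefix:
        out[prefix["glnn"]] = float((pg**2).sum() / ns**2)
    out[prefix["sn"]] = float((psz**2).sum() / ns)
    out[prefix["snn"]] = float((psz**2).sum() / ns**2)
    if "pct" in prefix:
        out[prefix["pct"]] = float(ns / n_pixels)
    out[prefix["glv"]] = float((p * (gg - mu_g) ** 2).sum())
    out[prefix["sv"]] = float((p * (ss - mu_s) ** 2).sum())
    out[prefix["entropy"]] = _entropy(p.ravel())
    out[prefix["lgl"]] = float((mat / gg**2).sum() / ns)
    out[prefix["hgl"]] = float((mat * gg**2).sum() / ns)
    out[prefix["slgl"]] = float((mat / (gg**2 * ss**2)).sum() / ns)
    out[prefix["shgl"]] = float((mat * gg**2 / ss**2).sum() / ns)
    out[prefix["llgl"]] = float((mat * ss**2 / gg**2).sum() / ns)
    out[prefix["lhgl"]] = float((mat * gg**2 * ss**2).sum() / ns)
    return out


_GLRLM_MAP = dict(
    small="ShortRunEmphasis", large="LongRunEmphasis",
    gln="GrayLevelNonUniformity", glnn="GrayLevelNonUniformityNormalized",
    sn="RunLengthNonUniformity", snn="RunLengthNonUniformityNormalized",
    pct="RunPercentage", glv="GrayLevelVariance", sv="RunVariance",
    entropy="RunEntropy", lgl="LowGrayLevelRunEmphasis",
    hgl="HighGrayLevelRunEmphasis", slgl="ShortRunLowGrayLevelEmphasis",
    shgl="ShortRunHighGrayLevelEmphasis", llgl="LongRunLowGrayLevelEmphasis",
    lhgl="LongRunHighGrayLevelEmphasis",
)

_GLSZM_MAP = dict(
    small="SmallAreaEmphasis", large="LargeAreaEmphasis",
    gln="GrayLevelNonUniformity", glnn="GrayLevelNonUniformityNormalized",
    sn="SizeZoneNonUniformity", snn="SizeZoneNonUniformityNormalized",
    pct="ZonePercentage", glv="GrayLevelVariance", sv="ZoneVariance",
    entropy="ZoneEntropy", lgl="LowGrayLevelZoneEmphasis",
    hgl="HighGrayLevelZoneEmphasis", slgl="SmallAreaLowGrayLevelEmphasis",
    shgl="SmallAreaHighGrayLevelEmphasis", llgl="LargeAreaLowGrayLevelEmphasis",
    lhgl="LargeAreaHighGrayLevelEmphasis",
)

# GLDM has no normalized gray-level non-uniformity and no percentage
# (every in-mask pixel contributes exactly one dependence), hence 14.
_GLDM_MAP = dict(
    small="SmallDependenceEmphasis", large="LargeDependenceEmphasis",
    gln="GrayLevelNonUniformity", sn="DependenceNonUniformity",
    snn="DependenceNonUniformityNormalized", glv="GrayLevelVariance",
    sv="DependenceVariance", entropy="DependenceEntropy",
    lgl="LowGrayLevelEmphasis", hgl="HighGrayLevelEmphasis",
    slgl="SmallDependenceLowGrayLevelEmphasis",
    shgl="SmallDependenceHighGrayLevelEmphasis",
    llgl="LargeDependenceLowGrayLevelEmphasis",
    lhgl="LargeDependenceHighGrayLevelEmphasis",
)


def glrlm_features_single(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    return _size_family_features(mat, n_pixels, _GLRLM_MAP)


def glszm_features(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    return _size_family_features(mat, n_pixels, _GLSZM_MAP)


def gldm_features(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    return _size_family_features(mat, n_pixels, _GLDM_MAP)


def ngtdm_features(table: np.ndarray) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength."""
    n_i = table[:, 0]
    s_i = table[:, 1]
    nvc = n_i.sum()
    if nvc == 0:
        return {k: 0.0 for k in
                ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p_i = n_i / nvc
    levels = np.arange(1, table.shape[0] + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())
    pi, li, si = p_i[present], levels[present], s_i[present]

    coars_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coars_den if coars_den > 0 else 1e6

    if ngp > 1:
        dij2 = (li[:, None] - li[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * dij2).sum()
            / (ngp * (ngp - 1)) * (s_i.sum() / nvc)
        )
        busy_den = float(np.abs(li[:, None] * pi[:, None]
                                - li[None, :] * pi[None, :]).sum())
        busyness = coars_den / busy_den if busy_den > 0 else 0.0
        absd = np.abs(li[:, None] - li[None, :])
        complexity = float(
            (absd * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
             / (pi[:, None] + pi[None, :])).sum() / nvc
        )
        s_sum = float(s_i.sum())
        strength = (
            float(((pi[:, None] + pi[None, :]) * dij2).sum()) / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features(kind: str, matrix, n_pixels: int | None = None,
                     **params) -> dict[str, float]:
    """Named feature vector for one family.

    Directional families (GLCM, GLRLM) receive the per-direction matrices
    and average feature values over the 4 directions.
    """
    if kind == "glcm":
        dicts = [glcm_features_single(m) for m in matrix]
        return {k: float(np.mean([d[k] for d in dicts])) for k in dicts[0]}
    if kind == "glrlm":
        dicts = [glrlm_features_single(m, n_pixels) for m in matrix]
        return {k: float(np.mean([d[k] for d in dicts])) for k in dicts[0]}
    if kind == "glszm":
        return glszm_features(matrix, n_pixels)
    if kind == "ngtdm":
        return ngtdm_features(matrix)
    if kind == "gldm":
        return gldm_features(matrix, n_pixels)
    raise ValueError(f"unknown texture kind {kind!r}")
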