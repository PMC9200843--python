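"""Gray-level texture matrices: run length (GLRLM), size zone (GLSZM) and
neighborhood gray-tone difference (NGTDM).

All three operate on a discretized ROI (levels 1..N_g inside the mask, 0
outside).  GLRLM accumulates runs over the 13 unique 3D directions and the
directional matrices are merged (summed) before features are computed;
GLSZM zones and NGTDM neighborhoods use 26-connectivity (Chebyshev
distance 1).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .preprocess import QuantizedROI

__all__ = [
    "DIRECTIONS_13",
    "run_length_matrix",
    "glrlm_features",
    "size_zone_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
]

#: the 13 unique (up to sign) displacement vectors of the 26-neighborhood
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: value returned for NGTDM coarseness on a perfectly homogeneous region
COARSENESS_CAP = 1.0e6


def _shift(arr: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """Array whose value at x is arr[x - d] (out-of-grid -> fill)."""
    out = np.full_like(arr, fill)
    src = tuple(
        slice(max(0, -di), arr.shape[i] - max(0, di)) for i, di in enumerate(d)
    )
    dst = tuple(
        slice(max(0, di), arr.shape[i] - max(0, -di)) for i, di in enumerate(d)
    )
    out[dst] = arr[src]
    return out


def run_length_matrix(
    levels: np.ndarray, direction: tuple[int, int, int]
) -> np.ndarray:
    """GLRLM for one direction: entry [g-1, r-1] counts maximal runs of
    gray level g with length r.  Out-of-mask voxels (level 0) break runs."""
    lv = np.asarray(levels)
    if lv.ndim != 3:
        raise ValueError("levels must be 3D")
    ng = int(lv.max())
    if ng < 1:
        raise ValueError("quantized ROI is empty")
    d = tuple(int(x) for x in direction)

    # continues[x]: the run through x extends to x + d
    nxt = _shift(lv, tuple(-di for di in d), fill=0)
    continues = (lv > 0) & (lv == nxt)
    # start[x]: x opens a run (no same-level in-mask predecessor at x - d)
    prv = _shift(lv, d, fill=0)
    start = (lv > 0) & (lv != prv)

    max_run = int(np.ceil(np.sqrt(sum(s**2 for s in lv.shape)))) + 1
    mat = np.zeros((ng, max_run), dtype=np.int64)
    front = start
    r = 1
    while front.any():
        ended = front & ~continues
        if ended.any():
            np.add.at(mat[:, r - 1], lv[ended] - 1, 1)
        front = _shift(front & continues, d)
        r += 1
    # trim trailing all-zero run lengths
    used = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : used[-1] + 1] if used.size else mat[:, :1]


def _merge_matrices(mats: list[np.ndarray]) -> np.ndarray:
    rmax = max(m.shape[1] for m in mats)
    out = np.zeros((mats[0].shape[0], rmax), dtype=np.int64)
    for m in mats:
        out[:, : m.shape[1]] += m
    return out


def _weighted_stats(P: np.ndarray) -> dict[str, float]:
    """Common statistics of a gray-level x size matrix (runs or zones)."""
    Ns = P.sum()
    p = P / Ns
    g = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((pg * g[:, 0]).sum())
    mu_s = float((ps * s[0, :]).sum())
    nz = p[p > 0]
    return {
        "small": float((p / s**2).sum()),
        "large": float((p * s**2).sum()),
        "gln": float((P.sum(axis=1) ** 2).sum() / Ns),
        "glnn": float((P.sum(axis=1) ** 2).sum() / Ns**2),
        "sn": float((P.sum(axis=0) ** 2).sum() / Ns),
        "snn": float((P.sum(axis=0) ** 2).sum() / Ns**2),
        "low_gray": float((p / g**2).sum()),
        "high_gray": float((p * g**2).sum()),
        "small_low": float((p / (g**2 * s**2)).sum()),
        "small_high": float((p * g**2 / s**2).sum()),
        "large_low": float((p * s**2 / g**2).sum()),
        "large_high": float((p * g**2 * s**2).sum()),
        "gl_var": float((p * (g - mu_g) ** 2).sum()),
        "s_var": float((p * (s - mu_s) ** 2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "Ns": float(Ns),
    }


def glrlm_features(
    quantized: QuantizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float]:
    lv = quantized.levels
    mats = [run_length_matrix(lv, d) for d in directions]
    P = _merge_matrices(mats)
    st = _weighted_stats(P)
    n_vox = int((lv > 0).sum())
    return {
        "glrlm_sre": st["small"],
        "glrlm_lre": st["large"],
        "glrlm_gln": st["gln"],
        "glrlm_glnn": st["glnn"],
        "glrlm_rln": st["sn"],
        "glrlm_rlnn": st["snn"],
        "glrlm_rp": st["Ns"] / (n_vox * len(directions)),
        "glrlm_lgre": st["low_gray"],
        "glrlm_hgre": st["high_gray"],
        "glrlm_srlge": st["small_low"],
        "glrlm_srhge": st["small_high"],
        "glrlm_lrlge": st["large_low"],
        "glrlm_lrhge": st["large_high"],
        "glrlm_glv": st["gl_var"],
        "glrlm_rlv": st["s_var"],
        "glrlm_re": st["entropy"],
    }


_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def size_zone_matrix(levels: np.ndarray) -> np.ndarray:
    """GLSZM: entry [g-1, s-1] counts 26-connected zones of level g with
    exactly s voxels."""
    lv = np.asarray(levels)
    ng = int(lv.max())
    if ng < 1:
        raise ValueError("quantized ROI is empty")
    n_vox = int((lv > 0).sum())
    mat = np.zeros((ng, n_vox), dtype=np.int64)
    for g in range(1, ng + 1):
        lab, n_zones = ndimage.label(lv == g, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(mat[g - 1], sizes - 1, 1)
    used = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : used[-1] + 1]


def glszm_features(quantized: QuantizedROI) -> dict[str, float]:
    lv = quantized.levels
    P = size_zone_matrix(lv)
    st = _weighted_stats(P)
    n_vox = int((lv > 0).sum())
    return {
        "glszm_sae": st["small"],
        "glszm_lae": st["large"],
        "glszm_gln": st["gln"],
        "glszm_glnn": st["glnn"],
        "glszm_szn": st["sn"],
        "glszm_sznn": st["snn"],
        "glszm_zp": st["Ns"] / n_vox,
        "glszm_lgze": st["low_gray"],
        "glszm_hgze": st["high_gray"],
        "glszm_salge": st["small_low"],
        "glszm_sahge": st["small_high"],
        "glszm_lalge": st["large_low"],
        "glszm_lahge": st["large_high"],
        "glszm_glv": st["gl_var"],
        "glszm_zv": st["s_var"],
        "glszm_ze": st["entropy"],
    }


def ngtdm_table(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_i and summed absolute differences s_i
    from the mean of the 26-neighborhood (in-mask neighbors only).

    Only voxels with at least one in-mask neighbor contribute.
    """
    lv = np.asarray(levels, dtype=float)
    inmask = lv > 0
    kernel = _STRUCT_26.copy()
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.convolve(lv * inmask, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(inmask.astype(float), kernel, mode="constant", cval=0.0)
    valid = inmask & (nb_cnt > 0)
    if not valid.any():
        raise ValueError("no in-mask voxel has an in-mask neighbor")
    ng = int(lv.max())
    n = np.zeros(ng)
    s = np.zeros(ng)
    abar = nb_sum[valid] / nb_cnt[valid]
    vals = lv[valid]
    for i in range(1, ng + 1):
        sel = vals == i
        n[i - 1] = sel.sum()
        s[i - 1] = np.abs(i - abar[sel]).sum()
    return n, s


def ngtdm_features(quantized: QuantizedROI) -> dict[str, float]:
    n, s = ngtdm_table(quantized.levels)
    N = n.sum()
    p = n / N
    ng = len(p)
    i = np.arange(1, ng + 1, dtype=float)
    nz = p > 0
    ngp = int(nz.sum())

    ps = float((p * s).sum())
    coarseness = min(1.0 / ps, COARSENESS_CAP) if ps > 0 else COARSENESS_CAP

    if ngp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum()
            / (ngp * (ngp - 1))
            * (s.sum() / N)
        )
        ipi = i * p
        denom = float(
            np.abs(ipi[nz][:, None] - ipi[nz][None, :]).sum()
        )
        busyness = ps / denom if denom > 0 else 0.0
        both = nz[:, None] & nz[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            cplx = np.abs(ii - jj) * (
                (pi * s[:, None] + pj * s[None, :]) / (pi + pj)
            )
        complexity = float(cplx[both].sum() / N)
        ssum = float(s.sum())
        strength = (
            float(((pi + pj) * (ii - jj) ** 2)[both].sum()) / ssum
            if ssum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
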