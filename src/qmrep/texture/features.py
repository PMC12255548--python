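"""IBSI-compliant texture features from the four matrix classes.

59 features per source image: 24 gray level co-occurrence (GLCM), 16 run
length (GLRLM), 14 dependence (GLDM) and 5 neighboring gray tone difference
(NGTDM) features.  Gray levels enter the formulas as their discretized bin
numbers; entropies use base-2 logarithms; co-occurrence and run-length
features are computed per in-plane direction and averaged.

Degenerate windows (a single gray level, or no co-occurring pair) follow the
common library conventions: correlation-type features evaluate to 1 and
difference-type features to 0.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "FEATURE_NAMES",
    "glcm_features",
    "glrlm_features",
    "gldm_features",
    "ngtdm_features",
]

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

#: All 59 (class, name) identifiers, in canonical order.
FEATURE_NAMES = (
    tuple(("GLCM", n) for n in GLCM_NAMES)
    + tuple(("GLRLM", n) for n in GLRLM_NAMES)
    + tuple(("GLDM", n) for n in GLDM_NAMES)
    + tuple(("NGTDM", n) for n in NGTDM_NAMES)
)
assert len(FEATURE_NAMES) == 59


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _glcm_dir(p: np.ndarray, g: np.ndarray) -> dict:
    """24 co-occurrence features of one normalized symmetric matrix ``p``
    over present gray levels ``g`` (bin numbers, sorted)."""
    ng = len(g)
    i = g[:, None]
    j = g[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((g * px).sum())
    uy = float((g * py).sum())
    sigx = float(np.sqrt(((g - ux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((g - uy) ** 2 * py).sum()))

    gmin, gmax = int(g[0]), int(g[-1])
    sum_idx = (i + j).astype(int) - 2 * gmin           # 0 .. 2(gmax-gmin)
    diff_idx = np.abs(i - j).astype(int)               # 0 .. gmax-gmin
    p_sum = np.zeros(2 * (gmax - gmin) + 1)
    np.add.at(p_sum, sum_idx, p)
    k_sum = np.arange(p_sum.size) + 2 * gmin
    p_diff = np.zeros(gmax - gmin + 1)
    np.add.at(p_diff, diff_idx, p)
    k_diff = np.arange(p_diff.size)

    da = float((k_diff * p_diff).sum())
    out = {
        "Autocorrelation": float((i * j * p).sum()),
        "ClusterProminence": float(((i + j - ux - uy) ** 4 * p).sum()),
        "ClusterShade": float(((i + j - ux - uy) ** 3 * p).sum()),
        "ClusterTendency": float(((i + j - ux - uy) ** 2 * p).sum()),
        "Contrast": float(((i - j) ** 2 * p).sum()),
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "InverseVariance": float((p_diff[1:] / k_diff[1:] ** 2).sum()) if p_diff.size > 1 else 0.0,
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": _entropy2(p.ravel()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float(((g - ux) ** 2 * px).sum()),
    }
    if sigx > 0 and sigy > 0:
        out["Correlation"] = float(((i * j * p).sum() - ux * uy) / (sigx * sigy))
    else:
        out["Correlation"] = 1.0  # single-level convention
    hx = _entropy2(px)
    hy = _entropy2(py)
    hxy = out["JointEntropy"]
    outer = np.outer(px, py)
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-(p[pos] * np.log2(outer[pos])).sum())
    hxy2 = _entropy2(outer.ravel())
    denom = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    inner = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["Imc2"] = float(np.sqrt(max(inner, 0.0)))
    if ng < 2:
        out["MCC"] = 1.0
    else:
        keep = px > 0
        if keep.sum() < 2:
            out["MCC"] = 1.0
        else:
            ps = p[np.ix_(keep, keep)]
            pxs = px[keep]
            pys = py[keep]
            # Q(a,b) = sum_k p(a,k) p(b,k) / (px(a) py(k))
            w = ps / pys[None, :]
            q = (ps @ w.T) / pxs[:, None]
            ev = np.sort(np.abs(np.linalg.eigvals(q)))
            out["MCC"] = float(np.sqrt(max(ev[-2], 0.0))) if ev.size >= 2 else 1.0
    return out


def glcm_features(counts: np.ndarray, g: np.ndarray) -> dict:
    """Direction-averaged co-occurrence features.

    ``counts``: (n_dir, Ng, Ng) symmetric pair counts.  Directions with no
    pair fall back to a single-entry matrix at the lowest present level
    (degenerate-window convention).
    """
    per_dir = []
    for d in range(counts.shape[0]):
        total = counts[d].sum()
        if total > 0:
            p = counts[d] / total
        else:
            p = np.zeros_like(counts[d])
            p[0, 0] = 1.0
        per_dir.append(_glcm_dir(p, g))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


def _glrlm_dir(mat: np.ndarray, g: np.ndarray, n_pix: int) -> dict:
    nr = float(mat.sum())
    if nr == 0:
        mat = mat.copy()
        mat[0, 0] = 1.0
        nr = 1.0
    r = np.arange(1, mat.shape[1] + 1, dtype=float)
    gl = g[:, None]
    rl = r[None, :]
    p = mat / nr
    pg = mat.sum(axis=1) / nr
    pr = mat.sum(axis=0) / nr
    mu_g = float((g * pg).sum())
    mu_r = float((r * pr).sum())
    return {
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((mat.sum(axis=1) ** 2).sum() / nr**2),
        "GrayLevelVariance": float(((g - mu_g) ** 2 * pg).sum()),
        "HighGrayLevelRunEmphasis": float((mat * gl**2).sum() / nr),
        "LongRunEmphasis": float((mat * rl**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((mat * gl**2 * rl**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((mat * rl**2 / gl**2).sum() / nr),
        "LowGrayLevelRunEmphasis": float((mat / gl**2).sum() / nr),
        "RunEntropy": _entropy2(p.ravel()),
        "RunLengthNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((mat.sum(axis=0) ** 2).sum() / nr**2),
        "RunPercentage": float(nr / n_pix) if n_pix > 0 else 0.0,
        "RunVariance": float(((r - mu_r) ** 2 * pr).sum()),
        "ShortRunEmphasis": float((mat / rl**2).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((mat * gl**2 / rl**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((mat / (gl**2 * rl**2)).sum() / nr),
    }


def glrlm_features(counts: np.ndarray, g: np.ndarray, n_pix: int) -> dict:
    """Direction-averaged run-length features; ``n_pix`` is the number of
    valid voxels in the window."""
    per_dir = [_glrlm_dir(counts[d], g, n_pix) for d in range(counts.shape[0])]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


def gldm_features(mat: np.ndarray, g: np.ndarray) -> dict:
    """14 dependence features; ``mat`` is (Ng, 9) with dependence j = col+1."""
    nz = float(mat.sum())
    if nz == 0:
        raise ValueError("dependence matrix is empty")
    jj = np.arange(1, mat.shape[1] + 1, dtype=float)
    gl = g[:, None]
    jl = jj[None, :]
    p = mat / nz
    pg = mat.sum(axis=1) / nz
    pj = mat.sum(axis=0) / nz
    mu_g = float((g * pg).sum())
    mu_j = float((jj * pj).sum())
    return {
        "DependenceEntropy": _entropy2(p.ravel()),
        "DependenceNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((mat.sum(axis=0) ** 2).sum() / nz**2),
        "DependenceVariance": float(((jj - mu_j) ** 2 * pj).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelVariance": float(((g - mu_g) ** 2 * pg).sum()),
        "HighGrayLevelEmphasis": float((mat * gl**2).sum() / nz),
        "LargeDependenceEmphasis": float((mat * jl**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * gl**2 * jl**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * jl**2 / gl**2).sum() / nz),
        "LowGrayLevelEmphasis": float((mat / gl**2).sum() / nz),
        "SmallDependenceEmphasis": float((mat / jl**2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * gl**2 / jl**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (gl**2 * jl**2)).sum() / nz),
    }


def ngtdm_features(n: np.ndarray, p: np.ndarray, s: np.ndarray, g: np.ndarray) -> dict:
    """5 neighboring gray tone difference features."""
    present = n > 0
    gi = g[present].astype(float)
    pi = p[present]
    si = s[present]
    ngp = len(gi)
    nvp = float(n.sum())
    out = {k: 0.0 for k in NGTDM_NAMES}
    if nvp == 0:
        out["Coarseness"] = 1e6
        return out
    psum = float((pi * si).sum())
    out["Coarseness"] = float(1.0 / psum) if psum > 0 else 1e6
    out["Coarseness"] = min(out["Coarseness"], 1e6)
    if ngp > 1:
        gdiff2 = (gi[:, None] - gi[None, :]) ** 2
        out["Contrast"] = float(
            (pi[:, None] * pi[None, :] * gdiff2).sum()
            / (ngp * (ngp - 1))
            * (si.sum() / nvp)
        )
        bus_den = float(np.abs(gi[:, None] * pi[:, None] - gi[None, :] * pi[None, :]).sum())
        out["Busyness"] = float(psum / bus_den) if bus_den > 0 else 0.0
        pij = pi[:, None] + pi[None, :]
        out["Complexity"] = float(
            (np.abs(gi[:, None] - gi[None, :])
             * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
             / pij).sum() / nvp
        )
        s_den = float(si.sum())
        out["Strength"] = float((pij * gdiff2).sum() / s_den) if s_den > 0 else 0.0
    return out
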