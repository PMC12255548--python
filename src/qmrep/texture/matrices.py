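"""Texture-matrix builders on small 2-D windows.

All builders operate on a 2-D integer label grid (output of fixed-bin-width
discretization, labels >= 1) with a parallel boolean validity grid; invalid
voxels (outside the analysis mask or cropped away) contribute nothing and
break co-occurrence pairs and runs.

The in-plane direction set is the four distance-1 offsets (0, 45, 90,
135 degrees).  Co-occurrence matrices are symmetric; dependence uses the
8-neighborhood with zero tolerance (a neighbor is dependent iff its label is
equal); the neighborhood gray-tone difference uses the mean over existing
valid 8-neighbors.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DIRECTIONS_2D", "glcm", "glrlm", "gldm", "ngtdm"]

#: Distance-1 in-plane offsets: 0, 45, 90, 135 degrees (row, col).
DIRECTIONS_2D = ((0, 1), (1, 1), (1, 0), (1, -1))

NEIGHBORS_8 = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def _level_index(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Map label values to indices into ``levels`` (assumed sorted)."""
    return np.searchsorted(levels, labels)


def glcm(labels: np.ndarray, valid: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Symmetric gray level co-occurrence counts per direction.

    Returns an array of shape ``(4, Ng, Ng)`` of pair counts (each unordered
    pair counted in both orders).  A pair contributes only if both voxels
    are valid.
    """
    ng = len(levels)
    idx = _level_index(labels, levels)
    out = np.zeros((len(DIRECTIONS_2D), ng, ng))
    nr, nc = labels.shape
    for d, (dr, dc) in enumerate(DIRECTIONS_2D):
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = valid[r0:r1, c0:c1] & valid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        np.add.at(out[d], (a[ok], b[ok]), 1.0)
    # symmetrize: count each pair in both orders
    out += out.transpose(0, 2, 1)
    return out


def glrlm(labels: np.ndarray, valid: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Gray level run length counts per direction.

    Returns ``(4, Ng, Nr)`` with ``Nr`` the longest possible run
    (max window side).  A run is a maximal set of consecutive valid voxels
    of equal label along the direction; invalid voxels break runs.
    """
    ng = len(levels)
    idx = _level_index(labels, levels)
    nr_, nc_ = labels.shape
    max_run = max(nr_, nc_)
    out = np.zeros((len(DIRECTIONS_2D), ng, max_run))

    def lines(dr, dc):
        if (dr, dc) == (0, 1):
            for r in range(nr_):
                yield [(r, c) for c in range(nc_)]
        elif (dr, dc) == (1, 0):
            for c in range(nc_):
                yield [(r, c) for r in range(nr_)]
        elif (dr, dc) == (1, 1):
            for s in range(-(nc_ - 1), nr_):
                yield [
                    (r, r - s)
                    for r in range(max(0, s), min(nr_, s + nc_))
                ]
        else:  # (1, -1)
            for s in range(nr_ + nc_ - 1):
                yield [
                    (r, s - r)
                    for r in range(max(0, s - nc_ + 1), min(nr_, s + 1))
                ]

    for d, (dr, dc) in enumerate(DIRECTIONS_2D):
        mat = out[d]
        for line in lines(dr, dc):
            run_label = -1
            run_len = 0
            for (r, c) in line:
                if valid[r, c] and idx[r, c] == run_label:
                    run_len += 1
                else:
                    if run_len:
                        mat[run_label, run_len - 1] += 1.0
                    if valid[r, c]:
                        run_label, run_len = idx[r, c], 1
                    else:
                        run_label, run_len = -1, 0
            if run_len:
                mat[run_label, run_len - 1] += 1.0
    return out


def gldm(labels: np.ndarray, valid: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Gray level dependence counts.

    ``P[i, j]`` is the number of valid voxels with level index ``i`` and
    ``j`` = (number of equal-label valid 8-neighbors) + 1, so every valid
    voxel contributes exactly once and ``j`` starts at 1 (column 0).
    """
    ng = len(levels)
    idx = _level_index(labels, levels)
    nr, nc = labels.shape
    dep = np.zeros(labels.shape, dtype=int)
    for dr, dc in NEIGHBORS_8:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        same = (
            (idx[r0:r1, c0:c1] == idx[r0 + dr : r1 + dr, c0 + dc : c1 + dc])
            & valid[r0:r1, c0:c1]
            & valid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        )
        dep[r0:r1, c0:c1] += same
    out = np.zeros((ng, 9))  # dependence j-1 in 0..8
    np.add.at(out, (idx[valid], dep[valid]), 1.0)
    return out


def ngtdm(labels: np.ndarray, valid: np.ndarray, levels: np.ndarray):
    """Neighboring gray tone difference statistics.

    Returns ``(n, p, s)`` per present level: voxel counts, probabilities and
    summed absolute differences from the mean of the existing valid
    8-neighbors.  Voxels without any valid neighbor are excluded.
    """
    ng = len(levels)
    idx = _level_index(labels, levels)
    vals = labels.astype(float)
    nr, nc = labels.shape
    nb_sum = np.zeros(labels.shape)
    nb_cnt = np.zeros(labels.shape)
    for dr, dc in NEIGHBORS_8:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        ok = valid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        nb_sum[r0:r1, c0:c1] += np.where(ok, vals[r0 + dr : r1 + dr, c0 + dc : c1 + dc], 0.0)
        nb_cnt[r0:r1, c0:c1] += ok
    use = valid & (nb_cnt > 0)
    diff = np.zeros(labels.shape)
    diff[use] = np.abs(vals[use] - nb_sum[use] / nb_cnt[use])
    n = np.zeros(ng)
    s = np.zeros(ng)
    np.add.at(n, idx[use], 1.0)
    np.add.at(s, idx[use], diff[use])
    total = n.sum()
    p = n / total if total > 0 else n
    return n, p, s
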