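"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately use naive per-element enumeration (loops over voxel
pairs, runs, neighborhoods, candidate thresholds) so that they share no
code path with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

DIRECTIONS_2D = ((0, 1), (1, 1), (1, 0), (1, -1))
NEIGHBORS_8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def bf_glcm(labels, valid, levels):
    """Symmetric co-occurrence counts by looping over every voxel pair."""
    ng = len(levels)
    lut = {int(g): i for i, g in enumerate(levels)}
    nr, nc = labels.shape
    out = np.zeros((4, ng, ng))
    for d, (dr, dc) in enumerate(DIRECTIONS_2D):
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc and valid[r, c] and valid[r2, c2]:
                    i, j = lut[int(labels[r, c])], lut[int(labels[r2, c2])]
                    out[d, i, j] += 1
                    out[d, j, i] += 1
    return out


def bf_glrlm(labels, valid, levels):
    """Run-length counts by walking every line and grouping runs."""
    from itertools import groupby

    ng = len(levels)
    lut = {int(g): i for i, g in enumerate(levels)}
    nr, nc = labels.shape
    max_run = max(nr, nc)
    out = np.zeros((4, ng, max_run))

    def coords(d):
        if d == (0, 1):
            return [[(r, c) for c in range(nc)] for r in range(nr)]
        if d == (1, 0):
            return [[(r, c) for r in range(nr)] for c in range(nc)]
        if d == (1, 1):
            lines = []
            for s in range(-(nc - 1), nr):
                lines.append(
                    [(r, r - s) for r in range(nr) if 0 <= r - s < nc]
                )
            return lines
        lines = []
        for s in range(nr + nc - 1):
            lines.append([(r, s - r) for r in range(nr) if 0 <= s - r < nc])
        return lines

    for d_idx, d in enumerate(DIRECTIONS_2D):
        for line in coords(d):
            tokens = [
                int(labels[r, c]) if valid[r, c] else None for (r, c) in line
            ]
            for key, grp in groupby(tokens):
                if key is None:
                    continue
                out[d_idx, lut[key], len(list(grp)) - 1] += 1
    return out


def bf_gldm(labels, valid, levels):
    """Dependence counts by looping over voxels and their 8-neighborhoods."""
    ng = len(levels)
    lut = {int(g): i for i, g in enumerate(levels)}
    nr, nc = labels.shape
    out = np.zeros((ng, 9))
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            dep = 0
            for dr, dc in NEIGHBORS_8:
                r2, c2 = r + dr, c + dc
                if (
                    0 <= r2 < nr and 0 <= c2 < nc
                    and valid[r2, c2]
                    and labels[r2, c2] == labels[r, c]
                ):
                    dep += 1
            out[lut[int(labels[r, c])], dep] += 1
    return out


def bf_ngtdm(labels, valid, levels):
    """Neighborhood gray-tone difference stats by per-voxel loops."""
    ng = len(levels)
    lut = {int(g): i for i, g in enumerate(levels)}
    nr, nc = labels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            nb = [
                labels[r + dr, c + dc]
                for dr, dc in NEIGHBORS_8
                if 0 <= r + dr < nr and 0 <= c + dc < nc and valid[r + dr, c + dc]
            ]
            if not nb:
                continue
            i = lut[int(labels[r, c])]
            n[i] += 1
            s[i] += abs(labels[r, c] - np.mean(nb))
    total = n.sum()
    p = n / total if total else n
    return n, p, s


def bf_yen_threshold(values):
    """Exhaustive sweep of Yen's maximum-correlation criterion over all 256
    histogram bin boundaries; returns the threshold (bin center)."""
    lo, hi = float(np.min(values)), float(np.max(values))
    counts, edges = np.histogram(values, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    best_crit, best_t = -np.inf, centers[0]
    for t in range(1, len(p)):
        p1 = p[:t].sum()
        p2 = 1.0 - p1
        s1 = (p[:t] ** 2).sum()
        s2 = (p[t:] ** 2).sum()
        if s1 <= 0 or s2 <= 0 or p1 <= 0 or p2 <= 0:
            continue
        crit = -np.log(s1 * s2) + 2.0 * np.log(p1 * p2)
        if crit > best_crit:
            best_crit, best_t = crit, centers[t - 1]
    return best_t


def bf_erode(mask, radius_mm, spacing):
    """Erosion by checking, per voxel, every voxel-center within radius."""
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    half = np.floor(radius_mm / spacing).astype(int)
    offsets = [
        (i, j, k)
        for i in range(-half[0], half[0] + 1)
        for j in range(-half[1], half[1] + 1)
        for k in range(-half[2], half[2] + 1)
        if (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2
        <= radius_mm**2 + 1e-12
    ]
    out = np.zeros_like(mask)
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                ok = True
                for i, j, k in offsets:
                    x2, y2, z2 = x + i, y + j, z + k
                    if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz) or not mask[x2, y2, z2]:
                        ok = False
                        break
                out[x, y, z] = ok
    return out


def ivim_contamination_bounds(f, d, dstar, b_values, b_min=200.0):
    """Closed-form bounds on the segmented-IVIM errors caused by the
    neglected pseudo-diffusion compartment.

    The high-b log-signal perturbation is
    ``delta(b) = ln(1 + (f/(1-f)) e^{-b (D*-D)}) <= dmax`` with ``dmax``
    evaluated at ``b_min``; ordinary least squares amplifies it into the
    slope by ``sum|b-bbar| / sum (b-bbar)^2`` and into the intercept by
    ``1/n + bbar sum|b-bbar| / sum (b-bbar)^2``.  Returns
    ``(d_bound, f_bound)`` (absolute errors; arrays broadcast).
    """
    b = np.asarray(b_values, dtype=float)
    bh = b[b >= b_min]
    bbar = bh.mean()
    lev = np.abs(bh - bbar).sum() / ((bh - bbar) ** 2).sum()
    dmax = (f / (1.0 - f)) * np.exp(-bh.min() * (dstar - d))
    d_bound = dmax * lev
    c_bound = dmax * (1.0 / len(bh) + bbar * lev)
    f_bound = (1.0 - f) * np.expm1(c_bound)
    return d_bound, f_bound


def rician_mean(nu, sigma):
    """Closed-form mean of a Rician variable (Bessel-function form)."""
    from scipy.special import i0e, i1e

    a = nu**2 / (4.0 * sigma**2)
    # mean = sigma sqrt(pi/2) L_{1/2}(-nu^2/(2 sigma^2))
    #      = sigma sqrt(pi/2) [(1 + 2a) I0(a) + 2a I1(a)] e^{-a}
    l_half = (1.0 + 2.0 * a) * i0e(a) + 2.0 * a * i1e(a)
    return sigma * np.sqrt(np.pi / 2.0) * l_half
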