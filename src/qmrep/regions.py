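"""Region derivation and set algebra for prostate zone analysis.

The analysis regions are the whole gland (WG), the peripheral zone (PZ), the
non-peripheral zone (nPZ = WG minus PZ), tumor, and benign (WG minus tumor).
The WG contour is eroded by 1 mm in 3-D before use, so that contouring error
at the gland boundary does not leak non-prostate tissue into the statistics;
the tumor mask is obtained by Yen's automatic histogram threshold on a tumor
probability map, restricted to the eroded gland.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_yen

from .volume import ImageVolume

__all__ = ["RegionSet", "erode_region", "yen_threshold", "derive_regions"]

log = logging.getLogger(__name__)

REGION_NAMES = ("WG", "PZ", "nPZ", "tumor", "benign")


@dataclass
class RegionSet:
    """Boolean masks for WG, PZ, nPZ, tumor and benign on a common grid.

    Invariants (checked on construction): ``npz = wg & ~pz``,
    ``benign = wg & ~tumor``, ``tumor ⊆ wg``, ``pz ∩ npz = ∅``.
    """

    wg: np.ndarray
    pz: np.ndarray
    npz: np.ndarray
    tumor: np.ndarray
    benign: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wg", "pz", "npz", "tumor", "benign"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shape = self.wg.shape
        for name in ("pz", "npz", "tumor", "benign"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"region {name!r} is not aligned with WG")
        if not np.array_equal(self.npz, self.wg & ~self.pz):
            raise ValueError("nPZ must equal WG minus PZ")
        if not np.array_equal(self.benign, self.wg & ~self.tumor):
            raise ValueError("benign must equal WG minus tumor")
        if np.any(self.tumor & ~self.wg):
            raise ValueError("tumor must be a subset of WG")
        if np.any(self.pz & self.npz):
            raise ValueError("PZ and nPZ must be disjoint")

    def __getitem__(self, name: str) -> np.ndarray:
        key = {"WG": "wg", "PZ": "pz", "nPZ": "npz", "tumor": "tumor", "benign": "benign"}
        try:
            return getattr(self, key[name])
        except KeyError:
            raise KeyError(f"unknown region {name!r}; expected one of {REGION_NAMES}")

    def counts(self) -> dict[str, int]:
        return {name: int(self[name].sum()) for name in REGION_NAMES}


def ball_element(radius_mm: float, spacing) -> np.ndarray:
    """Discretized ball structuring element for anisotropic spacing.

    A voxel belongs to the element iff its center lies within ``radius_mm``
    of the center voxel in physical (mm) coordinates.
    """
    spacing = np.asarray(spacing, dtype=float)
    half = np.floor(radius_mm / spacing).astype(int)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_mm**2 + 1e-12


def erode_region(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Morphological erosion of ``mask`` by a physical-radius ball.

    Radius 0 is the identity.  An erosion that empties the mask is allowed
    but logged as a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius_mm < 0:
        raise ValueError("erosion radius must be >= 0")
    if radius_mm == 0:
        return mask.copy()
    selem = ball_element(radius_mm, spacing)
    out = ndimage.binary_erosion(mask, structure=selem, border_value=0)
    if mask.any() and not out.any():
        log.warning("erosion by %.3g mm emptied a %d-voxel mask", radius_mm, mask.sum())
    return out


def yen_threshold(prob: ImageVolume | np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Threshold a probability map by maximizing Yen's criterion.

    The histogram uses 256 bins over the masked min-max range; voxels within
    ``mask`` whose probability exceeds the maximizing threshold are selected.
    A constant map within the mask admits no separating threshold and yields
    an empty mask with a warning.
    """
    values = prob.values if isinstance(prob, ImageVolume) else np.asarray(prob)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    sample = values[mask]
    if not np.all(np.isfinite(sample)):
        raise ValueError("probability map must be finite within the mask")
    lo, hi = float(sample.min()), float(sample.max())
    if hi <= lo:
        log.warning("constant probability map within mask; returning empty tumor mask")
        return np.zeros_like(mask)
    counts, edges = np.histogram(sample, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    thr = float(threshold_yen(hist=(counts, centers)))
    out = np.zeros_like(mask)
    out[mask] = values[mask] > thr
    return out


def derive_regions(
    wg: np.ndarray,
    pz: np.ndarray,
    tumor_prob: ImageVolume,
    spacing=None,
    erosion_mm: float = 1.0,
) -> RegionSet:
    """Build the full :class:`RegionSet` from raw WG/PZ masks and a tumor
    probability map.

    The WG is eroded by ``erosion_mm`` (default 1 mm) in 3-D; nPZ is the
    eroded WG minus PZ; the tumor mask is the Yen threshold of the
    probability map intersected with the eroded WG; benign is the eroded WG
    minus tumor.  A PZ that is not a subset of the eroded WG is clipped, with
    the clipped voxel count logged.
    """
    if spacing is None:
        spacing = tumor_prob.spacing
    wg = np.asarray(wg, dtype=bool)
    pz = np.asarray(pz, dtype=bool)
    prob_vals = tumor_prob.values if isinstance(tumor_prob, ImageVolume) else tumor_prob
    if np.nanmin(prob_vals) < 0 or np.nanmax(prob_vals) > 1:
        raise ValueError("tumor probability values must lie in [0, 1]")
    wg_er = erode_region(wg, erosion_mm, spacing)
    clipped = int(np.sum(pz & ~wg_er))
    if clipped:
        log.info("clipped %d PZ voxels outside the eroded WG", clipped)
    pz_in = pz & wg_er
    npz = wg_er & ~pz_in
    if not npz.any():
        log.warning("nPZ is empty (PZ covers the eroded WG)")
    masked_vals = prob_vals[wg_er]
    if wg_er.any() and masked_vals.max() > masked_vals.min():
        tumor = yen_threshold(tumor_prob, wg_er)
    else:
        tumor = np.zeros_like(wg_er)
    tumor &= wg_er
    benign = wg_er & ~tumor
    return RegionSet(wg=wg_er, pz=pz_in, npz=npz, tumor=tumor, benign=benign)
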