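"""Voxel-wise texture-feature map extraction.

Pipeline per source image (the T2w volume and the six parametric maps):

1. resample to 1 mm isotropic resolution (trilinear; nearest-neighbor for
   masks);
2. normalize: per-volume z-score scaled by 100 and clipped to [-300, 300];
3. discretize with a fixed bin width of 20 gray-level units, anchored at the
   volume-global masked minimum;
4. slide a 5 x 5 mm in-plane window over every masked voxel of every slice,
   crop the window at slice edges and to the mask, and evaluate all 59
   texture features of the window, writing each to its feature map.

With 7 source images this yields 7 x 59 = 413 feature maps per session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..volume import ImageVolume
from . import matrices
from .features import (
    FEATURE_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    ngtdm_features,
)

__all__ = [
    "FeatureMap",
    "resample_isotropic",
    "normalize_image",
    "discretize",
    "window_features",
    "extract_voxel_features",
]


@dataclass
class FeatureMap:
    """A voxel-wise texture-feature map with provenance metadata."""

    volume: ImageVolume
    source_quantity: str
    feature_class: str
    feature_name: str
    valid: np.ndarray

    @property
    def key(self) -> str:
        return f"{self.source_quantity}|{self.feature_class}|{self.feature_name}"

    @property
    def values(self) -> np.ndarray:
        return self.volume.values


def resample_isotropic(
    volume: ImageVolume, target: float = 1.0, is_mask: bool = False
) -> ImageVolume:
    """Resample to isotropic ``target`` mm voxels.

    Trilinear interpolation for intensity volumes, nearest-neighbor for
    masks.  A volume already at the target spacing is returned unchanged
    (copied).  Grids share the first-voxel-center origin convention.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if np.allclose(volume.spacing, (target,) * 3):
        return volume.copy()
    new_shape = tuple(
        max(1, int(round(n * s / target))) for n, s in zip(volume.shape, volume.spacing)
    )
    coords = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(new_shape, volume.spacing)],
        indexing="ij",
    )
    order = 0 if is_mask else 1
    vals = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float), np.array(coords), order=order,
        mode="nearest",
    )
    if is_mask:
        vals = vals > 0.5
    return ImageVolume(vals, (target,) * 3)


def normalize_image(volume: ImageVolume, scale: float = 100.0) -> ImageVolume:
    """Per-volume z-score normalization scaled and clipped.

    ``(x - mean) / sd * scale`` (population sd), clipped to
    ``[-3 scale, +3 scale]`` so the default scale of 100 yields gray values
    in [-300, 300].  Raises on zero intensity spread.
    """
    vals = np.asarray(volume.values, dtype=float)
    finite = np.isfinite(vals)
    mean = vals[finite].mean()
    sd = vals[finite].std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot normalize a volume with zero intensity spread")
    out = (vals - mean) / sd * scale
    out = np.clip(out, -3.0 * scale, 3.0 * scale)
    out[~finite] = np.nan
    return volume.with_values(out)


def discretize(
    volume: ImageVolume | np.ndarray,
    bin_width: float = 20.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Fixed-bin-width discretization anchored at the masked global minimum.

    ``label = floor((x - min_in_mask) / bin_width) + 1``; labels are
    contiguous from 1.  Returns an integer grid (0 outside the mask).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = volume.values if isinstance(volume, ImageVolume) else np.asarray(volume)
    if mask is None:
        mask = np.isfinite(vals)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(vals)
    out = np.zeros(vals.shape, dtype=np.int32)
    if not mask.any():
        return out
    lo = vals[mask].min()
    out[mask] = np.floor((vals[mask] - lo) / bin_width).astype(np.int32) + 1
    return out


def window_features(labels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """All 59 texture features of one discretized 2-D window.

    ``labels``: integer grid (>= 1 where valid); ``valid``: boolean grid.
    Returns the feature values in :data:`FEATURE_NAMES` order.  This is the
    single-window primitive the voxel-wise extractor applies at every voxel,
    and doubles as a standalone oracle target.
    """
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValueError("window has no valid voxel")
    levels = np.unique(labels[valid]).astype(float)
    n_pix = int(valid.sum())
    gl = glcm_features(matrices.glcm(labels, valid, levels), levels)
    rl = glrlm_features(matrices.glrlm(labels, valid, levels), levels, n_pix)
    dm = gldm_features(matrices.gldm(labels, valid, levels), levels)
    n, p, s = matrices.ngtdm(labels, valid, levels)
    nt = ngtdm_features(n, p, s, levels)
    byclass = {"GLCM": gl, "GLRLM": rl, "GLDM": dm, "NGTDM": nt}
    return np.array([byclass[cls][name] for cls, name in FEATURE_NAMES])


def extract_voxel_features(
    volume: ImageVolume,
    mask: np.ndarray,
    kernel_mm: float = 5.0,
    bin_width: float = 20.0,
    source_quantity: str = "",
    normalized: bool = True,
) -> list[FeatureMap]:
    """Sliding-window texture-feature maps of one source image.

    ``volume`` must already be resampled (isotropic in-plane) and, unless
    ``normalized=False``, normalized.  For each masked voxel a 2-D in-plane
    window of ``kernel_mm`` (5 x 5 voxels at 1 mm) centered on it —
    cropped at slice edges and intersected with the mask — is evaluated with
    :func:`window_features`.  Returns the 59 :class:`FeatureMap`s.
    """
    mask = np.asarray(mask, dtype=bool) & np.isfinite(volume.values)
    if not mask.any():
        raise ValueError("mask is empty")
    if not normalized:
        volume = normalize_image(volume)
    k = int(round(kernel_mm / volume.spacing[0]))
    if k < 3:
        raise ValueError(f"kernel of {kernel_mm} mm spans {k} < 3 voxels")
    half = k // 2
    labels = discretize(volume, bin_width=bin_width, mask=mask)
    nx, ny, nz = volume.shape
    out = np.full((59,) + volume.shape, np.nan)
    for z in range(nz):
        sl_mask = mask[:, :, z]
        if not sl_mask.any():
            continue
        sl_labels = labels[:, :, z]
        rows, cols = np.nonzero(sl_mask)
        for r, c in zip(rows, cols):
            r0, r1 = max(0, r - half), min(nx, r + half + 1)
            c0, c1 = max(0, c - half), min(ny, c + half + 1)
            out[:, r, c, z] = window_features(
                sl_labels[r0:r1, c0:c1], sl_mask[r0:r1, c0:c1]
            )
    maps = []
    for idx, (cls, name) in enumerate(FEATURE_NAMES):
        vals = out[idx]
        maps.append(
            FeatureMap(
                volume=volume.with_values(vals),
                source_quantity=source_quantity,
                feature_class=cls,
                feature_name=name,
                valid=mask & np.isfinite(vals),
            )
        )
    return maps
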