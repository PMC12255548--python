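"""Core image containers and NIfTI I/O.

Every image in the pipeline — acquired volumes, region masks, fitted
parametric maps and texture-feature maps — is carried as an
:class:`ImageVolume`: a 3-D scalar grid with per-axis voxel spacing (mm) and
an affine orientation.  Multi-point acquisitions (diffusion b-values,
gradient-echo echo times, variable flip angles) are ordered stacks of aligned
volumes, :class:`AcquisitionSeries`.  Fitted quantities are
:class:`ParametricMap`s: a value grid plus an authoritative boolean validity
grid; invalid voxels carry NaN and are excluded from all downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "AcquisitionSeries",
    "ParametricMap",
    "read_volume",
    "write_volume",
    "QUANTITY_UNITS",
]

#: Units of the supported map quantities.
QUANTITY_UNITS = {
    "ADC": "mm^2/s",
    "D": "mm^2/s",
    "f": "1",
    "HS": "1",
    "R2*": "1/s",
    "T1": "ms",
    "T2w": "a.u.",
}


@dataclass
class ImageVolume:
    """A 3-D scalar grid with voxel spacing and orientation.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.  NaN marks invalid voxels.
    spacing : tuple of float
        Per-axis voxel size in mm; strictly positive.
    affine : ndarray (4, 4), optional
        Voxel-to-world transform.  Defaults to a diagonal affine built from
        ``spacing`` with the origin at zero.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"ImageVolume requires a 3-D grid, got {self.values.ndim}-D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def aligned_with(self, other: "ImageVolume") -> bool:
        """Two volumes are aligned iff shape, spacing and orientation match."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine)
        )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.spacing, self.affine.copy())

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """A new volume on the same grid carrying ``values``."""
        return ImageVolume(np.asarray(values), self.spacing, self.affine.copy())


@dataclass
class AcquisitionSeries:
    """An ordered stack of aligned volumes along an acquisition axis.

    ``axis_kind`` is one of ``"b-value"`` (s/mm^2), ``"echo-time"`` (ms) or
    ``"flip-angle"`` (degrees); ``axis_values`` are strictly increasing.
    ``repetition_time`` (ms) is required for the flip-angle kind, where the
    SPGR steady state depends on TR.
    """

    volumes: list[ImageVolume]
    axis_kind: str
    axis_values: np.ndarray
    repetition_time: float | None = None

    def __post_init__(self) -> None:
        if self.axis_kind not in ("b-value", "echo-time", "flip-angle"):
            raise ValueError(f"unknown axis kind {self.axis_kind!r}")
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        if len(self.volumes) != self.axis_values.size:
            raise ValueError("one axis value per volume required")
        if np.any(np.diff(self.axis_values) <= 0):
            raise ValueError("axis values must be strictly increasing")
        if self.axis_kind == "b-value" and np.any(self.axis_values < 0):
            raise ValueError("b-values must be >= 0")
        if self.axis_kind == "echo-time" and np.any(self.axis_values <= 0):
            raise ValueError("echo times must be > 0")
        if self.axis_kind == "flip-angle":
            if np.any((self.axis_values <= 0) | (self.axis_values > 90)):
                raise ValueError("flip angles must lie in (0, 90] degrees")
            if self.repetition_time is None or self.repetition_time <= 0:
                raise ValueError("flip-angle series requires a positive TR (ms)")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if not v.aligned_with(ref):
                raise ValueError("all volumes in a series must be aligned")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def reference(self) -> ImageVolume:
        return self.volumes[0]

    def stack(self) -> np.ndarray:
        """Signal array of shape (n_points, nx, ny, nz)."""
        return np.stack([v.values for v in self.volumes], axis=0)


@dataclass
class ParametricMap:
    """A fitted quantity per voxel with a validity mask.

    ``valid`` is the authoritative record of fit success; invalid voxels hold
    NaN in ``values`` and are excluded from every statistic downstream.
    """

    volume: ImageVolume
    quantity: str
    valid: np.ndarray | None = None
    units: str = field(default="")

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.volume.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.volume.shape:
            raise ValueError("valid grid must match the volume shape")
        if not self.units:
            self.units = QUANTITY_UNITS.get(self.quantity, "")
        # NaN is the sentinel: force it wherever the fit is flagged invalid.
        vals = np.asarray(self.volume.values, dtype=float).copy()
        vals[~self.valid] = np.nan
        self.volume = replace(self.volume, values=vals)

    @property
    def values(self) -> np.ndarray:
        return self.volume.values

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape

    def valid_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Finite values inside ``mask`` (whole grid if None)."""
        sel = self.valid if mask is None else (self.valid & mask)
        return self.volume.values[sel]


def read_volume(path) -> ImageVolume:
    """Read a 3-D NIfTI-1 volume.

    Raises
    ------
    ValueError
        If the payload is not 3-D or the header spacing is non-finite or
        non-positive; the message names the offending file.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable file → report with path
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D payload, got {data.ndim} dimensions"
        )
    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-finite or non-positive voxel spacing {zooms}")
    return ImageVolume(data, tuple(float(z) for z in zooms), np.asarray(img.affine))


def write_volume(volume: ImageVolume, path) -> str:
    """Write an :class:`ImageVolume` as NIfTI-1; returns the path written.

    The round trip through :func:`read_volume` preserves finite values,
    spacing and orientation bit-exactly (float64 payload).
    """
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return str(path)
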