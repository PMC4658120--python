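"""3D volume containers, file I/O, resampling and in-plane downsampling.

Coordinate convention: array axes 0, 1, 2 correspond to the x, y, z axes of
the scanner frame, voxel indices are 0-based, and the physical position of
voxel ``(i, j, k)`` is ``origin + index * spacing``.  Volumes with a
non-identity direction matrix (oblique/rotated geometry) are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from spinevb.errors import (
    DimensionalityError,
    MissingLabelError,
    ParameterError,
    VolumeFormatError,
)

__all__ = [
    "Volume3D",
    "LabelVolume",
    "CenterAnnotation",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_centers",
    "write_centers",
    "compute_center",
    "resample_volume",
    "downsample_inplane",
]


@dataclass
class Volume3D:
    """A scalar 3D image on a regular grid with anisotropic voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units), axes (x, y, z).
    spacing
        Physical size of one voxel per axis, in mm.
    slice_axis
        Array axis perpendicular to the acquisition slices.  Sagittal MR
        volumes have slices parallel to the YZ plane (``slice_axis=0``);
        axial CT volumes have slices parallel to the XY plane
        (``slice_axis=2``).
    origin
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: np.ndarray
    slice_axis: int = 0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"volume data must be 3D, got {self.data.ndim}D"
            )
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ParameterError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.slice_axis not in (0, 1, 2):
            raise ParameterError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def inplane_axes(self) -> tuple[int, int]:
        """The two array axes lying within an acquisition slice."""
        return tuple(a for a in (0, 1, 2) if a != self.slice_axis)

    def physical(self, index: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of (possibly fractional) voxel indices."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def to_index(self, position: np.ndarray) -> np.ndarray:
        """Continuous voxel index of a physical position (mm)."""
        return (np.asarray(position, dtype=float) - self.origin) / self.spacing


@dataclass
class LabelVolume(Volume3D):
    """Integer-coded VB mask sharing the grid of its paired :class:`Volume3D`.

    Voxel value 0 is background; value ``i`` marks the i-th vertebral body,
    named by ``vb_names[i - 1]``.
    """

    vb_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ParameterError("label volume data must be integer-typed")


@dataclass
class CenterAnnotation:
    """Ordered ground-truth or detected VB center coordinates in mm."""

    centers: np.ndarray
    vb_names: list[str]

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if len(self.vb_names) != len(self.centers):
            raise ParameterError("one name per center required")
        if not np.all(np.isfinite(self.centers)):
            raise ParameterError("center coordinates must be finite")

    def __len__(self) -> int:
        return len(self.centers)


_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mhd", ".mha")


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format: {path.name!r} "
            f"(expected one of {_SUPPORTED_SUFFIXES})"
        )
    return path


def read_volume(path: str | Path, slice_axis: int = 0) -> Volume3D:
    """Read a NIfTI or MetaImage file into a :class:`Volume3D`.

    ``slice_axis`` is explicit caller input: the acquisition orientation is
    not recoverable from the voxel grid alone.
    """
    path = _check_path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - SimpleITK message detail
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D image, got {img.GetDimension()}D"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise VolumeFormatError(
            f"{path.name}: non-identity orientation matrices are not supported"
        )
    # GetArrayFromImage yields (z, y, x); transpose to our (x, y, z) axes.
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Volume3D(
        data=data,
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        slice_axis=slice_axis,
        origin=np.asarray(img.GetOrigin(), dtype=float),
    )


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume to NIfTI or MetaImage, preserving grid geometry."""
    path = _check_path(path)
    img = sitk.GetImageFromArray(np.transpose(vol.data, (2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def read_labels(
    path: str | Path, slice_axis: int = 0, vb_names: list[str] | None = None
) -> LabelVolume:
    """Read an integer-coded VB mask volume."""
    vol = read_volume(path, slice_axis=slice_axis)
    data = np.rint(vol.data).astype(np.int32)
    if vb_names is None:
        vb_names = [f"VB{i}" for i in range(1, int(data.max()) + 1)]
    return LabelVolume(
        data=data, spacing=vol.spacing, slice_axis=slice_axis,
        origin=vol.origin, vb_names=vb_names,
    )


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    write_volume(
        Volume3D(labels.data.astype(np.int16), labels.spacing,
                 labels.slice_axis, labels.origin),
        path,
    )


def read_centers(path: str | Path) -> CenterAnnotation:
    """Read an ordered VB-center annotation from JSON.

    The file holds records ``{"vb_names": [...], "centers_mm": [[x,y,z],...]}``.
    """
    with open(path) as fh:
        payload = json.load(fh)
    return CenterAnnotation(
        centers=np.asarray(payload["centers_mm"], dtype=float),
        vb_names=list(payload["vb_names"]),
    )


def write_centers(annotation: CenterAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "vb_names": list(annotation.vb_names),
                "centers_mm": np.asarray(annotation.centers).tolist(),
            },
            fh,
            indent=2,
        )


def compute_center(labels: LabelVolume, vb_index: int) -> np.ndarray:
    """Geometrical center (mm) of the voxels carrying label ``vb_index``.

    This is the ground-truth definition used throughout: the centroid of
    the delineated VB region converted to physical coordinates.
    """
    idx = np.argwhere(labels.data == vb_index)
    if idx.size == 0:
        raise MissingLabelError(f"label {vb_index} not present in volume")
    return labels.physical(idx.mean(axis=0))


def resample_volume(vol: Volume3D, target_spacing) -> Volume3D:
    """Resample to ``target_spacing`` (mm), covering the same physical extent.

    Intensities are linearly interpolated; :class:`LabelVolume` inputs use
    nearest-neighbor interpolation and return a :class:`LabelVolume`.
    """
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ParameterError(f"target spacing must be 3 positive values, got {target}")
    is_labels = isinstance(vol, LabelVolume)
    if np.allclose(target, vol.spacing):
        out_data = vol.data.copy()
    else:
        new_shape = np.maximum(
            1, np.rint(np.asarray(vol.shape) * vol.spacing / target).astype(int)
        )
        grids = np.meshgrid(
            *[np.arange(n) * t / s for n, t, s in zip(new_shape, target, vol.spacing)],
            indexing="ij",
        )
        coords = np.stack([g.ravel() for g in grids])
        order = 0 if is_labels else 1
        out_data = ndimage.map_coordinates(
            vol.data, coords, order=order, mode="nearest"
        ).reshape(tuple(new_shape))
    if is_labels:
        return LabelVolume(out_data.astype(vol.data.dtype), target,
                           vol.slice_axis, vol.origin.copy(),
                           vb_names=list(vol.vb_names))
    return Volume3D(out_data, target, vol.slice_axis, vol.origin.copy())


def downsample_inplane(vol: Volume3D, factor: int) -> Volume3D:
    """Reduce the two in-plane axes by ``factor`` with block averaging.

    The slice axis keeps its resolution ("maintain the inter-slice
    resolution"); the in-plane spacing is multiplied by ``factor``.  Axis
    lengths not divisible by ``factor`` are trimmed at the high end before
    averaging.  Block averaging (rather than decimation) anti-aliases the
    coarse image, and the origin is shifted so each output voxel sits at
    the physical center of its source block.
    """
    if int(factor) != factor or factor < 1:
        raise ParameterError(f"downsampling factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return Volume3D(vol.data.copy(), vol.spacing.copy(), vol.slice_axis,
                        vol.origin.copy())
    ax0, ax1 = vol.inplane_axes
    shape = list(vol.shape)
    trimmed = [slice(None)] * 3
    for ax in (ax0, ax1):
        trimmed[ax] = slice(0, (shape[ax] // factor) * factor)
    data = vol.data[tuple(trimmed)].astype(float)
    # reshape-mean over factor-sized blocks along both in-plane axes
    for ax in (ax0, ax1):
        shp = list(data.shape)
        shp[ax] //= factor
        shp.insert(ax + 1, factor)
        data = data.reshape(shp).mean(axis=ax + 1)
    spacing = vol.spacing.copy()
    origin = vol.origin.copy()
    for ax in (ax0, ax1):
        spacing[ax] *= factor
        origin[ax] += (factor - 1) / 2.0 * vol.spacing[ax]
    return Volume3D(data, spacing, vol.slice_axis, origin)
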