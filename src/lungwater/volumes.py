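"""3D volume and mask containers, NIfTI I/O, and the package axis convention.

Every array in this package lives on a fixed anatomical frame:

* axis 0 — coronal slice index, running anterior -> posterior,
* axis 1 — row, running superior -> inferior,
* axis 2 — column, running subject-right -> subject-left.

In nibabel's orientation-code language this is the ``('P', 'I', 'L')`` frame.
Voxel indexing is 0-based and a voxel's physical position is the position of
its center; physical offsets are converted to voxel units through ``spacing``
(millimetres per voxel along each axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "AXIS_CODES",
    "LABELS",
    "Volume",
    "LabelMask",
    "LungSegmentation",
    "read_volume",
    "read_label_mask",
    "write_volume",
    "reslice_sagittal",
]

#: nibabel orientation codes of the package frame (anterior->posterior,
#: superior->inferior, right->left).
AXIS_CODES = ("P", "I", "L")

#: Tissue label vocabulary used by :class:`LabelMask`.
LABELS = {
    "background": 0,
    "body": 1,
    "right_lung": 2,
    "left_lung": 3,
    "liver": 4,
    "airway": 5,
}

#: Default isotropic voxel size (mm) of the acquisition this package targets.
DEFAULT_SPACING = (3.5, 3.5, 3.5)


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing on the package anatomical frame.

    Parameters
    ----------
    data
        3D array of non-negative, finite intensities (arbitrary signal units).
    spacing
        Voxel size in mm per axis ``(ds, dr, dc)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if not np.isfinite(self.data).all():
            raise ValueError("Volume contains non-finite voxels")
        if np.any(self.data < 0):
            raise ValueError("Volume contains negative intensities")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_isotropic(self, rtol: float = 0.01) -> bool:
        s = np.asarray(self.spacing)
        return bool(np.all(np.abs(s - s[0]) <= rtol * s[0]))


@dataclass
class LabelMask:
    """Integer tissue labels on the same lattice as a paired :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelMask data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMask data must be an integer array")
        bad = set(np.unique(self.data)) - set(LABELS.values())
        if bad:
            raise ValueError(f"labels outside the vocabulary: {sorted(bad)}")
        self.spacing = _check_spacing(self.spacing)

    def mask(self, name: str) -> np.ndarray:
        """Binary mask of one named tissue."""
        return self.data == LABELS[name]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LungSegmentation:
    """Disjoint binary right/left lung masks on a volume grid."""

    right_mask: np.ndarray
    left_mask: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.right_mask = np.asarray(self.right_mask, dtype=bool)
        self.left_mask = np.asarray(self.left_mask, dtype=bool)
        if self.right_mask.shape != self.left_mask.shape:
            raise ValueError("right/left masks must share a grid")
        if self.right_mask.ndim != 3:
            raise ValueError("lung masks must be 3D")
        if np.any(self.right_mask & self.left_mask):
            raise ValueError("right and left lung masks overlap")
        self.spacing = _check_spacing(self.spacing)

    @property
    def both(self) -> np.ndarray:
        return self.right_mask | self.left_mask

    @property
    def voxel_counts(self) -> tuple[int, int]:
        return int(self.right_mask.sum()), int(self.left_mask.sum())

    @property
    def volume_liters(self) -> float:
        """Total segmented lung volume in liters (count x voxel volume)."""
        n = int(self.both.sum())
        return n * float(np.prod(self.spacing)) * 1e-6

    def to_label_mask(self) -> LabelMask:
        lab = np.zeros(self.right_mask.shape, dtype=np.int16)
        lab[self.right_mask] = LABELS["right_lung"]
        lab[self.left_mask] = LABELS["left_lung"]
        return LabelMask(lab, self.spacing)


def _package_affine(spacing) -> np.ndarray:
    """RAS affine of a volume stored on the (P, I, L) package frame."""
    ds, dr, dc = spacing
    aff = np.zeros((4, 4))
    aff[1, 0] = -ds  # axis 0 increases posterior  => decreasing A
    aff[2, 1] = -dr  # axis 1 increases inferior   => decreasing S
    aff[0, 2] = -dc  # axis 2 increases toward left => decreasing R
    aff[3, 3] = 1.0
    return aff


def _load_reoriented(path):
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    ornt = nib.orientations.ornt_transform(
        nib.orientations.io_orientation(img.affine),
        nib.orientations.axcodes2ornt(AXIS_CODES),
    )
    data = nib.orientations.apply_orientation(np.asanyarray(img.dataobj), ornt)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    # ornt[i, 0] is the output position of input axis i; invert it for zooms
    spacing = tuple(zooms[np.argsort(ornt[:, 0].astype(int))])
    return data, spacing


def read_volume(path) -> Volume:
    """Read a 3D NIfTI file and reorient it to the package frame.

    Header orientation codes are honored: the stored array is permuted and
    flipped so axis 0 runs anterior->posterior, axis 1 superior->inferior and
    axis 2 right->left. Spacing is taken from the header zooms.
    """
    data, spacing = _load_reoriented(path)
    return Volume(np.ascontiguousarray(data, dtype=np.float64), spacing)


def read_label_mask(path) -> LabelMask:
    """Read a NIfTI label volume (see :data:`LABELS`) on the package frame."""
    data, spacing = _load_reoriented(path)
    return LabelMask(np.ascontiguousarray(np.rint(data).astype(np.int16)), spacing)


def write_volume(volume: Volume | LabelMask, path) -> None:
    """Write a Volume or LabelMask as NIfTI-1, preserving dtype and spacing."""
    data = volume.data
    if isinstance(volume, LabelMask):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _package_affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_array(data: np.ndarray, spacing, path) -> None:
    """Write a raw 3D array as NIfTI on the package frame.

    Unlike :func:`write_volume` this performs no value checks; it exists for
    derived maps (e.g. an LWD overlay with a negative sentinel outside the
    lungs) that are display products, not signal volumes.
    """
    spacing = _check_spacing(spacing)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _package_affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def reslice_sagittal(volume: Volume) -> Volume:
    """Permute an isotropic coronal stack into the sagittal view.

    Output axes: axis 0 right->left, axis 1 superior->inferior,
    axis 2 anterior->posterior. This is a pure permutation — no interpolation,
    voxel values unchanged — and therefore requires isotropic voxels (within
    1%); permuting an anisotropic grid would distort geometry.
    """
    if not volume.is_isotropic():
        raise ValueError(
            f"reslice_sagittal requires isotropic spacing, got {volume.spacing}"
        )
    data = np.transpose(volume.data, (2, 1, 0))
    s = volume.spacing
    return Volume(np.ascontiguousarray(data), (s[2], s[1], s[0]))
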