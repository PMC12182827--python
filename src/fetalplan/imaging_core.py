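"""Coordinate systems, volume/grid types, and shared geometric primitives.

Conventions used throughout the package:

* Voxel indices are 0-based; bounding boxes are half-open ``[lower, upper)``.
* The patient (world) frame is RAS+ in millimetres: x grows to the patient's
  Right, y to Anterior, z to Superior.  NIfTI files are read through their
  sform (qform as fallback, with a logged warning on disagreement).
* Fractional voxel coordinates are allowed in coordinate transforms;
  nearest-neighbour sampling is used only where integer labels are resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, GridMismatchError, InvalidInputError

log = logging.getLogger(__name__)

#: Canonical landmark structure names (tubular ones can yield keypoints).
LANDMARK_NAMES = ("UV", "DAo", "DAo-D", "H-L", "AP-L", "spine")
TUBULAR_NAMES = ("UV", "DAo", "spine")

#: Default integer codes for the landmark label map.
DEFAULT_LANDMARK_CODES: dict[str, int] = {
    "UV": 1, "DAo": 2, "DAo-D": 3, "H-L": 4, "AP-L": 5, "spine": 6,
}
BODY_CODES: dict[str, int] = {"body": 1}


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image plus the affine mapping voxel indices to patient mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units.
    affine : ndarray, shape (4, 4)
        Maps homogeneous 0-based voxel indices to RAS+ patient coordinates
        in millimetres.  Must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise InvalidInputError(f"data must be 3D, got ndim={data.ndim}")
        if affine.shape != (4, 4):
            raise InvalidInputError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ConfigurationError("affine is singular")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "ImageVolume | LabelMap") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass(frozen=True)
class LabelMap:
    """Integer-labelled volume sharing an :class:`ImageVolume` grid."""

    labels: np.ndarray
    affine: np.ndarray
    label_codes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        affine = np.asarray(self.affine, dtype=float)
        if labels.ndim != 3:
            raise InvalidInputError("labels must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise InvalidInputError("labels must be an integer array")
        if affine.shape != (4, 4):
            raise InvalidInputError("affine must be 4x4")
        present = set(np.unique(labels)) - {0}
        known = set(int(v) for v in self.label_codes.values())
        if not present <= known:
            raise InvalidInputError(
                f"labels {sorted(present - known)} missing from label_codes"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "label_codes", dict(self.label_codes))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "ImageVolume | LabelMap") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def code(self, name: str) -> int:
        return int(self.label_codes[name])

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of one named structure."""
        return self.labels == self.code(name)

    def has(self, name: str) -> bool:
        return name in self.label_codes and bool(np.any(self.mask(name)))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel box, inclusive lower / exclusive upper indices."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self):
        lo = tuple(int(v) for v in self.lower)
        up = tuple(int(v) for v in self.upper)
        if any(l >= u for l, u in zip(lo, up)):
            raise InvalidInputError(f"empty bounding box {lo}..{up}")
        if any(l < 0 for l in lo):
            raise InvalidInputError("bounding box lower corner negative")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))  # type: ignore[return-value]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(u - l for l, u in zip(self.lower, self.upper))  # type: ignore[return-value]

    def contains_box(self, other: "BoundingBox") -> bool:
        return all(
            sl <= ol and ou <= su
            for sl, ol, ou, su in zip(self.lower, other.lower, other.upper, self.upper)
        )

    @staticmethod
    def full(shape: tuple[int, int, int]) -> "BoundingBox":
        return BoundingBox((0, 0, 0), tuple(int(s) for s in shape))


# ---------------------------------------------------------------------------
# Coordinate transforms


def voxel_to_patient(index, volume: ImageVolume | LabelMap) -> np.ndarray:
    """Map (fractional) voxel indices to patient coordinates in mm.

    ``index`` may be a single triple or an (N, 3) array; the result has the
    matching shape.
    """
    idx = np.asarray(index, dtype=float)
    if not np.all(np.isfinite(idx)):
        raise InvalidInputError("non-finite voxel index")
    single = idx.ndim == 1
    pts = np.atleast_2d(idx)
    out = pts @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    return out[0] if single else out


def patient_to_voxel(point, volume: ImageVolume | LabelMap) -> np.ndarray:
    """Inverse of :func:`voxel_to_patient` (no clipping to the grid)."""
    pt = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(pt)):
        raise InvalidInputError("non-finite patient point")
    try:
        inv = np.linalg.inv(volume.affine)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in ctor
        raise ConfigurationError("affine is singular") from exc
    single = pt.ndim == 1
    pts = np.atleast_2d(pt)
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if single else out


def crop_to_box(volume: ImageVolume, box: BoundingBox) -> ImageVolume:
    """Crop a volume; retained voxels keep their patient coordinates.

    The output affine's translation is shifted so that output voxel (0,0,0)
    maps to the patient position of the box's lower corner in the input.
    """
    _check_box_in_grid(box, volume.shape)
    new_affine = volume.affine.copy()
    new_affine[:3, 3] = voxel_to_patient(np.asarray(box.lower, float), volume)
    return ImageVolume(volume.data[box.slices].copy(), new_affine)


def crop_labels_to_box(labels: LabelMap, box: BoundingBox) -> LabelMap:
    """Same as :func:`crop_to_box` for label maps."""
    _check_box_in_grid(box, labels.shape)
    new_affine = labels.affine.copy()
    new_affine[:3, 3] = voxel_to_patient(np.asarray(box.lower, float), labels)
    return LabelMap(labels.labels[box.slices].copy(), new_affine, labels.label_codes)


def _check_box_in_grid(box: BoundingBox, shape) -> None:
    if any(u > s for u, s in zip(box.upper, shape)):
        raise InvalidInputError(f"box {box} exceeds grid {tuple(shape)}")


def ras_to_lps(point) -> np.ndarray:
    """Convert an RAS+ point (or array of points) to LPS (DICOM patient).

    LPS negates the first two axes; the helper is its own inverse.
    """
    pt = np.asarray(point, dtype=float).copy()
    pt[..., 0] *= -1.0
    pt[..., 1] *= -1.0
    return pt


lps_to_ras = ras_to_lps


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine_from_nifti(img: nib.Nifti1Image) -> np.ndarray:
    sform, scode = img.get_sform(coded=True)
    qform, qcode = img.get_qform(coded=True)
    if scode > 0:
        if qcode > 0 and not np.allclose(sform, qform, atol=1e-3):
            log.warning("sform and qform disagree; using sform")
        return np.asarray(sform, float)
    if qcode > 0:
        return np.asarray(qform, float)
    return np.asarray(img.affine, float)


def load_volume(path) -> ImageVolume:
    """Read a NIfTI volume as float data + sform affine (RAS+ mm)."""
    img = nib.load(str(path))
    return ImageVolume(np.asanyarray(img.dataobj).astype(np.float64),
                       _affine_from_nifti(img))


def save_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.set_sform(volume.affine, code=1)
    img.set_qform(volume.affine, code=1)
    nib.save(img, str(path))


def load_labels(path, label_codes: Mapping[str, int]) -> LabelMap:
    """Read a NIfTI label map; ``label_codes`` names the integer labels."""
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded, atol=1e-3):
            raise InvalidInputError(f"{path}: non-integer label values")
        labels = rounded.astype(np.int32)
    return LabelMap(labels.astype(np.uint16), _affine_from_nifti(img), label_codes)


def save_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.uint16), labels.affine)
    img.set_sform(labels.affine, code=1)
    img.set_qform(labels.affine, code=1)
    nib.save(img, str(path))


def require_same_grid(a, b) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"grids differ: shape {a.shape} vs {b.shape} or affines differ"
        )
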