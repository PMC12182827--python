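"""Landmark keypoints from a cardiac-landmark label map.

Each structure gets a patient-frame center of mass; the tubular structures
(UV, DAo, spine) additionally get start/mid/end keypoints obtained by
projecting the labeled voxels on the first principal axis of their point
cloud:

* start / end — the points on the principal axis at the minimal and maximal
  voxel projections, so the start-to-end direction is the principal axis
  itself (far more stable against end-cap voxel quantization than picking
  single extreme voxels); "start" is the endpoint with the smaller patient z
  (inferior), a purely cosmetic convention since plane orientation is
  axis-unsigned;
* mid — centroid of the voxels whose projection lies within half a voxel
  spacing of the median projection (nearest labeled voxel when that slab is
  empty); the median is robust to uneven voxel density along the vessel and
  the slab centroid cancels cross-sectional quantization.

Structures with fewer than 3 voxels or a principal-extent anisotropy below
1.5 are rejected as degenerate: a near-spherical blob cannot orient a plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateLandmarkError,
    LandmarkDetectionError,
    MissingLandmarkError,
)
from .imaging_core import (
    LANDMARK_NAMES,
    TUBULAR_NAMES,
    BoundingBox,
    ImageVolume,
    LabelMap,
    crop_to_box,
    require_same_grid,
    voxel_to_patient,
)
from .localization import SegmentationBackend

MIN_TUBULAR_VOXELS = 3
MIN_ANISOTROPY = 1.5


@dataclass
class LandmarkSet:
    """Per-structure keypoints in patient mm (RAS+).

    ``com`` holds every present structure; ``keypoints`` holds
    start/mid/end for the tubular structures that passed the degeneracy
    check.  ``skipped`` records structures that were present but degenerate,
    with the reason.
    """

    com: dict[str, np.ndarray] = field(default_factory=dict)
    keypoints: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def present(self, structure: str) -> bool:
        return structure in self.com

    def has_keypoints(self, structure: str) -> bool:
        return structure in self.keypoints

    def to_json_dict(self) -> dict:
        return {
            "frame": "RAS",
            "units": "mm",
            "com": {k: v.tolist() for k, v in self.com.items()},
            "keypoints": {
                k: {p: q.tolist() for p, q in v.items()}
                for k, v in self.keypoints.items()
            },
            "skipped": dict(self.skipped),
        }

    @staticmethod
    def from_json_dict(d: dict) -> "LandmarkSet":
        return LandmarkSet(
            com={k: np.asarray(v, float) for k, v in d.get("com", {}).items()},
            keypoints={
                k: {p: np.asarray(q, float) for p, q in v.items()}
                for k, v in d.get("keypoints", {}).items()
            },
            skipped=dict(d.get("skipped", {})),
        )


def landmark_com(labels: LabelMap, structure: str) -> np.ndarray:
    """Unweighted mean of labeled voxel centers, in patient mm."""
    if structure not in labels.label_codes:
        raise MissingLandmarkError(structure)
    vox = np.argwhere(labels.mask(structure))
    if vox.size == 0:
        raise MissingLandmarkError(structure)
    return voxel_to_patient(vox.mean(axis=0), labels)


def tubular_keypoints(
    labels: LabelMap, structure: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(start, mid, end) patient points of a tubular structure."""
    if structure not in labels.label_codes:
        raise MissingLandmarkError(structure)
    vox = np.argwhere(labels.mask(structure))
    if vox.size == 0:
        raise MissingLandmarkError(structure)
    if len(vox) < MIN_TUBULAR_VOXELS:
        raise DegenerateLandmarkError(
            structure, f"{structure}: only {len(vox)} voxels"
        )
    pts = voxel_to_patient(vox.astype(float), labels)
    centered = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    # principal-extent anisotropy: singular values scale with extents
    if svals[0] < MIN_ANISOTROPY * max(svals[1], 1e-12):
        raise DegenerateLandmarkError(
            structure,
            f"{structure}: anisotropy {svals[0] / max(svals[1], 1e-12):.2f} < "
            f"{MIN_ANISOTROPY}",
        )
    axis = vt[0]
    proj = centered @ axis
    shell = 0.5 * float(labels.spacing.min())
    mean = pts.mean(axis=0)
    # endpoints on the principal axis at the extreme projections, so the
    # start->end direction is the principal axis itself
    p_lo = mean + proj.min() * axis
    p_hi = mean + proj.max() * axis
    med = np.median(proj)
    slab = np.abs(proj - med) <= shell
    if slab.any():
        mid = pts[slab].mean(axis=0)
    else:
        mid = pts[np.argmin(np.abs(proj - med))]
    # inferior-to-superior ordering of the endpoints
    start, end = (p_lo, p_hi) if p_lo[2] <= p_hi[2] else (p_hi, p_lo)
    return start, mid, end


def detect_landmarks(
    volume: ImageVolume,
    box: BoundingBox,
    backend: SegmentationBackend,
    structures: tuple[str, ...] = LANDMARK_NAMES,
) -> LandmarkSet:
    """Run the landmark backend on the thorax crop and extract keypoints.

    All outputs are in the original (uncropped) patient frame — cropping
    preserves patient coordinates by construction.  Raises
    :class:`LandmarkDetectionError` if the backend fails or no structure at
    all is found.
    """
    cropped = crop_to_box(volume, box)
    try:
        labels = backend(cropped)
    except Exception as exc:
        raise LandmarkDetectionError(f"landmark backend failed: {exc}") from exc
    require_same_grid(labels, cropped)

    out = LandmarkSet()
    for name in structures:
        if not labels.has(name):
            continue
        out.com[name] = landmark_com(labels, name)
        if name in TUBULAR_NAMES:
            try:
                start, mid, end = tubular_keypoints(labels, name)
            except DegenerateLandmarkError as exc:
                out.skipped[name] = str(exc)
            else:
                out.keypoints[name] = {"start": start, "mid": mid, "end": end}
    if not out.com:
        raise LandmarkDetectionError("no landmark structures detected")
    return out
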