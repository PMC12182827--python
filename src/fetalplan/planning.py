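"""Cross-sectional 2D phase-contrast plane prescriptions.

Through-plane flow is only quantitative when the slice is perpendicular to
the vessel, so the slice-select direction (the plane normal) is the vessel
axis: the unit vector from the start to the end keypoint of the vessel
segmentation.  The mid keypoint positions the slice.  For the descending
aorta, the thoracic spine can serve as an orientation surrogate (the two run
parallel at the lung level), which is more stable when the DAo segmentation
itself is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, InvalidInputError, MissingLandmarkError
from .landmarks import LandmarkSet

#: Patient anterior direction in RAS+ (used by the spine-surrogate fallback).
ANTERIOR = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class ScanProtocol:
    """Geometric acquisition parameters of the 2D PC slice."""

    fov_mm: tuple[float, float] = (300.0, 300.0)
    thickness_mm: float = 5.0
    min_vessel_length_mm: float = 3.0

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise InvalidInputError("thickness must be > 0")
        if any(f <= 0 for f in self.fov_mm):
            raise InvalidInputError("FOV must be > 0")


@dataclass(frozen=True)
class PlanePrescription:
    """A 2D PC slice in patient coordinates (RAS+, mm).

    ``normal`` is the slice-select direction; ``read_dir``/``phase_dir``
    complete a right-handed orthonormal triad spanning the slice.
    """

    vessel: str
    center: np.ndarray
    normal: np.ndarray
    read_dir: np.ndarray
    phase_dir: np.ndarray
    fov_mm: tuple[float, float] = (300.0, 300.0)
    thickness_mm: float = 5.0
    mode: str = "vessel"

    def __post_init__(self):
        for name in ("center", "normal", "read_dir", "phase_dir"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        basis = np.stack([self.read_dir, self.phase_dir, self.normal])
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-9):
            raise InvalidInputError("plane basis is not orthonormal")
        if np.linalg.det(basis) < 0:
            raise InvalidInputError("plane basis is left-handed")
        if self.thickness_mm <= 0:
            raise InvalidInputError("thickness must be > 0")

    def to_json_dict(self) -> dict:
        return {
            "vessel": self.vessel,
            "mode": self.mode,
            "center_mm": self.center.tolist(),
            "normal": self.normal.tolist(),
            "read_dir": self.read_dir.tolist(),
            "phase_dir": self.phase_dir.tolist(),
            "fov_mm": list(self.fov_mm),
            "thickness_mm": self.thickness_mm,
            "frame": "RAS",
        }


def inplane_basis(normal) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed in-plane basis for a slice normal.

    ``read_dir = normalize(a x normal)`` where ``a`` is the canonical patient
    axis least parallel to the normal (ties broken in x, y, z order);
    ``phase_dir = normal x read_dir``.  Any orthonormal completion spans the
    same slice; this one is simply fixed and reproducible.
    """
    n = np.asarray(normal, float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise InvalidInputError("zero normal")
    n = n / norm
    # least-parallel canonical axis; strict < keeps the x->y->z tie-break
    axis_idx = 0
    best = abs(n[0])
    for i in (1, 2):
        if abs(n[i]) < best - 1e-15:
            best = abs(n[i])
            axis_idx = i
    a = np.zeros(3)
    a[axis_idx] = 1.0
    read = np.cross(a, n)
    read /= np.linalg.norm(read)
    phase = np.cross(n, read)
    return read, phase


def plane_from_keypoints(
    start, mid, end, protocol: ScanProtocol = ScanProtocol(),
    vessel: str = "vessel", mode: str = "vessel",
) -> PlanePrescription:
    """Slice normal = unit(end - start); slice center = mid."""
    start = np.asarray(start, float)
    mid = np.asarray(mid, float)
    end = np.asarray(end, float)
    axis = end - start
    length = np.linalg.norm(axis)
    if length < protocol.min_vessel_length_mm:
        raise DegenerateGeometryError(
            f"{vessel}: start-end distance {length:.2f} mm below "
            f"{protocol.min_vessel_length_mm} mm"
        )
    normal = axis / length
    read, phase = inplane_basis(normal)
    return PlanePrescription(
        vessel=vessel,
        center=mid,
        normal=normal,
        read_dir=read,
        phase_dir=phase,
        fov_mm=protocol.fov_mm,
        thickness_mm=protocol.thickness_mm,
        mode=mode,
    )


def plan_uv(
    landmarks: LandmarkSet, protocol: ScanProtocol = ScanProtocol()
) -> PlanePrescription:
    """Umbilical-vein plane from the UV start/mid/end keypoints."""
    if not landmarks.has_keypoints("UV"):
        raise MissingLandmarkError(
            "UV", landmarks.skipped.get("UV", "UV keypoints absent")
        )
    kp = landmarks.keypoints["UV"]
    return plane_from_keypoints(
        kp["start"], kp["mid"], kp["end"], protocol, vessel="UV", mode="vessel"
    )


def plan_dao(
    landmarks: LandmarkSet,
    mode: str = "vessel",
    protocol: ScanProtocol = ScanProtocol(),
    anterior_offset_mm: float = 15.0,
) -> PlanePrescription:
    """Descending-aorta plane.

    ``mode='vessel'``: normal and center from the DAo keypoints.
    ``mode='spine-surrogate'``: normal from the spine keypoints (spine and
    DAo run parallel at the lung level); center = DAo center of mass when
    the DAo label exists, else the spine midpoint offset anteriorly by
    ``anterior_offset_mm`` (an anatomical prior for the DAo's position just
    anterior to the vertebral column).
    """
    if mode == "vessel":
        if not landmarks.has_keypoints("DAo"):
            raise MissingLandmarkError(
                "DAo", landmarks.skipped.get("DAo", "DAo keypoints absent")
            )
        kp = landmarks.keypoints["DAo"]
        return plane_from_keypoints(
            kp["start"], kp["mid"], kp["end"], protocol, vessel="DAo", mode="vessel"
        )
    if mode != "spine-surrogate":
        raise InvalidInputError(f"unknown DAo planning mode {mode!r}")
    if not landmarks.has_keypoints("spine"):
        raise MissingLandmarkError(
            "spine", landmarks.skipped.get("spine", "spine keypoints absent")
        )
    kp = landmarks.keypoints["spine"]
    axis = kp["end"] - kp["start"]
    length = np.linalg.norm(axis)
    if length < protocol.min_vessel_length_mm:
        raise DegenerateGeometryError("spine extent below minimum length")
    normal = axis / length
    if landmarks.present("DAo"):
        center = landmarks.com["DAo"]
    else:
        center = kp["mid"] + anterior_offset_mm * ANTERIOR
    read, phase = inplane_basis(normal)
    return PlanePrescription(
        vessel="DAo",
        center=center,
        normal=normal,
        read_dir=read,
        phase_dir=phase,
        fov_mm=protocol.fov_mm,
        thickness_mm=protocol.thickness_mm,
        mode="spine-surrogate",
    )
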