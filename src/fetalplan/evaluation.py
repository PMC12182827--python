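"""Segmentation-agreement and planning-quality metrics.

Dice, IoU and center-of-mass distance quantify agreement between two
segmentations of the same structure; :class:`PlanningError` is the
quantitative twin of subjective position/orientation scoring, possible on
phantoms because the true vessel geometry is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, MissingLandmarkError
from .imaging_core import LabelMap, require_same_grid
from .landmarks import landmark_com
from .phantom import PhantomGroundTruth, true_axis
from .planning import PlanePrescription


@dataclass(frozen=True)
class QualityScore:
    """Reviewer score: 0-poor, 1-fair, 2-optimal per aspect; max total 4."""

    position: int
    orientation: int

    def __post_init__(self):
        for v in (self.position, self.orientation):
            if v not in (0, 1, 2):
                raise InvalidInputError("scores must be 0, 1 or 2")

    @property
    def total(self) -> int:
        return self.position + self.orientation


@dataclass(frozen=True)
class PlanningError:
    """Geometric planning error against phantom ground truth.

    angular_error_deg : unsigned angle between the prescribed normal and the
        true vessel axis (axes are sign-invariant, so it lies in [0, 90]).
    center_offset_mm  : distance from the true vessel midpoint to the
        prescribed slice center.
    out_of_plane_mm   : component of that offset along the normal — the part
        that actually moves the slice off the vessel midpoint.
    """

    angular_error_deg: float
    center_offset_mm: float
    out_of_plane_mm: float


def _masks(a: LabelMap, b: LabelMap, label) -> tuple[np.ndarray, np.ndarray]:
    require_same_grid(a, b)
    name = label if isinstance(label, str) else None
    if name is not None:
        return a.labels == a.code(name), b.labels == b.code(name)
    return a.labels == int(label), b.labels == int(label)


def dice(a: LabelMap, b: LabelMap, label) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); both-empty defined as 1."""
    ma, mb = _masks(a, b, label)
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def iou(a: LabelMap, b: LabelMap, label) -> float:
    """Intersection over union |A∩B| / |A∪B|; both-empty defined as 1."""
    ma, mb = _masks(a, b, label)
    union = int((ma | mb).sum())
    if union == 0:
        return 1.0
    return int((ma & mb).sum()) / union


def com_distance(a: LabelMap, b: LabelMap, label) -> float:
    """Euclidean distance in mm between patient-frame centers of mass."""
    require_same_grid(a, b)
    name = label if isinstance(label, str) else _name_for(a, int(label))
    return float(np.linalg.norm(landmark_com(a, name) - landmark_com(b, name)))


def _name_for(m: LabelMap, code: int) -> str:
    for k, v in m.label_codes.items():
        if int(v) == code:
            return k
    raise MissingLandmarkError(str(code), f"no structure with code {code}")


def planning_error(p: PlanePrescription, gt: PhantomGroundTruth) -> PlanningError:
    """Compare a prescription with the phantom's true vessel geometry."""
    if p.vessel not in gt.tangents:
        raise MissingLandmarkError(p.vessel, f"{p.vessel} absent from ground truth")
    axis = true_axis(gt, p.vessel)
    cosang = np.clip(abs(float(p.normal @ axis)), 0.0, 1.0)
    true_mid = gt.keypoints[p.vessel]["mid"]
    offset = true_mid - p.center
    return PlanningError(
        angular_error_deg=float(np.degrees(np.arccos(cosang))),
        center_offset_mm=float(np.linalg.norm(offset)),
        out_of_plane_mm=float(abs(offset @ p.normal)),
    )
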