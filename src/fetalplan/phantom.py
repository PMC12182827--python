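"""Synthetic fetal-thorax phantom with analytically known geometry.

The phantom stands in for scanner data and for trained segmentation
networks: it produces a bright-blood-like anatomical volume, a fetal body
mask, a six-structure cardiac landmark label map, and the exact ground-truth
geometry (centerlines, keypoints, tangents) after an arbitrary rigid pose.
Because every quantity downstream of segmentation is geometric, plane
planning can be validated by parameter recovery against this ground truth.

Canonical anatomy (before the rigid pose; patient mm, RAS+, body centered at
the origin with its long axis along z):

* fetal body — ellipsoid;
* descending aorta (DAo) — a tube of configurable radius whose centerline is
  a circular arc in the x-z plane (curvature 0 gives a straight
  superior-inferior vessel), just anterior to the spine;
* umbilical vein (UV) — a straight oblique tube in the upper abdomen;
* spine — a straight tube parallel to the canonical DAo, posterior to it;
* DAo-D — a sphere at the inferior (diaphragm) end of the DAo;
* AP-L — two spheres at the lung apices;
* H-L — a thin elliptical slab at the heart-liver interface.

Tissue-class mean intensities are assigned per structure and the volume is
corrupted with Rician noise (magnitude of a complex Gaussian), the
appropriate model for low-SNR magnitude MR images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.spatial.transform import Rotation

from .errors import GenerationError
from .imaging_core import (
    BODY_CODES,
    DEFAULT_LANDMARK_CODES,
    ImageVolume,
    LabelMap,
    patient_to_voxel,
    voxel_to_patient,
)

Vec3 = tuple[float, float, float]


class PhantomConfig(BaseModel):
    """Full parameterization of the synthetic thorax.

    Defaults emulate a third-trimester fetal thorax imaged at 1.5 mm
    isotropic resolution on a low-field (0.55T-like, hence noisy) system.
    All lengths in mm; angles in degrees.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = Field(1.5, gt=0)

    # rigid pose applied to the whole fetus (rotation about the grid center)
    pose_rotation_deg: Vec3 = (0.0, 0.0, 0.0)
    pose_translation_mm: Vec3 = (0.0, 0.0, 0.0)

    body_semiaxes_mm: Vec3 = (38.0, 45.0, 58.0)

    dao_length_mm: float = Field(40.0, gt=0)
    dao_radius_mm: float = Field(3.0, gt=0)
    #: curvature of the DAo centerline arc (1/mm); 0 = straight.
    dao_curvature_per_mm: float = Field(0.0, ge=0)

    uv_length_mm: float = Field(30.0, gt=0)
    uv_radius_mm: float = Field(3.0, gt=0)
    #: UV direction as (polar from +z, azimuth from +x) in degrees.
    uv_direction_deg: tuple[float, float] = (50.0, 75.0)

    spine_length_mm: float = Field(44.0, gt=0)
    spine_radius_mm: float = Field(5.0, gt=0)

    dao_d_radius_mm: float = Field(4.0, gt=0)
    apl_radius_mm: float = Field(5.0, gt=0)
    hl_thickness_mm: float = Field(4.5, gt=0)

    noise_sigma: float = Field(8.0, ge=0)
    intensity_means: dict[str, float] = Field(
        default_factory=lambda: {
            "background": 30.0,
            "body": 100.0,
            "UV": 190.0,
            "DAo": 190.0,
            "DAo-D": 190.0,
            "H-L": 130.0,
            "AP-L": 60.0,
            "spine": 45.0,
        }
    )

    @model_validator(mode="after")
    def _check_lengths(self) -> "PhantomConfig":
        min_len = 4.0 * self.spacing_mm
        for name, length in (
            ("dao_length_mm", self.dao_length_mm),
            ("uv_length_mm", self.uv_length_mm),
            ("spine_length_mm", self.spine_length_mm),
        ):
            if length <= min_len:
                raise ValueError(f"{name} must exceed 4x spacing ({min_len} mm)")
        return self


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Exact post-pose geometry of the generated phantom.

    centerlines : per tubular structure, an (M, 3) polyline in patient mm.
    keypoints   : per tubular structure, true start/mid/end points (start is
                  the inferior end in the canonical frame).
    tangents    : per tubular structure, the unit centerline tangent at the
                  arc-length midpoint.
    """

    centerlines: dict[str, np.ndarray]
    keypoints: dict[str, dict[str, np.ndarray]]
    tangents: dict[str, np.ndarray]
    body_volume_mL: float
    body_center: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "centerlines": {k: v.tolist() for k, v in self.centerlines.items()},
            "keypoints": {
                k: {p: q.tolist() for p, q in v.items()}
                for k, v in self.keypoints.items()
            },
            "tangents": {k: v.tolist() for k, v in self.tangents.items()},
            "body_volume_mL": self.body_volume_mL,
            "body_center": self.body_center.tolist(),
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "frame": "RAS",
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @staticmethod
    def load(path) -> "PhantomGroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return PhantomGroundTruth(
            centerlines={k: np.asarray(v) for k, v in d["centerlines"].items()},
            keypoints={
                k: {p: np.asarray(q) for p, q in v.items()}
                for k, v in d["keypoints"].items()
            },
            tangents={k: np.asarray(v) for k, v in d["tangents"].items()},
            body_volume_mL=float(d["body_volume_mL"]),
            body_center=np.asarray(d["body_center"]),
            rotation=np.asarray(d["rotation"]),
            translation=np.asarray(d["translation"]),
        )


def true_axis(gt: PhantomGroundTruth, structure: str) -> np.ndarray:
    """Unit tangent of a tubular structure at its centerline midpoint."""
    if structure not in gt.tangents:
        raise KeyError(f"no tubular ground truth for structure {structure!r}")
    return gt.tangents[structure]


# ---------------------------------------------------------------------------
# canonical geometry helpers


def _dao_centerline(cfg: PhantomConfig, n: int = 65) -> np.ndarray:
    """Circular-arc centerline starting at the inferior end, tangent +z."""
    s0 = np.array([0.0, -12.0, -cfg.dao_length_mm / 2.0])
    s = np.linspace(0.0, cfg.dao_length_mm, n)
    k = cfg.dao_curvature_per_mm
    if k == 0.0:
        pts = s0 + np.outer(s, np.array([0.0, 0.0, 1.0]))
    else:
        r = 1.0 / k
        pts = s0 + np.stack(
            [r * (1.0 - np.cos(k * s)), np.zeros_like(s), r * np.sin(k * s)], axis=1
        )
    return pts


def _dao_tangent_mid(cfg: PhantomConfig) -> np.ndarray:
    k = cfg.dao_curvature_per_mm
    a = k * cfg.dao_length_mm / 2.0
    return np.array([np.sin(a), 0.0, np.cos(a)])


def _uv_centerline(cfg: PhantomConfig, n: int = 33) -> np.ndarray:
    pol, az = np.deg2rad(cfg.uv_direction_deg)
    d = np.array(
        [np.sin(pol) * np.cos(az), np.sin(pol) * np.sin(az), np.cos(pol)]
    )
    s0 = np.array([3.0, 14.0, -24.0])
    s = np.linspace(0.0, cfg.uv_length_mm, n)
    return s0 + np.outer(s, d)


def _spine_centerline(cfg: PhantomConfig, n: int = 45) -> np.ndarray:
    half = cfg.spine_length_mm / 2.0
    s = np.linspace(-half, half, n)
    return np.stack([np.zeros_like(s), np.full_like(s, -26.0), s], axis=1)


def _polyline_keypoints(line: np.ndarray) -> dict[str, np.ndarray]:
    """start / arc-length-mid / end of a polyline (start = first node)."""
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    mid = np.interp(arc[-1] / 2.0, arc, np.arange(len(line)))
    i = int(np.floor(mid))
    frac = mid - i
    mid_pt = line[i] if i + 1 >= len(line) else (1 - frac) * line[i] + frac * line[i + 1]
    return {"start": line[0], "mid": mid_pt, "end": line[-1]}


def _min_dist_to_polyline(points: np.ndarray, line: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline (union of segments)."""
    best = np.full(points.shape[0], np.inf)
    for a, b in zip(line[:-1], line[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.linalg.norm(points - a, axis=1)
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
            d = np.linalg.norm(points - a - np.outer(t, ab), axis=1)
        np.minimum(best, d, out=best)
    return best


# ---------------------------------------------------------------------------
# generation


def _center_affine(cfg: PhantomConfig) -> np.ndarray:
    """Isotropic affine placing the patient origin at the grid center."""
    aff = np.eye(4)
    aff[:3, :3] *= cfg.spacing_mm
    aff[:3, 3] = -cfg.spacing_mm * (np.asarray(cfg.shape) - 1) / 2.0
    return aff


def _pose(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    R = Rotation.from_euler("xyz", cfg.pose_rotation_deg, degrees=True).as_matrix()
    t = np.asarray(cfg.pose_translation_mm, float)
    return R, t


def _check_fits(name: str, pts_patient: np.ndarray, pad_mm: float,
                template: ImageVolume) -> None:
    vox = patient_to_voxel(pts_patient, template)
    pad = pad_mm / template.spacing.min()
    hi = np.asarray(template.shape) - 1
    if np.any(vox < pad - 0.5) or np.any(vox > hi - pad + 0.5):
        raise GenerationError(f"structure {name!r} exceeds the phantom grid")


def generate_phantom(
    config: PhantomConfig,
) -> tuple[ImageVolume, LabelMap, LabelMap, PhantomGroundTruth]:
    """Generate (image, body mask, landmark map, ground truth).

    Deterministic: the same config (including seed) yields byte-identical
    arrays and ground truth.
    """
    cfg = config
    R, t = _pose(cfg)
    affine = _center_affine(cfg)
    shape = tuple(cfg.shape)
    template = ImageVolume(np.zeros(shape, dtype=np.float32), affine)

    # patient coordinates of every voxel center, then canonical coordinates
    idx = np.ascontiguousarray(np.indices(shape, dtype=np.float32).reshape(3, -1).T)
    X = voxel_to_patient(idx, template)          # (N, 3) patient mm
    C = np.ascontiguousarray((X - t) @ R)        # R.T @ (x - t), row-vector form

    # canonical geometry
    dao_line = _dao_centerline(cfg)
    uv_line = _uv_centerline(cfg)
    spine_line = _spine_centerline(cfg)
    a, b, c = cfg.body_semiaxes_mm

    # fit checks (centerline nodes padded by tube radius; body apices)
    body_apices = np.array(
        [[a, 0, 0], [-a, 0, 0], [0, b, 0], [0, -b, 0], [0, 0, c], [0, 0, -c]],
        float,
    )
    _check_fits("body", body_apices @ R.T + t, 0.0, template)
    for name, line, rad in (
        ("DAo", dao_line, cfg.dao_radius_mm),
        ("UV", uv_line, cfg.uv_radius_mm),
        ("spine", spine_line, cfg.spine_radius_mm),
    ):
        _check_fits(name, line @ R.T + t, rad, template)

    # ---- body mask
    body = (((C / np.array([a, b, c])) ** 2).sum(axis=1) <= 1.0)

    # ---- landmark labels, first-wins precedence
    labels = np.zeros(C.shape[0], dtype=np.uint16)

    def paint(mask: np.ndarray, name: str) -> None:
        labels[(labels == 0) & mask] = DEFAULT_LANDMARK_CODES[name]

    def _candidates(line: np.ndarray, radius: float) -> np.ndarray:
        lo = line.min(axis=0) - radius - 2.0 * cfg.spacing_mm
        hi = line.max(axis=0) + radius + 2.0 * cfg.spacing_mm
        return np.flatnonzero(np.all((C >= lo) & (C <= hi), axis=1))

    def cylinder_mask(start, direction, length: float, radius: float) -> np.ndarray:
        """Finite cylinder with flat end caps (no protrusion past the
        centerline endpoints, keeping detected endpoints comparable to the
        ground-truth centerline)."""
        d = np.asarray(direction, float)
        line = np.stack([np.asarray(start, float),
                         np.asarray(start, float) + length * d])
        where = _candidates(line, radius)
        rel = C[where] - np.asarray(start, float)
        u = rel @ d
        radial2 = np.einsum("ij,ij->i", rel, rel) - u ** 2
        out = np.zeros(C.shape[0], dtype=bool)
        out[where] = (u >= 0.0) & (u <= length) & (radial2 <= radius * radius)
        return out

    def arc_tube_mask(line: np.ndarray, radius: float) -> np.ndarray:
        """DAo tube: straight cylinder at zero curvature, else the section
        of a torus swept by the circular-arc centerline (flat angular ends)."""
        k = cfg.dao_curvature_per_mm
        s0 = line[0]
        if k == 0.0:
            return cylinder_mask(s0, (0.0, 0.0, 1.0), cfg.dao_length_mm, radius)
        r_c = 1.0 / k
        center = s0 + np.array([r_c, 0.0, 0.0])
        where = _candidates(line, radius)
        rel = C[where] - center
        rho = np.hypot(rel[:, 0], rel[:, 2])
        dist2 = (rho - r_c) ** 2 + rel[:, 1] ** 2
        phi = np.arctan2(rel[:, 2], -rel[:, 0])  # 0 at start, k*L at end
        out = np.zeros(C.shape[0], dtype=bool)
        out[where] = (
            (dist2 <= radius * radius) & (phi >= 0.0) & (phi <= k * cfg.dao_length_mm)
        )
        return out

    def sphere_mask(center: Iterable[float], radius: float) -> np.ndarray:
        ctr = np.asarray(center, float)
        pad = radius + 2.0 * cfg.spacing_mm
        cand = np.all((C >= ctr - pad) & (C <= ctr + pad), axis=1)
        out = np.zeros(C.shape[0], dtype=bool)
        where = np.flatnonzero(cand)
        d = C[where] - ctr
        out[where] = np.einsum("ij,ij->i", d, d) <= radius * radius
        return out

    uv_dir0 = (uv_line[-1] - uv_line[0]) / np.linalg.norm(uv_line[-1] - uv_line[0])
    paint(cylinder_mask(uv_line[0], uv_dir0, cfg.uv_length_mm, cfg.uv_radius_mm),
          "UV")
    paint(arc_tube_mask(dao_line, cfg.dao_radius_mm), "DAo")
    paint(sphere_mask(dao_line[0], cfg.dao_d_radius_mm), "DAo-D")
    paint(
        cylinder_mask(spine_line[0], (0.0, 0.0, 1.0), cfg.spine_length_mm,
                      cfg.spine_radius_mm),
        "spine",
    )
    apl = sphere_mask((14.0, -2.0, 20.0), cfg.apl_radius_mm) | sphere_mask(
        (-14.0, -2.0, 20.0), cfg.apl_radius_mm
    )
    paint(apl, "AP-L")
    hl_center = np.array([0.0, 2.0, -14.0])
    hl = (np.abs(C[:, 2] - hl_center[2]) <= cfg.hl_thickness_mm / 2.0) & (
        ((C[:, 0] - hl_center[0]) / 24.0) ** 2
        + ((C[:, 1] - hl_center[1]) / 28.0) ** 2
        <= 1.0
    )
    paint(hl, "H-L")

    for name, code in DEFAULT_LANDMARK_CODES.items():
        if not np.any(labels == code):
            raise GenerationError(f"structure {name!r} rasterized to zero voxels")

    # ---- intensities + Rician noise
    means = cfg.intensity_means
    img = np.full(C.shape[0], means["background"], dtype=np.float64)
    img[body] = means["body"]
    for name, code in DEFAULT_LANDMARK_CODES.items():
        img[labels == code] = means[name]
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        n1 = rng.normal(0.0, cfg.noise_sigma, img.shape)
        n2 = rng.normal(0.0, cfg.noise_sigma, img.shape)
        img = np.sqrt((img + n1) ** 2 + n2 ** 2)

    volume = ImageVolume(img.reshape(shape).astype(np.float32), affine)
    body_map = LabelMap(
        body.reshape(shape).astype(np.uint16), affine, BODY_CODES
    )
    landmark_map = LabelMap(
        labels.reshape(shape), affine, DEFAULT_LANDMARK_CODES
    )

    # ---- ground truth in the posed patient frame
    def posed(pts: np.ndarray) -> np.ndarray:
        return pts @ R.T + t

    centerlines = {
        "UV": posed(uv_line),
        "DAo": posed(dao_line),
        "spine": posed(spine_line),
    }
    keypoints = {}
    for name, line in (("UV", uv_line), ("DAo", dao_line), ("spine", spine_line)):
        kp = {k: posed(v[None, :])[0] for k, v in _polyline_keypoints(line).items()}
        # same inferior-first endpoint convention as the landmark detector
        if kp["start"][2] > kp["end"][2]:
            kp["start"], kp["end"] = kp["end"], kp["start"]
        keypoints[name] = kp
    uv_dir = (uv_line[-1] - uv_line[0]) / np.linalg.norm(uv_line[-1] - uv_line[0])
    tangents = {
        "UV": R @ uv_dir,
        "DAo": R @ _dao_tangent_mid(cfg),
        "spine": R @ np.array([0.0, 0.0, 1.0]),
    }
    gt = PhantomGroundTruth(
        centerlines=centerlines,
        keypoints=keypoints,
        tangents=tangents,
        body_volume_mL=4.0 / 3.0 * np.pi * a * b * c / 1000.0,
        body_center=t.copy(),
        rotation=R,
        translation=t,
    )
    return volume, body_map, landmark_map, gt
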