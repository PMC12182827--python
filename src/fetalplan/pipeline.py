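"""End-to-end planning pipeline: localize -> landmarks -> planes -> report.

The three geometric stages mirror the clinical workflow: (A) extract the
fetal body from the whole-uterus anatomical volume and focus a bounding box
on the thorax; (B) detect the cardiac landmarks inside the box and reduce
them to keypoints in patient coordinates; (C) prescribe 2D PC planes
cross-sectional to the umbilical vein and descending aorta.  A failure in
one vessel never aborts the other; a failure of localization or landmark
detection fails the run globally and is reported as such.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Any

from pydantic import BaseModel, ConfigDict, Field

from .errors import (
    DegenerateGeometryError,
    FetalPlanError,
    InvalidInputError,
    LandmarkDetectionError,
    LocalizationError,
    MissingLandmarkError,
)
from .imaging_core import DEFAULT_LANDMARK_CODES, ImageVolume, load_labels
from .landmarks import detect_landmarks
from .localization import (
    ExternalCommandBackend,
    OracleBackend,
    SegmentationBackend,
    ThresholdBackend,
    extract_body_mask,
    thorax_bounding_box,
)
from .planning import ScanProtocol, plan_dao, plan_uv

SCHEMA_VERSION = "1.0"


class BackendConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "oracle"  # oracle | threshold | external
    #: oracle backend: NIfTI paths of the ground-truth label maps
    body_labels: str | None = None
    landmark_labels: str | None = None
    dilate_vox: int = 0
    erode_vox: int = 0
    jitter_mm: float = 0.0
    #: threshold backend
    threshold: float | None = None
    #: external backend: argv prefix; input/output NIfTI paths are appended
    command: list[str] | None = None


class BoxConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    margin_mm: float = 10.0
    fraction: tuple[float, float] = (0.25, 0.75)


class PlanningConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dao_mode: str = "vessel"  # vessel | spine-surrogate
    fov_mm: tuple[float, float] = (300.0, 300.0)
    thickness_mm: float = 5.0
    min_vessel_length_mm: float = 3.0
    anterior_offset_mm: float = 15.0


class PipelineConfig(BaseModel):
    """Single-file configuration of a pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    backend: BackendConfig = Field(default_factory=BackendConfig)
    box: BoxConfig = Field(default_factory=BoxConfig)
    planning: PlanningConfig = Field(default_factory=PlanningConfig)
    seed: int = 0
    output_dir: str | None = None

    @property
    def protocol(self) -> ScanProtocol:
        return ScanProtocol(
            fov_mm=tuple(self.planning.fov_mm),
            thickness_mm=self.planning.thickness_mm,
            min_vessel_length_mm=self.planning.min_vessel_length_mm,
        )


@dataclass
class PlanningReport:
    """Machine-readable outcome of one pipeline run."""

    success: bool
    failure: str | None = None
    vessels: dict[str, dict[str, Any]] = field(default_factory=dict)
    landmarks: dict[str, Any] | None = None
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    config: dict[str, Any] = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def to_json_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "success": self.success,
            "failure": self.failure,
            "vessels": self.vessels,
            "landmarks": self.landmarks,
            "timings_s": self.timings_s,
            "warnings": self.warnings,
            "config": self.config,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def validate_report(report: dict) -> None:
    """Structural validation of a report dict against the shipped schema.

    Raises :class:`InvalidInputError` on the first violation.
    """
    required = {
        "schema_version": str,
        "success": bool,
        "vessels": dict,
        "timings_s": dict,
        "warnings": list,
        "config": dict,
    }
    for key, typ in required.items():
        if key not in report:
            raise InvalidInputError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise InvalidInputError(f"report key {key!r} must be {typ.__name__}")
    if not report["success"] and not report.get("failure"):
        raise InvalidInputError("failed report must carry a failure reason")
    for vessel, entry in report["vessels"].items():
        if entry.get("status") not in ("planned", "skipped"):
            raise InvalidInputError(f"vessel {vessel}: bad status")
        if entry["status"] == "planned" and "prescription" not in entry:
            raise InvalidInputError(f"vessel {vessel}: planned without prescription")
        if entry["status"] == "skipped" and "reason" not in entry:
            raise InvalidInputError(f"vessel {vessel}: skipped without reason")


def build_backend(cfg: BackendConfig, *, which: str) -> SegmentationBackend:
    """Instantiate the configured backend; ``which`` is 'body' or 'landmarks'."""
    if cfg.name == "oracle":
        path = cfg.body_labels if which == "body" else cfg.landmark_labels
        if path is None:
            raise InvalidInputError(f"oracle backend needs {which} label path")
        codes = {"body": 1} if which == "body" else DEFAULT_LANDMARK_CODES
        labels = load_labels(path, codes)
        return OracleBackend(
            labels,
            dilate_vox=cfg.dilate_vox,
            erode_vox=cfg.erode_vox,
            jitter_mm=cfg.jitter_mm,
        )
    if cfg.name == "threshold":
        return ThresholdBackend(cfg.threshold)
    if cfg.name == "external":
        if not cfg.command:
            raise InvalidInputError("external backend needs a command")
        codes = {"body": 1} if which == "body" else DEFAULT_LANDMARK_CODES
        return ExternalCommandBackend(cfg.command, codes)
    raise InvalidInputError(f"unknown backend {cfg.name!r}")


def run_pipeline(
    volume: ImageVolume,
    config: PipelineConfig,
    body_backend: SegmentationBackend | None = None,
    landmark_backend: SegmentationBackend | None = None,
) -> PlanningReport:
    """Execute the full planning pipeline on one volume.

    Backends may be passed in directly (library use, e.g. in-memory oracle);
    otherwise they are built from the configuration.
    """
    report = PlanningReport(success=False, config=config.model_dump(mode="json"))
    t0 = time.perf_counter()
    try:
        if body_backend is None:
            body_backend = build_backend(config.backend, which="body")
        if landmark_backend is None:
            landmark_backend = build_backend(config.backend, which="landmarks")

        body = extract_body_mask(volume, body_backend)
        box = thorax_bounding_box(
            body, config.box.margin_mm, tuple(config.box.fraction)
        )
        report.timings_s["localization"] = round(time.perf_counter() - t0, 4)

        t1 = time.perf_counter()
        landmarks = detect_landmarks(volume, box, landmark_backend)
        report.landmarks = landmarks.to_json_dict()
        report.timings_s["landmarks"] = round(time.perf_counter() - t1, 4)
    except LocalizationError as exc:
        report.failure = f"localization: {exc}"
        return report
    except LandmarkDetectionError as exc:
        report.failure = f"landmarks: {exc}"
        return report

    t2 = time.perf_counter()
    protocol = config.protocol
    try:
        p = plan_uv(landmarks, protocol)
        report.vessels["UV"] = {"status": "planned",
                                "prescription": p.to_json_dict()}
    except (MissingLandmarkError, DegenerateGeometryError) as exc:
        report.vessels["UV"] = {"status": "skipped", "reason": str(exc)}
    try:
        p = plan_dao(
            landmarks,
            mode=config.planning.dao_mode,
            protocol=protocol,
            anterior_offset_mm=config.planning.anterior_offset_mm,
        )
        report.vessels["DAo"] = {"status": "planned",
                                 "prescription": p.to_json_dict()}
    except (MissingLandmarkError, DegenerateGeometryError) as exc:
        report.vessels["DAo"] = {"status": "skipped", "reason": str(exc)}
    report.timings_s["planning"] = round(time.perf_counter() - t2, 4)
    report.timings_s["total"] = round(time.perf_counter() - t0, 4)

    report.success = True
    validate_report(report.to_json_dict())
    return report


__all__ = [
    "BackendConfig",
    "BoxConfig",
    "PipelineConfig",
    "PlanningConfig",
    "PlanningReport",
    "SCHEMA_VERSION",
    "build_backend",
    "run_pipeline",
    "validate_report",
    "FetalPlanError",
]
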