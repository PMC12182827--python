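"""Exception hierarchy.

Every failure mode the pipeline can report maps onto one of these classes so
that the CLI can translate them into distinct exit codes and the library user
can catch precisely the stage that failed.
"""

from __future__ import annotations


class FetalPlanError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FetalPlanError):
    """Malformed or non-finite user input (bad index, empty box, ...)."""


class ConfigurationError(FetalPlanError):
    """Invalid configuration: singular affine, unknown config keys, ..."""


class GenerationError(FetalPlanError):
    """Phantom generation failed, e.g. a structure does not fit the grid."""


class GridMismatchError(FetalPlanError):
    """Two volumes/label maps do not share shape and affine."""


class LocalizationError(FetalPlanError):
    """Fetal body could not be localized (empty segmentation output)."""


class MissingLandmarkError(FetalPlanError):
    """A requested landmark label is absent from the label map."""

    def __init__(self, structure: str, message: str | None = None):
        self.structure = structure
        super().__init__(message or f"landmark {structure!r} is absent")


class DegenerateLandmarkError(FetalPlanError):
    """A tubular landmark is too small or too isotropic to orient a plane."""

    def __init__(self, structure: str, message: str | None = None):
        self.structure = structure
        super().__init__(message or f"landmark {structure!r} is degenerate")


class LandmarkDetectionError(FetalPlanError):
    """Landmark stage failed entirely (backend failure / no landmarks)."""


class DegenerateGeometryError(FetalPlanError):
    """Plane prescription impossible: start and end points coincide."""
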