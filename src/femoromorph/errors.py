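"""Exception hierarchy for the femoromorph pipeline.

Every stage raises a subclass of :class:`FemoromorphError`, so callers can
catch pipeline failures without masking programming errors.
"""


class FemoromorphError(Exception):
    """Base class for all pipeline errors."""


class MeshFormatError(FemoromorphError):
    """The file could not be parsed as an STL/PLY surface mesh."""


class EmptyMeshError(FemoromorphError):
    """Fewer than four vertices remain after cleaning."""


class InsufficientGeometryError(FemoromorphError):
    """Too few valid cross-sections to fit an axis."""


class LandmarkNotFoundError(FemoromorphError):
    """A landmark candidate region was empty; carries the landmark name."""

    def __init__(self, landmark: str, message: str | None = None):
        self.landmark = landmark
        detail = f" ({message})" if message else ""
        super().__init__(f"landmark not found: {landmark}{detail}")


class DegenerateFrameError(FemoromorphError):
    """The condylar line is too close to the shaft axis to span a frame."""


class HeadFitError(FemoromorphError):
    """The femoral-head sphere fit was rejected (inlier fraction too low)."""


class ProjectionDegenerateError(FemoromorphError):
    """The neck axis is too close to the superior axis to project."""


class FeasibilityError(FemoromorphError):
    """A parameter vector cannot be realised as a mesh; names the relation."""


class MeasurementInconsistentError(FemoromorphError):
    """Averaged measurements violate a parameter invariant."""


class CohortSpecError(FemoromorphError):
    """Invalid cohort sampling specification (e.g. non-repairable matrix)."""
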