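"""Exception hierarchy for radioplan."""


class RadioplanError(Exception):
    """Base class for all radioplan errors."""


class MeshValidationError(RadioplanError):
    """Mesh violates a structural invariant (non-finite, bad indices, degenerate)."""


class StlParseError(RadioplanError):
    """Malformed STL input.

    Parameters
    ----------
    message : str
    byte_offset : int, optional
        Offset into the file where the inconsistency was detected.
    """

    def __init__(self, message, byte_offset=None):
        if byte_offset is not None:
            message = f"{message} (byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


class TransformValidationError(RadioplanError):
    """Rotation matrix is not orthogonal, or determinant inconsistent."""


class DegenerateGeometryError(RadioplanError):
    """Point configuration is rank deficient (e.g. collinear Kabsch input)."""


class RegistrationError(RadioplanError):
    """ICP failed; carries an optional ``stage`` label for pipeline errors."""

    def __init__(self, message, stage=None):
        if stage is not None:
            message = f"[stage: {stage}] {message}"
        super().__init__(message)
        self.stage = stage


class TrimmingCollapseError(RegistrationError):
    """Fewer than 3 correspondences survived trimming."""


class EmptySelectionError(RadioplanError):
    """A region/mask selection returned no points or faces."""


class InsufficientShaftError(RadioplanError):
    """Mesh does not extend far enough proximally to fit the central axis."""


class IllConditionedFrameError(RadioplanError):
    """Styloid landmark projects too close to the shaft axis."""


class GimbalLockError(RadioplanError):
    """Middle Cardan angle exceeds the gimbal guard."""


class PlanningError(RadioplanError):
    """Osteotomy planning failed (e.g. empty distal fragment)."""


class PairingError(RadioplanError):
    """Per-case table is missing one arm for some case."""


class StatsError(RadioplanError):
    """Degenerate statistical input (constant data, zero pooled SD, ...)."""
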