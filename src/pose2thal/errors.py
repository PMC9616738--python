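"""Exception types shared across the package."""


class Pose2ThalError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(Pose2ThalError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(Pose2ThalError, ValueError):
    """Input carries no usable geometric information (e.g. zero spread)."""


class InvalidRotationError(Pose2ThalError, ValueError):
    """Matrix supplied as a rotation is not a proper rotation."""


class InvalidCameraError(Pose2ThalError, ValueError):
    """Camera projection matrix is rank deficient."""


class InvalidTuningError(Pose2ThalError, ValueError):
    """Tuning specification produces non-finite or overflowing rates."""


class UnderdeterminedPoseError(Pose2ThalError, ValueError):
    """Too few valid landmarks to constrain a pose fit."""


class SchemaError(Pose2ThalError, ValueError):
    """Tabular input does not match the expected schema."""


class EmptyInputError(Pose2ThalError, ValueError):
    """No data rows/frames supplied."""
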