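"""Exception hierarchy shared across the package."""


class CTDMError(Exception):
    """Base class for all package-specific errors."""


class TPSParseError(CTDMError):
    """A TPS landmark file could not be parsed; message names the record."""


class SchemaError(CTDMError):
    """Landmark schema is internally inconsistent or incomplete."""


class ValidationError(CTDMError):
    """A sample failed validation against its schema."""


class DegenerateShapeError(CTDMError):
    """Configuration carries no shape information (coincident landmarks)."""


class SingularKernelError(CTDMError):
    """Thin-plate-spline kernel is singular (coincident reference points)."""


class ShapeMismatchError(CTDMError):
    """Operands have different landmark counts."""


class UndefinedAxisError(CTDMError):
    """Group means coincide; the between-group axis is undefined."""


class ConstantInputError(CTDMError):
    """A statistic is undefined for a constant input vector."""


class GroupError(CTDMError):
    """A required group label is missing or empty."""
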