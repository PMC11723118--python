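"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (config 2, data 3, numeric 4).
"""


class LarvaposeError(Exception):
    """Base class for all package errors."""


class SchemaError(LarvaposeError, ValueError):
    """An annotation file violates the 26-keypoint schema."""


class FormatError(LarvaposeError, ValueError):
    """A file is structurally not the expected dialect."""


class ConfigurationError(LarvaposeError, ValueError):
    """A run configuration or model/spec combination is invalid."""


class DataError(LarvaposeError, ValueError):
    """Input data violates a precondition (empty split, bad geometry...)."""


class DegenerateGeometryError(DataError):
    """Anchor keypoints do not define a usable similarity transform."""


class NumericalError(LarvaposeError, ArithmeticError):
    """A numerical failure (NaN loss, divergence) aborted a computation."""
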