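"""Exception hierarchy shared across the package."""


class HsitexError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HsitexError):
    """A file is missing, garbled, or not in the declared format."""


class ConsistencyError(HsitexError):
    """Mutually inconsistent inputs (header vs raster, grid mismatch, ...)."""


class SchemaError(HsitexError):
    """A table is missing required columns."""


class VocabularyError(HsitexError):
    """A categorical value is outside its fixed vocabulary."""


class GeometryError(HsitexError):
    """A pixel window falls outside the raster."""


class ParameterError(HsitexError):
    """An operation parameter violates its precondition."""


class CalibrationError(HsitexError):
    """Reflectance calibration is undefined (white <= dark somewhere)."""


class DegenerateTargetError(HsitexError):
    """A target vector is constant where variance is required."""


class SelectionError(HsitexError):
    """Wavelength selection produced an empty subset."""


class BudgetError(HsitexError):
    """A combinatorial search exceeds its configured budget."""


class SolverError(HsitexError):
    """A linear system could not be solved."""


class TrainingError(HsitexError):
    """Iterative training diverged."""
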