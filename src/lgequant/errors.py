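"""Exception hierarchy shared across the toolkit.

Errors are split into user-input problems (bad files, bad flags, bad
geometry) and pipeline-state problems (missing or degenerate reference
annotations), so callers can map them to distinct exit codes.
"""


class LgequantError(Exception):
    """Base class for all package errors."""


class InputError(LgequantError):
    """Invalid user input (files, flags, schemas)."""


class UsageError(InputError):
    """API misuse: out-of-range argument, unknown mode, etc."""


class ValidationError(InputError):
    """An input file violates its schema or invariants."""


class AmbiguityError(InputError):
    """Input is internally inconsistent (e.g. mixed study UIDs)."""


class MetadataError(InputError):
    """A required DICOM tag is missing or unusable; names the tag."""


class GeometryError(InputError):
    """Invalid polygon geometry (open or self-intersecting rings)."""


class BoundsError(LgequantError):
    """A mask or coordinate lies outside its image grid."""


class MissingReferenceError(LgequantError):
    """No ROI / remote reference annotation where one is required."""


class MissingGroundworkError(LgequantError):
    """No myocardial groundwork annotation where one is required."""


class MissingAnnotationError(LgequantError):
    """A stored annotation (e.g. gold scar) is absent."""


class DegenerateReferenceError(LgequantError):
    """Reference sample too small for a standard deviation."""


class SpecError(InputError):
    """Synthetic-cohort specification is geometrically infeasible."""
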