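"""Exception hierarchy for the endplate morphometry pipeline."""


class EndplateError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(EndplateError):
    """Raised when an STL file cannot be parsed.

    Carries ``byte_offset``, the position in the file at which the
    structure first became inconsistent (e.g. where a truncated facet
    block begins).
    """

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (at byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


class EmptyMeshError(EndplateError):
    """Raised when a mesh contains no facets."""


class ParameterError(EndplateError, ValueError):
    """Raised for invalid user-supplied parameters."""


class NoSectionError(EndplateError):
    """Raised when a cutting plane does not intersect the mesh."""


class DegenerateSectionError(EndplateError):
    """Raised when a cross-section is too small to measure."""


class UndefinedEffectError(EndplateError):
    """Raised when an association effect size is undefined (table too small)."""


class EnumerationBudgetError(EndplateError):
    """Raised when an exact test would exceed its enumeration budget."""


class InputError(EndplateError, ValueError):
    """Raised for malformed analysis inputs (labels, tables, records)."""
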