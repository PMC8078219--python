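"""Exception hierarchy shared across the package."""


class HistocytoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HistocytoError):
    """A file or byte stream does not follow the expected format."""


class IntegrityError(HistocytoError):
    """Inputs are individually well-formed but mutually inconsistent
    (duplicate ids, id sets that do not match, ...)."""


class ValidationError(HistocytoError):
    """A value violates a domain invariant (e.g. intensity outside [0, 255]).

    Carries a list of ``(row, column, message)`` tuples in ``details`` when
    the violations are per-row.
    """

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or []


class UnsupportedRoiTypeError(FormatError):
    """The .roi payload encodes an ROI type this package does not handle."""

    def __init__(self, type_code):
        super().__init__(f"unsupported ImageJ ROI type code {type_code} "
                         "(only polygon, freehand and traced ROIs are handled)")
        self.type_code = type_code


class RoiOverflowError(HistocytoError):
    """Polygon extent exceeds the signed 16-bit relative coordinate range."""


class DimensionError(HistocytoError):
    """Array geometries (image, labels, masks) do not agree."""


class PackingError(HistocytoError):
    """The synthetic scene could not place all cells without overlap."""


class SchemaVersionError(FormatError):
    """A persisted gate file uses a schema version newer than this package."""
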