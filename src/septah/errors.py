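"""Exception hierarchy shared by all septah modules."""


class SeptahError(Exception):
    """Base class for all package-specific errors."""


class InputError(SeptahError, ValueError):
    """Invalid argument values or selections (bad cutoffs, unknown names, ...)."""


class ParseError(SeptahError):
    """A file could not be parsed; message carries the offending line when known."""


class StructuralError(SeptahError):
    """A trajectory file is internally inconsistent (e.g. atom counts differ between models)."""


class FormatOverflowError(SeptahError):
    """A value cannot be represented in the fixed-width output format (PDB fields)."""


class ConstructionError(SeptahError):
    """A synthetic scene cannot be realised with the requested geometry."""


class DegenerateGeometryError(SeptahError):
    """Geometry is degenerate for the requested operation (collinear points, zero-length axis)."""
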