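"""Exception hierarchy shared across the package."""


class PathcolorError(Exception):
    """Base class for all package errors."""


class MolfileFormatError(PathcolorError):
    """Malformed molfile text (bad counts line, truncated blocks, ...)."""


class MolfileIndexError(MolfileFormatError):
    """A bond references an atom index outside the atom block."""


class UnsupportedDialectError(PathcolorError):
    """Input is in a dialect this package deliberately does not read (e.g. V3000)."""


class CapacityError(PathcolorError):
    """Value exceeds a fixed-width field of the output format."""


class HierarchyError(PathcolorError):
    """Pathway hierarchy violates its contract (cycle, self-edge)."""


class EmptyInputError(PathcolorError):
    """An operation received no usable input rows/entities."""


class SchemaError(PathcolorError):
    """Persisted matrix does not match the expected vocabulary/shape."""


class StratificationError(PathcolorError):
    """Labels cannot be stratified (single class present)."""


class TrainingDivergenceError(PathcolorError):
    """Model training produced a non-finite loss."""


class ConfigError(PathcolorError):
    """Invalid configuration value."""
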