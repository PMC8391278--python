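"""Exception hierarchy for the coilquant pipeline."""


class CoilQuantError(Exception):
    """Base class for all coilquant errors."""


class FormatError(CoilQuantError):
    """The input container could not be read (unknown or broken format)."""


class EmptyInputError(CoilQuantError):
    """An input held no usable data (zero frames, empty trace, ...)."""


class ConfigurationError(CoilQuantError):
    """A configuration value is missing or outside its valid range."""


class PlacementError(CoilQuantError):
    """Synthetic eggs could not be placed without overlap."""


class NoEggsFoundError(CoilQuantError):
    """ROI detection found no chorions; the pipeline refuses to continue."""
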