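"""Exception hierarchy.

Every error raised by focidens derives from :class:`FociDensError` so callers
can catch the package's failures with a single except clause.
"""


class FociDensError(Exception):
    """Base class for all focidens errors."""


class ConfigurationError(FociDensError):
    """Invalid user configuration (e.g. a channel index out of range)."""


class FormatError(FociDensError):
    """A file or array does not have the expected structure."""


class ContractError(FociDensError):
    """An operation was called with input violating its documented contract."""


class DegenerateImageError(FociDensError):
    """The image carries no usable signal (e.g. constant raster for Otsu)."""


class InsufficientDataError(FociDensError):
    """Too few dose levels / calibration conditions for the requested fit."""


class EmptyConditionError(FociDensError):
    """A condition has zero objects left after exclusion."""


class UndefinedFactorError(FociDensError):
    """Radiosensitization factor undefined (nonpositive control gradient)."""


class PlacementError(FociDensError):
    """Synthetic scene could not be laid out within the retry budget."""


class SceneSpecError(FociDensError):
    """A synthetic-data specification is internally inconsistent."""
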