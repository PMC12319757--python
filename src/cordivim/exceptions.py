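"""Exception hierarchy for cordivim."""


class CordivimError(Exception):
    """Base class for all cordivim errors."""


class InvalidParameterError(CordivimError, ValueError):
    """A model parameter is non-finite or outside its physical domain."""


class DegenerateSignalError(CordivimError, ValueError):
    """A signal is constant or otherwise uninformative for the requested statistic."""


class InvalidSignalError(CordivimError, ValueError):
    """A signal decay violates its contract (wrong length, negative, non-finite, all-zero)."""


class InsufficientDataError(CordivimError, ValueError):
    """Too few usable data points for the requested fit."""


class LogDomainError(CordivimError, ValueError):
    """Non-positive signal where a logarithm is required."""


class EmptyMaskError(CordivimError, ValueError):
    """A binary mask selects no voxels."""


class EmptyROIError(CordivimError, ValueError):
    """A probabilistic ROI has zero total weight in the requested slice."""


class GeometryError(CordivimError, ValueError):
    """The requested phantom grid cannot hold the cord geometry."""


class InvalidSpecError(CordivimError, ValueError):
    """A phantom specification field is out of range."""


class DegenerateVarianceError(CordivimError, ValueError):
    """A reliability statistic is undefined because a variance term is zero."""


class UndefinedCVError(CordivimError, ValueError):
    """The within-subject CV is undefined (zero mean)."""


class MissingCellError(CordivimError, ValueError):
    """A factorial design is incomplete for at least one subject."""


class DatasetError(CordivimError, ValueError):
    """A diffusion dataset is internally inconsistent (frames vs b-table, grids, repetitions)."""
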