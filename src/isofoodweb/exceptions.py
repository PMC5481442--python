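"""Exception hierarchy for invalid or degenerate inputs."""


class IsoFoodWebError(ValueError):
    """Base class for all package-specific input errors."""


class UndefinedInputError(IsoFoodWebError):
    """The requested quantity is undefined for this input (e.g. empty data)."""


class InsufficientDataError(IsoFoodWebError):
    """Too few observations to compute the quantity."""


class DegenerateInputError(IsoFoodWebError):
    """Input is structurally valid but degenerate (e.g. zero variance)."""


class DegenerateGeometryError(IsoFoodWebError):
    """Point configuration has no well-defined ellipse (singular covariance)."""


class MissingBaselineError(IsoFoodWebError):
    """No designated primary-consumer baseline present in the data."""


class ParseError(IsoFoodWebError):
    """A delimited input file failed validation; the message names the rows."""
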