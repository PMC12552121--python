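"""Exception hierarchy for the gxeprs pipeline."""


class GxeprsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GxeprsError, ValueError):
    """Invalid simulation or analysis configuration."""


class FormatError(GxeprsError, ValueError):
    """Malformed or mutually inconsistent input files."""


class DegenerateInputError(GxeprsError, ValueError):
    """Input without enough variation to carry out the operation."""


class CollinearityError(GxeprsError, ValueError):
    """Design matrix is rank deficient; message names the collinear columns."""


class ConvergenceError(GxeprsError, RuntimeError):
    """Iterative fit failed to converge (e.g. separation in logistic models)."""
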