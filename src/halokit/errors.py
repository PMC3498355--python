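"""Package exception hierarchy.

Errors are grouped so the CLI can map them onto stable exit codes:
usage/parameter problems, data problems, and optimisation failures.
"""


class HalokitError(Exception):
    """Base class for all package errors."""


class ParameterError(HalokitError, ValueError):
    """Invalid parameter value (bad threshold, unknown option)."""


class ParseError(HalokitError, ValueError):
    """Malformed structure or table input."""


class EmptyStructureError(ParseError):
    """Structure input contains no atoms."""


class InsufficientDataError(HalokitError, ValueError):
    """Too few observations for the requested analysis."""


class DegenerateDataError(HalokitError, ValueError):
    """Data has no usable variation (e.g. all values identical)."""


class DesignError(HalokitError, ValueError):
    """Experimental design cannot identify the model (e.g. one concentration)."""


class GeometryError(HalokitError, ValueError):
    """Ill-defined geometric construction (zero-length vector arm)."""


class ConstructionError(HalokitError, ValueError):
    """Requested synthetic geometry is not physically realizable."""


class FitError(HalokitError, RuntimeError):
    """Optimisation failed to converge; carries the best attempt if any."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
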