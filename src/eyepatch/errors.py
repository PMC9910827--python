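"""Exception hierarchy.

``ParameterError`` flags invalid arguments or configuration values;
``DataError`` flags inputs that are structurally valid but unusable
(too short, missing cells, degenerate responses); ``FitError`` flags a
non-identifiable model fit.
"""


class EyepatchError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EyepatchError, ValueError):
    """An argument or parameter value is outside its valid domain."""


class DataError(EyepatchError, ValueError):
    """Input data cannot support the requested computation."""


class FitError(DataError):
    """A model fit is non-identifiable for the given data."""
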