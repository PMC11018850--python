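"""Exception hierarchy for smfdx.

All user-input problems derive from :class:`SmfdxError` so callers can catch
one base class; parameter vs data vs parse problems stay distinguishable.
"""


class SmfdxError(Exception):
    """Base class for all smfdx errors."""


class ConfigurationError(SmfdxError, ValueError):
    """An invalid generator or run configuration; the message names the field."""


class ParameterError(SmfdxError, ValueError):
    """An invalid operation parameter (window sizes, tolerances, thresholds)."""


class DataError(SmfdxError, ValueError):
    """Inconsistent input data (unknown groups, duplicate ids, missing class)."""


class SpectrumParseError(SmfdxError, ValueError):
    """A spectrum file could not be parsed; the message carries the line number."""


class FormulaError(SmfdxError, ValueError):
    """A molecular formula could not be parsed; the message names the token."""


class ConvergenceError(SmfdxError, RuntimeError):
    """An iterative fit failed to converge; the message carries diagnostics."""
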