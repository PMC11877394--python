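"""Exception hierarchy shared across the toolkit.

``ValidationError`` covers rejected inputs (bad data), ``ConfigError``
rejected configurations (bad parameters), and ``NoEstimateError`` the
explicit "no estimate possible" signal that several estimators raise
instead of returning a number.
"""


class TempocodeError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(TempocodeError, ValueError):
    """An input value violates a documented precondition."""


class ConfigError(TempocodeError, ValueError):
    """A configuration (stage, filter, spec) is internally inconsistent."""


class NoEstimateError(TempocodeError):
    """An estimator cannot produce a meaningful value from this input."""


class UndefinedPhaseError(NoEstimateError):
    """Phase is undefined because one signal has negligible power at f."""
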