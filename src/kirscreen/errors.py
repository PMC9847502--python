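"""Exception hierarchy shared across the package.

All validation failures derive from :class:`ValidationError` so the CLI can
map them to exit code 2; everything else surfaces as an ordinary runtime
error (exit code 1).
"""


class KirScreenError(Exception):
    """Base class for package-specific errors."""


class ValidationError(KirScreenError, ValueError):
    """Invalid argument, malformed input, or unmet precondition."""


class UndefinedRateError(ValidationError):
    """Rate estimator is undefined (zero mean count or zero-length window)."""


class MissingControlError(ValidationError):
    """A plate lacks the matched vehicle-control wells needed for deltas."""


class MissingDataError(ValidationError):
    """Required rows (phenotypes, profiles) are absent; message lists them."""


class ConfigError(ValidationError):
    """Pipeline configuration is inconsistent or references missing files."""
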