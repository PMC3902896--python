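"""Exception hierarchy for srbind.

All errors derive from :class:`SrbindError` so callers can catch the
package's failures with a single except clause; each subclass maps to one
distinct validation failure mode (and one CLI exit code).
"""


class SrbindError(Exception):
    """Base class for all srbind errors."""


class InvalidParameterError(SrbindError, ValueError):
    """A physical parameter is out of its admissible range (e.g. K <= 0)."""


class InsufficientDataError(SrbindError, ValueError):
    """Too few data points to determine the requested quantity."""


class ConfigurationError(SrbindError, ValueError):
    """Inconsistent inputs, e.g. a curve whose HRE has no affinity entry."""


class ExtrapolationError(SrbindError, ValueError):
    """A requested dose lies outside the measured dose grid."""


class DegenerateRegressionError(SrbindError, ValueError):
    """Zero variance in a regression variable."""


class InvalidPerturbationError(SrbindError, ValueError):
    """A perturbation would produce a negative activation amplitude."""


class PromoterSizeError(SrbindError, ValueError):
    """Promoter architecture exceeds the exact-enumeration bound."""
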