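"""Exception hierarchy for opitraj.

All errors derive from :class:`OpitrajError`; configuration/data errors are
also ``ValueError`` subclasses so generic callers can catch them uniformly.
"""


class OpitrajError(Exception):
    """Base class for all opitraj errors."""


class ConfigurationError(OpitrajError, ValueError):
    """A configuration object failed validation; the message names the field."""


class DataQualityError(OpitrajError, ValueError):
    """Input tables violate a structural requirement (e.g. overlapping enrollment)."""


class DomainError(OpitrajError, ValueError):
    """An operation was applied outside its domain (e.g. MME of a non-opioid)."""


class ConvergenceError(OpitrajError, RuntimeError):
    """All EM restarts collapsed or failed; carries the best partial fit if any."""

    def __init__(self, message, best_model=None):
        super().__init__(message)
        self.best_model = best_model


class SelectionError(OpitrajError, RuntimeError):
    """No candidate model in a selection grid converged."""


class SeparationError(OpitrajError, RuntimeError):
    """Perfect separation in a logistic regression; message names the predictor."""


class CollinearityError(OpitrajError, ValueError):
    """Collinear predictor columns; message lists the dependent columns."""
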