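"""Exception hierarchy for replimix."""


class ReplimixError(Exception):
    """Base class for all replimix errors."""


class SchemaError(ReplimixError):
    """A required input column could not be resolved."""


class EmptyInputError(ReplimixError):
    """An input file or table contained no records."""


class EmptyResultError(ReplimixError):
    """An operation removed or excluded every record."""


class ConfigError(ReplimixError):
    """An invalid configuration value."""


class ValidationError(ReplimixError):
    """Numerical inputs violated a precondition (non-finite, wrong shape...)."""


class UnattainableError(ReplimixError):
    """A requested replication-probability target cannot be reached.

    Carries ``supremum``, the estimated limiting probability as the
    sample-size factor grows without bound.
    """

    def __init__(self, message: str, supremum: float | None = None):
        super().__init__(message)
        self.supremum = supremum


class InfeasibleBandError(ReplimixError):
    """The F-localization feasible set is empty.

    Usually means the censor window retained too little mass or the band
    level is too strict for the number of studies; widen the censor window
    or increase ``alpha_band``.
    """
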