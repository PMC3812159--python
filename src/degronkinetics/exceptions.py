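"""Exception hierarchy for degronkinetics."""


class DegronKineticsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DegronKineticsError, ValueError):
    """A domain object or argument violates its invariants."""


class ParseError(DegronKineticsError, ValueError):
    """A delimited-text input could not be parsed or failed schema checks."""


class IntegrationError(DegronKineticsError, RuntimeError):
    """The ODE solver produced a non-finite or failed solution."""


class UndefinedCorrelationError(DegronKineticsError, ValueError):
    """Pearson correlation requested on a series with zero variance."""


class UnknownDegronError(DegronKineticsError, KeyError):
    """A degron name is not in the reference parameter table."""


class FitError(DegronKineticsError, RuntimeError):
    """The MCMC fit encountered a non-finite objective."""
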