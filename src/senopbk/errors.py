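"""Exception hierarchy for senopbk."""


class SenopbkError(Exception):
    """Base class for all senopbk errors."""


class ConfigurationError(SenopbkError):
    """A parameter or configuration value is invalid; the message names it."""


class UnknownParameterError(SenopbkError, KeyError):
    """A parameter name is not in the registry."""


class UnknownObservableError(SenopbkError, KeyError):
    """A state/observable name is not defined for this simulation."""


class IntegrationError(SenopbkError):
    """The ODE solver failed or produced a state outside tolerance."""


class PairingError(SenopbkError):
    """Full/blank incubation measurements could not be paired."""


class FitError(SenopbkError):
    """Regression input is insufficient (e.g. a single substrate level)."""


class UndefinedREPError(SenopbkError):
    """A relative-potency ratio has a zero denominator."""


class BudgetInconsistencyError(SenopbkError):
    """7-GS-DHP exceeds the bioactivation budget F*f*(REP1*)dose."""


class SensitivityError(SenopbkError):
    """A sensitivity coefficient is undefined (baseline output is zero)."""
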