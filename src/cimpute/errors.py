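"""Exception hierarchy for cimpute."""


class CimputeError(Exception):
    """Base class for all cimpute errors."""


class ConfigurationError(CimputeError, ValueError):
    """A required column or configuration entry is absent or inconsistent."""


class ParseError(CimputeError, ValueError):
    """A data cell could not be parsed as a number."""


class ValidationError(CimputeError, ValueError):
    """Input data violates an invariant (e.g. missing class label)."""


class ParameterError(CimputeError, ValueError):
    """A numeric parameter is outside its admissible range."""


class UsageError(CimputeError, RuntimeError):
    """An operation was invoked outside its precondition."""
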