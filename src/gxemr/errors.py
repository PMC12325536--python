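"""Exception hierarchy shared across the pipeline stages."""


class GxEMRError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(GxEMRError, ValueError):
    """A scalar or array parameter is outside its valid domain."""


class StructuralError(GxEMRError, ValueError):
    """Inputs are individually valid but mutually inconsistent
    (shape mismatches, rank deficiency, mismatched labels)."""


class SequencingError(GxEMRError, RuntimeError):
    """A pipeline stage was invoked before its prerequisites were populated."""


class ConfigError(GxEMRError, ValueError):
    """A run configuration is missing, ambiguous or self-contradictory."""


class DegenerateDataError(GxEMRError, ValueError):
    """A statistic is undefined on the supplied data (zero variance,
    empty complete-case set, too few pairs); the message states why."""


class WeakInstrumentWarning(UserWarning):
    """Instrument-exposure association too weak for a stable Wald ratio."""
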