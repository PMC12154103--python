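"""Exception hierarchy shared across the pipeline stages."""


class PaxlearnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PaxlearnError):
    """An invalid simulation or run configuration; names the offending field."""


class ValidationError(PaxlearnError):
    """Input data violate a stated contract (range, label set, alignment)."""


class EmptyCohortError(PaxlearnError):
    """Screening removed every respondent."""


class PositivityError(PaxlearnError):
    """A treatment definition produced an empty arm."""


class DegenerateDataError(PaxlearnError):
    """A model fit received single-class data; a constant fallback is advised."""


class MetricError(PaxlearnError):
    """A holdout metric is undefined (e.g. AUC on a single-class holdout)."""


class InferenceError(PaxlearnError):
    """Effect summarisation received too few estimates."""
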