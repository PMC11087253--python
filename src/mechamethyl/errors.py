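"""Exception hierarchy shared across the pipeline stages."""


class MechaMethylError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(MechaMethylError, ValueError):
    """A study design or model design matrix is unusable (arm too small, singular, ...)."""


class EmptyInputError(MechaMethylError, ValueError):
    """An operation received an empty dataset where content is required."""


class DomainError(MechaMethylError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class AnnotationMismatchError(MechaMethylError, KeyError):
    """Probes present in results are missing from the probe annotation."""


class ConfigError(MechaMethylError, ValueError):
    """A run configuration failed validation."""
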