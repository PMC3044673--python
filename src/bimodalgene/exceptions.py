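"""Exception hierarchy shared across the pipeline."""


class BimodalGeneError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BimodalGeneError, ValueError):
    """A configuration value is outside its documented range."""


class DataError(BimodalGeneError, ValueError):
    """Input data violate a precondition (wrong domain, unknown id, ...)."""


class DegenerateDataError(DataError):
    """Data carry no usable signal (constant vector, empty mode, ...)."""


class NonConvergenceError(BimodalGeneError, RuntimeError):
    """Every optimisation path failed; carries the best grid candidate."""

    def __init__(self, message, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate
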