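"""Exception hierarchy shared across the package."""


class MrlinkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrlinkError):
    """A column map, config file, or parameter set is unusable."""


class InputError(MrlinkError):
    """Input data are structurally valid but unusable (e.g. zero rows)."""


class DomainError(MrlinkError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientInstrumentsError(MrlinkError):
    """Fewer instruments than the estimator's minimum."""


class WeakInstrumentError(MrlinkError):
    """Instrument strength too low for the requested estimator."""


class CollinearityError(MrlinkError):
    """Exposure effect matrix is rank deficient."""

    def __init__(self, message, exposures=None):
        super().__init__(message)
        self.exposures = list(exposures or [])


class EstimationError(MrlinkError):
    """An estimator failed to converge or the design is degenerate."""


class PipelineError(MrlinkError):
    """A pipeline stage could not run."""

    def __init__(self, message, stage=None):
        super().__init__(message)
        self.stage = stage
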