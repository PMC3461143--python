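"""Exception hierarchy shared across the package."""


class EbreedersError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EbreedersError):
    """A configuration is incomplete or internally inconsistent."""


class InadmissibleMomentsError(EbreedersError, ValueError):
    """A (mean, variance) pair cannot be realised by the requested family."""


class NoDataError(EbreedersError, ValueError):
    """An estimator was invoked on data carrying no signal (e.g. all-zero catches)."""


class UndefinedInputError(EbreedersError, ValueError):
    """Inputs lie outside the domain of the requested quantity."""
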