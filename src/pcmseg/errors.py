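"""Exception types shared across the package."""


class PcmsegError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PcmsegError, ValueError):
    """Input data violates a structural precondition (shape, channels, ...)."""


class InvalidParameterError(PcmsegError, ValueError):
    """A configuration parameter is outside its valid range."""


class InsufficientAnnotationError(PcmsegError, ValueError):
    """A training annotation mask lacks a required class."""


class ModelMismatchError(PcmsegError, ValueError):
    """A trained model is applied to features it was not built for."""


class IncompleteScanError(PcmsegError, ValueError):
    """A tile scan is missing one or more stage positions."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing tiles at positions: {self.missing}")
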