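"""Exception hierarchy shared across the pipeline stages."""


class FPScreenError(Exception):
    """Base class for all package errors."""


class InvalidModelError(FPScreenError):
    """Cavity model or panel parameters violate a physical precondition."""


class DegenerateInputError(FPScreenError):
    """An input signal is degenerate (all-zero power, zero maximum, ...)."""


class IncompatibleDomainError(FPScreenError):
    """Two spectra do not share a usable common wavelength window."""


class ConfigError(FPScreenError):
    """Pipeline configuration failed validation."""


class StageError(FPScreenError):
    """A pipeline stage aborted; carries the stage name for localization."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
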