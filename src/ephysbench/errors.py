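"""Exception hierarchy shared across the package."""


class EphysBenchError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EphysBenchError, ValueError):
    """An input value violates a documented invariant."""


class ConfigurationError(EphysBenchError, ValueError):
    """A configuration is internally inconsistent or incomplete."""


class SchedulingError(EphysBenchError, RuntimeError):
    """Artefact onsets could not be packed into the recording.

    Attributes
    ----------
    placed : int
        Number of events successfully placed before the failure.
    """

    def __init__(self, message: str, placed: int = 0):
        super().__init__(message)
        self.placed = placed


class ExportError(EphysBenchError, RuntimeError):
    """A dataset cannot be written in the requested format."""
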