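"""Exception hierarchy shared across the pipeline stages."""


class GaitnormError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitnormError):
    """Invalid configuration value (rates, cutoffs, grid axes, ...)."""


class InputError(GaitnormError):
    """Invalid data passed to an operation (shape, finiteness, length)."""


class DegenerateGeometryError(GaitnormError):
    """Collinear or coincident landmarks that do not define a frame."""


class DegenerateColumnError(GaitnormError):
    """A zero-variance waveform column reached the PCA codec."""


class NoCycleError(GaitnormError):
    """A trial yielded no analyzable gait cycle."""


class AssemblyError(GaitnormError):
    """Feature/target rows with inconsistent widths."""


class DivergenceError(GaitnormError):
    """Network training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")
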