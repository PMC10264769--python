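"""Exception hierarchy for hydrotrait."""


class HydrotraitError(Exception):
    """Base class for all hydrotrait errors."""


class InputError(HydrotraitError, ValueError):
    """Invalid or inconsistent input data."""


class ComputationError(HydrotraitError, RuntimeError):
    """A quantity is undefined for the given (otherwise valid) inputs."""


class FitError(ComputationError):
    """A model fit failed; carries diagnostics where available."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NewickError(HydrotraitError, ValueError):
    """Malformed or incomplete newick input."""
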