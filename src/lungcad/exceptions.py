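"""Exception types shared across the package."""


class ShapeError(ValueError):
    """An array's geometry is incompatible with the requested operation."""


class ConfigurationError(ValueError):
    """A declared architecture cannot be realised (shape inference failed)."""


class TrainingDivergedError(RuntimeError):
    """Loss or gradients became non-finite during training.

    Carries the last finite network state so a caller can inspect or
    checkpoint it.
    """

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state
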