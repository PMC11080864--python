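"""Exception hierarchy shared across the package."""


class EVStereoError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(EVStereoError, ValueError):
    """A geometric primitive or operation received inconsistent dimensions."""


class InvalidInputError(EVStereoError, ValueError):
    """A numeric input is outside its documented domain."""


class DivergenceError(EVStereoError, ValueError):
    """An estimator was evaluated at a point where it diverges."""


class PackingError(EVStereoError, RuntimeError):
    """Rejection sampling could not place a body without overlap.

    Raised after the attempt cap is exhausted; the message names the
    offending container so infeasible packing fractions fail loudly.
    """


class InconsistencyError(EVStereoError, ValueError):
    """Inputs that must agree (e.g. section thicknesses) do not."""


class PipelineStageError(EVStereoError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
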