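"""Exception hierarchy shared across the package."""


class PancedgeError(Exception):
    """Base class for all errors raised by pancedge."""


class ImageIOError(PancedgeError):
    """Unreadable, unsupported, or malformed image / manifest input."""


class ROIError(PancedgeError):
    """Region-of-interest definition violates its invariants."""


class PhantomError(PancedgeError):
    """Phantom specification is infeasible or invalid."""


class EdgeError(PancedgeError):
    """Edge detection or border extraction failed."""


class FitError(PancedgeError):
    """Baseline spline fit is not possible on the given border."""


class StageError(PancedgeError):
    """Failure inside the scoring pipeline, annotated with the stage name.

    The message is ``"<stage>/<detail>"`` so callers (and the CLI) can report
    exactly which processing step rejected the input.
    """

    def __init__(self, stage: str, detail: str):
        super().__init__(f"{stage}/{detail}")
        self.stage = stage
        self.detail = detail
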