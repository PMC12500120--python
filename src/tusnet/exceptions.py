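"""Exception hierarchy shared across the pipeline."""


class TusnetError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSignalError(TusnetError, ValueError):
    """A time series has zero variance where variability is required."""


class NumericalError(TusnetError, ArithmeticError):
    """A covariance or determinant is singular beyond repair."""


class DivergenceError(TusnetError, RuntimeError):
    """The numerical integration blew up.

    Carries the step index at which the state exceeded the bound.
    """

    def __init__(self, step: int, bound: float):
        self.step = step
        self.bound = bound
        super().__init__(f"state magnitude exceeded {bound:g} at step {step}")


class IsolatedNodeError(TusnetError, ValueError):
    """A graph node has zero strength, so walk-based measures are undefined."""


class DisconnectedGraphError(TusnetError, ValueError):
    """The thresholded backbone fell apart into several components."""

    def __init__(self, largest_component: int, n_nodes: int):
        self.largest_component = largest_component
        self.n_nodes = n_nodes
        super().__init__(
            f"backbone disconnected at requested density: largest component "
            f"has {largest_component}/{n_nodes} nodes"
        )


class PipelineError(TusnetError, RuntimeError):
    """A pipeline stage is missing an input artifact."""
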