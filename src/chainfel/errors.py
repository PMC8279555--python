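"""Exception hierarchy.

``NumericalError`` subclasses signal failures of the numerical machinery
(non-convergence, disconnected umbrella windows, rank-deficient fits); the
CLI maps them to exit code 2, while plain usage mistakes map to exit code 1.
"""


class ChainfelError(Exception):
    """Base class for all package errors."""


class NumericalError(ChainfelError):
    """A computation failed numerically rather than through bad usage."""


class ConvergenceError(NumericalError):
    """An iterative solver exhausted its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DisconnectedWindowsError(NumericalError):
    """Umbrella windows do not form a single overlapping component."""

    def __init__(self, components: list[list[int]]):
        self.components = components
        super().__init__(
            "umbrella windows do not overlap into a single component: "
            + "; ".join(str(c) for c in components)
        )
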