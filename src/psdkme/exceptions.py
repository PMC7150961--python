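"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant.

    Covers malformed CSV files, non-simplex histogram rows, degenerate
    designs (constant columns, duplicate experiment ids) and kernel
    specifications outside their admissible range.
    """


class SolverError(RuntimeError):
    """Raised when an iterative solver fails to reach its tolerance."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        #: best feasible iterate at the time of failure, if any
        self.result = result
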