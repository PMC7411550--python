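"""Exception types shared across the package."""


class FormatError(ValueError):
    """An input file does not conform to the expected schema."""


class DomainError(ValueError):
    """An argument lies outside its mathematical domain."""


class DegenerateDataError(ValueError):
    """Data are too degenerate for the requested construction (e.g. spline knots)."""


class ConvergenceError(RuntimeError):
    """Iterative fitting failed to converge; carries diagnostic detail."""

    def __init__(self, message: str, gradient_norm: float | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm


class SeparationError(ConvergenceError):
    """Monotone likelihood: some coefficient diverges (complete separation)."""


class UnidentifiedError(ValueError):
    """A requested effect is not identified by the data (aliased / no variation)."""
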