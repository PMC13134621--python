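"""Exception types raised across the package."""


class InvalidInputError(ValueError):
    """A physically or structurally invalid argument was supplied."""


class NoEquilibriumError(RuntimeError):
    """The swelling-pressure residual has no sign change in the search bracket.

    Carries the pressure components at the bracket ends to aid diagnosis.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnderdeterminedError(ValueError):
    """Too few observations to constrain the requested free parameters."""


class FitConvergenceError(RuntimeError):
    """The optimiser failed to converge; carries the best solution found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class InvalidGeometryError(ValueError):
    """A detection or measurement violates the imaging geometry."""


class DegenerateDesignError(ValueError):
    """Calibration inputs have no spread in the independent variable."""


class NonResponsiveCalibrationError(ValueError):
    """A calibration curve with non-positive slope cannot be inverted."""


class UndefinedCorrelationError(ValueError):
    """Correlation requested on data with zero variance in a coordinate."""


class NoDataError(ValueError):
    """A pipeline stage received an empty bundle or table."""
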