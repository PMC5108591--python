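"""Exception types shared across the package."""


class MyoquantError(Exception):
    """Base class for all package errors."""


class ValidationError(MyoquantError, ValueError):
    """Invalid parameters or malformed input data."""


class PlacementError(MyoquantError, RuntimeError):
    """Cell placement failed; carries the number of cells actually placed."""

    def __init__(self, placed: int, requested: int, attempts: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} cells "
            f"after {attempts} rejection attempts per cell; "
            "enlarge the field or reduce n_cells"
        )


class DesignError(MyoquantError, ValueError):
    """Rank-deficient or otherwise unusable design matrix."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        self.aliased = aliased or []
        super().__init__(message)


class SeparationError(MyoquantError, RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


class ConvergenceError(MyoquantError, RuntimeError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        self.trace = trace
        super().__init__(message)


class DegenerateRegionError(MyoquantError, ValueError):
    """Pixel region too small or collinear for shape moments."""
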