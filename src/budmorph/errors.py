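"""Exception hierarchy shared across the package."""


class BudmorphError(Exception):
    """Base class for all package-specific errors."""


class InputError(BudmorphError, ValueError):
    """Invalid user-supplied arguments (wrong sizes, signs, ranges)."""


class GeometryError(BudmorphError):
    """Degenerate or inconsistent geometric input (self-intersection,
    zero area, epithelium escaping the mesenchyme, meshing failure)."""


class ConvergenceError(BudmorphError):
    """A nonlinear or steady-state solve failed to converge."""


class SteadyStateError(ConvergenceError):
    """No admissible homogeneous fixed point was found; carries the
    scanned bracket for diagnosis."""

    def __init__(self, message: str, bracket=None):
        super().__init__(message)
        self.bracket = bracket
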