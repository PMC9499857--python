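"""Exception hierarchy shared across the package."""


class OcumaskError(Exception):
    """Base class for all package-specific errors."""


class DimensionMismatchError(OcumaskError, ValueError):
    """A parameter vector or array does not match the owning model's dimensions."""


class ContractViolationError(OcumaskError, ValueError):
    """An input violates a documented precondition (e.g. non-orthonormal rotation)."""


class DegenerateProjectionError(OcumaskError, ValueError):
    """Pinhole projection of points at or behind the camera plane."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(
            f"pinhole projection requires z > 0; offending point indices: {self.indices}"
        )


class InsufficientDataError(OcumaskError, ValueError):
    """Too few visible features to perform an estimation step."""


class NonConvergenceError(OcumaskError, RuntimeError):
    """The solver failed to converge; carries the iteration trace."""

    def __init__(self, message, report=None):
        self.report = report
        super().__init__(message)


class SchemaError(OcumaskError, ValueError):
    """An interchange file violates the documented schema."""
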