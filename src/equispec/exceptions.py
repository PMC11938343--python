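"""Exception hierarchy for equispec."""


class EquispecError(Exception):
    """Base class for all package errors."""


class ModelError(EquispecError):
    """An equilibrium model is malformed or a requested species family is empty."""


class SchemaError(EquispecError):
    """A model/protocol/dataset file violates its schema.

    The message names the file and the offending field.
    """


class ConvergenceError(EquispecError):
    """The mass-balance solver failed to converge.

    Carries the last scaled residual norm in :attr:`residual`.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GranError(EquispecError):
    """Gran-function linearization failed (non-monotone window, bad bracket)."""


class CalibrationError(EquispecError):
    """Electrode calibration failed or produced a non-Nernstian slope."""


class RefinementError(EquispecError):
    """Constant refinement failed (non-convergence, ill-conditioned normal matrix)."""
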