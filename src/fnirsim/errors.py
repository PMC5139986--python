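"""Exception hierarchy for fnirsim."""


class FnirsimError(Exception):
    """Base class for all fnirsim errors."""


class ModelDomainError(FnirsimError, ValueError):
    """A state variable left the domain of the model equations.

    Raised, for example, when a concentration that appears inside a
    logarithm becomes non-positive; the message names the offending pool.
    """


class CalibrationError(FnirsimError, ValueError):
    """A parameter set is inconsistent or violates the calibration targets."""


class ConvergenceError(FnirsimError, RuntimeError):
    """An iterative solve (steady state, ODE step) failed to converge."""
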