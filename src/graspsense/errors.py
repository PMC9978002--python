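"""Exception hierarchy for graspsense."""


class GraspSenseError(Exception):
    """Base class for all graspsense-specific errors."""


class SimulationDiverged(GraspSenseError):
    """The drivetrain integrator produced a non-finite state."""


class ConfigurationMissing(GraspSenseError, KeyError):
    """A protocol row refers to an object absent from the configuration."""


class UnlabeledTrace(GraspSenseError):
    """A trace without object metadata cannot be labeled."""


class InsufficientData(GraspSenseError):
    """Too few closures (or classes) to perform the requested split/fit."""


class InvalidLabel(GraspSenseError, ValueError):
    """A class label outside the supported set {0, 1, 2} (or {0, 1} binary)."""


class ModelInputMismatch(GraspSenseError, ValueError):
    """Feature vector dimension incompatible with the fitted model."""


class LearningRateTooHigh(GraspSenseError, RuntimeError):
    """Gradient descent diverged (cost grew an order of magnitude)."""


class TraceTooShort(GraspSenseError, ValueError):
    """Trace shorter than the per-closure decision window."""


class CalibrationError(GraspSenseError, RuntimeError):
    """Method-of-limits staircase produced a degenerate calibration."""
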