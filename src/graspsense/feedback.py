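"""Vibrotactile sensory-substitution encoding of stiffness predictions.

A single ERM vibromotor (200 Hz carrier) conveys the classifier's decision.
Four conditions are modeled:

* ``NoFB`` — no feedback at all (baseline; performance should sit at chance),
* ``AFB``  — no vibration; only incidental motor sound reaches the user
  (that cue lives in the evaluation responder, not here),
* ``1FB``  — one intensity (30%) for any object, nothing for void closures,
* ``2FB``  — graded intensity: 100% for rigid, 30% for soft, nothing for void.

Intensity percentages are fractions of the user's calibrated perceptual
band [pwm_min, pwm_max], found with an ascending method-of-limits
staircase; an ``absolute`` mode maps them to raw duty instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol
import warnings

import numpy as np

from .errors import CalibrationError

CONDITIONS = ("NoFB", "AFB", "1FB", "2FB")

#: ERM carrier frequency (Hz) whenever the motor is active.
VIBRATION_FREQUENCY_HZ = 200.0

#: Intensity fraction per (condition, predicted class); absent -> inactive.
INTENSITY_FRACTIONS = {
    "1FB": {1: 0.3, 2: 0.3},
    "2FB": {1: 1.0, 2: 0.3},
}


@dataclass(frozen=True)
class VibrationCalibration:
    """Perceptual PWM band of one user: detection threshold, comfort
    ceiling, and the staircase step used to find them (% duty)."""

    pwm_min: float
    pwm_max: float
    step: float = 4.0
    saturated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pwm_min < self.pwm_max <= 100.0:
            raise ValueError("need 0 <= pwm_min < pwm_max <= 100")


@dataclass(frozen=True)
class FeedbackCommand:
    """One vibromotor command: duty % at the 200 Hz carrier, or silence."""

    active: bool
    duty: float
    frequency: float
    condition: str
    class_encoded: int

    def __post_init__(self) -> None:
        if not self.active and self.duty != 0.0:
            raise ValueError("inactive command must carry zero duty")


def encode(
    prediction: int,
    condition: str,
    calibration: VibrationCalibration,
    mode: str = "range",
) -> FeedbackCommand:
    """Map a stiffness prediction to a vibromotor command (pure function).

    ``range`` mode (default) interprets intensity fractions over the
    calibrated band: duty = pwm_min + f·(pwm_max − pwm_min).  ``absolute``
    mode uses duty = 100·f directly.
    """
    if prediction not in (0, 1, 2):
        raise ValueError(f"invalid class: {prediction!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"invalid condition: {condition!r}")
    if mode not in ("range", "absolute"):
        raise ValueError(f"invalid mode: {mode!r}")
    fraction = INTENSITY_FRACTIONS.get(condition, {}).get(prediction)
    if fraction is None:
        return FeedbackCommand(False, 0.0, 0.0, condition, prediction)
    if mode == "range":
        duty = calibration.pwm_min + fraction * (calibration.pwm_max - calibration.pwm_min)
    else:
        duty = 100.0 * fraction
    return FeedbackCommand(True, float(duty), VIBRATION_FREQUENCY_HZ, condition, prediction)


class PerceptionResponder(Protocol):
    """What the staircase asks of a (human or simulated) subject."""

    def perceived(self, duty: float) -> bool: ...

    def strong(self, duty: float) -> bool: ...


@dataclass
class ThresholdResponder:
    """Deterministic subject with crisp perception/comfort thresholds."""

    perceived_threshold: float
    strong_threshold: float

    def perceived(self, duty: float) -> bool:
        return duty >= self.perceived_threshold

    def strong(self, duty: float) -> bool:
        return duty >= self.strong_threshold


class LogisticResponder:
    """Stochastic subject: psychometric (logistic) detection curves with a
    seeded noise stream, so a full staircase is reproducible given a seed."""

    def __init__(
        self,
        perceived_threshold: float,
        strong_threshold: float,
        slope: float = 2.0,
        seed: int = 0,
    ):
        self.perceived_threshold = perceived_threshold
        self.strong_threshold = strong_threshold
        self.slope = slope
        self._rng = np.random.default_rng(seed)

    def _prob(self, duty: float, threshold: float) -> float:
        return 1.0 / (1.0 + np.exp(-(duty - threshold) / self.slope))

    def perceived(self, duty: float) -> bool:
        return self._rng.random() < self._prob(duty, self.perceived_threshold)

    def strong(self, duty: float) -> bool:
        return self._rng.random() < self._prob(duty, self.strong_threshold)


def method_of_limits(
    responder: PerceptionResponder, step: float = 4.0
) -> VibrationCalibration:
    """Ascending method-of-limits staircase for the perceptual PWM band.

    Duty rises from 0 in ``step``-percent increments (steps of 4–5% by
    convention).  The first duty reported perceived becomes ``pwm_min``; the
    staircase continues and the first duty reported strong becomes
    ``pwm_max``.  If the subject never reports a strong sensation the band
    saturates at 100% (flagged, with a warning).  A collapsed band
    (pwm_max <= pwm_min) raises :class:`CalibrationError`.
    """
    if not 0 < step <= 100:
        raise ValueError("step must be in (0, 100]")
    duties = np.append(np.arange(0.0, 100.0, step), 100.0)
    pwm_min = None
    pwm_max = None
    saturated = False
    for duty in duties:
        if pwm_min is None:
            if not responder.perceived(duty):
                continue
            pwm_min = float(duty)
        if responder.strong(duty):
            pwm_max = float(duty)
            break
    if pwm_min is None:
        raise CalibrationError("vibration never perceived up to 100% duty")
    if pwm_max is None:
        pwm_max = 100.0
        saturated = True
        warnings.warn(
            "no strong sensation reported up to 100% duty; calibration saturated",
            stacklevel=2,
        )
    if pwm_max <= pwm_min:
        raise CalibrationError(
            f"degenerate band: pwm_min={pwm_min} >= pwm_max={pwm_max}"
        )
    return VibrationCalibration(
        pwm_min=pwm_min, pwm_max=pwm_max, step=float(step), saturated=saturated
    )
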