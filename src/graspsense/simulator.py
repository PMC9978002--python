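"""Single-DOF drivetrain simulation of an under-actuated prosthetic hand grasp.

The hand powertrain (one DC motor + planetary gearhead driving the whole
grasp) is reduced to a single output-shaft coordinate ``theta`` in degrees,
0 = fully open, increasing = closing.  Control mirrors the embedded cascade
scheme: an outer position loop (PD on the error between the commanded
reference ``theta_ref`` and the encoder angle ``theta_out``) produces a
current reference; an inner current loop (PI) produces the motor voltage.
Objects are unilateral rotational springs engaged past a contact angle, so

* void closures keep motor current low (friction/inertia only),
* contact plateaus the encoder while the reference keeps creeping under
  EMG-like residuals,
* steady-state current grows with object stiffness.

These three signatures are exactly what the downstream stiffness classifier
feeds on.  All default numeric parameters are synthetic (tuned for regime
separation, not measured from any physical hand); see the shipped
``hannes_like.yaml`` config.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import SimulationDiverged

DEG2RAD = math.pi / 180.0
RAD2DEG = 180.0 / math.pi

#: Nominal closing speed (deg/s) of an EMG-like reference at drive_level 1.
EMG_CLOSING_SPEED = 30.0
#: Low-pass cutoff (Hz) applied to the rectified excitation noise.
EMG_ENVELOPE_CUTOFF = 3.0
#: Mechanical range of the output shaft (deg).
THETA_MAX = 110.0

#: Shaft speed (deg/s) beyond which the integration counts as diverged.
_OMEGA_DIVERGED = 1e9


class StiffnessClass(str, enum.Enum):
    """Grasp outcome categories; integer labels follow the training convention."""

    VOID = "void"
    RIGID = "rigid"
    SOFT = "soft"

    @property
    def label(self) -> int:
        return {"void": 0, "rigid": 1, "soft": 2}[self.value]


#: label integer -> StiffnessClass
CLASS_OF_LABEL = {c.label: c for c in StiffnessClass}


@dataclass(frozen=True)
class MotorParams:
    """Electromechanical constants of the drive motor + gearhead, reflected
    at the output shaft.

    torque_constant       N·m/A
    armature_resistance   ohm
    electrical_time_constant  s  (first-order lag of current toward V/R)
    reflected_inertia     kg·m²
    viscous_friction      N·m·s/rad
    current_limit         mA (driver clamp; must exceed the 300 mA void gate)
    voltage_limit         V
    """

    torque_constant: float = 0.03
    armature_resistance: float = 1.0
    electrical_time_constant: float = 0.005
    reflected_inertia: float = 1e-4
    viscous_friction: float = 2e-3
    current_limit: float = 2000.0
    voltage_limit: float = 12.0

    def __post_init__(self) -> None:
        for name in (
            "torque_constant",
            "armature_resistance",
            "electrical_time_constant",
            "reflected_inertia",
            "viscous_friction",
            "current_limit",
            "voltage_limit",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"MotorParams.{name} must be strictly positive")
        if self.current_limit <= 300.0:
            raise ValueError(
                "current_limit must exceed 300 mA so contact can cross the void gate"
            )


@dataclass(frozen=True)
class ControllerGains:
    """Cascade controller gains.

    kp_pos  mA/deg, kd_pos mA·s/deg  — outer PD on the position error
    pos_to_current_gain — dimensionless scale from PD output to i_ref
    kp_cur  V/mA, ki_cur V/(mA·s)    — inner PI on the current error
    sample_rate Hz — fixed control/integration rate
    """

    kp_pos: float = 8.0
    kd_pos: float = 0.05
    pos_to_current_gain: float = 2.0
    kp_cur: float = 0.004
    ki_cur: float = 0.05
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("kp_pos", "kd_pos", "pos_to_current_gain", "kp_cur", "ki_cur"):
            if getattr(self, name) < 0:
                raise ValueError(f"ControllerGains.{name} must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass(frozen=True)
class ObjectModel:
    """A grasped object as a unilateral rotational spring at the output shaft.

    spring_rate N·m/deg (0 for void), contact_angle deg,
    contact_damping N·m·s/deg (dissipates only while closing into the object).
    """

    name: str = "void"
    stiffness_class: StiffnessClass = StiffnessClass.VOID
    spring_rate: float = 0.0
    contact_angle: float = 40.0
    contact_damping: float = 5e-4

    def __post_init__(self) -> None:
        if isinstance(self.stiffness_class, str):  # permit plain strings in configs
            object.__setattr__(
                self, "stiffness_class", StiffnessClass(self.stiffness_class)
            )
        if self.stiffness_class is StiffnessClass.VOID:
            if self.spring_rate != 0.0:
                raise ValueError("void object must have spring_rate = 0")
        elif self.spring_rate <= 0.0:
            raise ValueError("non-void object must have spring_rate > 0")
        if not 0.0 < self.contact_angle < THETA_MAX:
            raise ValueError("contact_angle must lie inside the mechanical range")
        if self.contact_damping < 0:
            raise ValueError("contact_damping must be >= 0")

    @property
    def label(self) -> int:
        return self.stiffness_class.label


@dataclass(frozen=True)
class ReferenceProfile:
    """Generator settings for the commanded closure trajectory.

    kind 'sinusoidal': amplitude·(1−cos(2π·frequency·t))/2 — a smooth
    close-and-reopen cycle, the bench acquisition waveform.

    kind 'emg_like': a noisy monotone ramp emulating proportional EMG speed
    control — rectified low-pass-filtered Gaussian excitation drives the
    closing speed (nominally ``EMG_CLOSING_SPEED·drive_level`` deg/s) until
    the amplitude plateau, after which the reference keeps creeping at
    ``residual_creep_rate`` (muscle-tone residuals that never fully vanish).
    """

    kind: str = "emg_like"
    amplitude: float = 90.0
    frequency: float = 0.25
    drive_level: float = 1.0
    residual_creep_rate: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoidal", "emg_like"):
            raise ValueError(f"unknown reference kind: {self.kind!r}")
        if self.kind == "emg_like" and self.residual_creep_rate <= 0:
            raise ValueError("residual_creep_rate must be > 0 for emg_like profiles")


@dataclass
class GraspTrace:
    """Time-aligned closure record: commanded angle, encoder angle, motor current."""

    t: np.ndarray
    theta_ref: np.ndarray
    theta_out: np.ndarray
    current: np.ndarray
    sample_rate: float
    object_meta: Optional[ObjectModel] = None

    def __post_init__(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ValueError("trace needs at least 2 samples")
        for arr in (self.theta_ref, self.theta_out, self.current):
            if len(arr) != n:
                raise ValueError("all trace channels must share one length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "theta_ref_deg": self.theta_ref,
                "theta_out_deg": self.theta_out,
                "current_mA": self.current,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, object_meta: Optional[ObjectModel] = None) -> "GraspTrace":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(float)
        rate = 1.0 / float(np.median(np.diff(t)))
        return cls(
            t=t,
            theta_ref=df["theta_ref_deg"].to_numpy(float),
            theta_out=df["theta_out_deg"].to_numpy(float),
            current=df["current_mA"].to_numpy(float),
            sample_rate=rate,
            object_meta=object_meta,
        )


def make_reference(
    profile: ReferenceProfile, duration: float, sample_rate: float
) -> np.ndarray:
    """Sample the commanded closure trajectory (deg) on a uniform grid.

    Reproducible: identical ``(profile, duration, sample_rate)`` give
    identical arrays (the emg_like noise stream is seeded by ``profile.seed``).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    if profile.amplitude == 0.0:
        return np.zeros(n)
    if profile.kind == "sinusoidal":
        return profile.amplitude * (1.0 - np.cos(2.0 * math.pi * profile.frequency * t)) / 2.0
    # emg_like
    rng = np.random.default_rng(profile.seed)
    white = rng.standard_normal(n)
    a = 1.0 - math.exp(-2.0 * math.pi * EMG_ENVELOPE_CUTOFF / sample_rate)
    env = _signal.lfilter([a], [1.0, -(1.0 - a)], white)
    env_sd = math.sqrt(a / (2.0 - a))  # stationary sd of the one-pole filter
    excitation = np.maximum(0.0, 1.0 + profile.noise_sd * env / env_sd)
    speed = EMG_CLOSING_SPEED * profile.drive_level * excitation
    theta = np.cumsum(speed) / sample_rate
    hit = np.nonzero(theta >= profile.amplitude)[0]
    if hit.size:
        k = int(hit[0])
        theta[k:] = profile.amplitude + profile.residual_creep_rate * (t[k:] - t[k])
    return theta


def contact_torque(theta_out, theta_dot, obj: ObjectModel):
    """Unilateral spring-damper reaction (N·m); zero before contact, never negative.

    Damping only resists closing into the object (``theta_dot > 0``) so the
    contact can never pull the fingers inward.
    """
    if obj.spring_rate == 0.0:  # void: nothing to push against
        torque = np.zeros_like(np.asarray(theta_out, float))
        return torque if torque.ndim else 0.0
    penetration = np.maximum(0.0, np.asarray(theta_out, float) - obj.contact_angle)
    engaged = penetration > 0.0
    torque = obj.spring_rate * penetration + np.where(
        engaged, obj.contact_damping * np.maximum(np.asarray(theta_dot, float), 0.0), 0.0
    )
    return torque if torque.ndim else float(torque)


def simulate_from_reference(
    motor: MotorParams,
    gains: ControllerGains,
    obj: ObjectModel,
    theta_ref: np.ndarray,
    sample_rate: float,
) -> GraspTrace:
    """Integrate the closed-loop plant along an arbitrary reference array.

    Fixed-step semi-implicit Euler at the control rate: current update first
    (exact first-order-lag step toward V/R), then torque balance, velocity,
    position.  The PI integrator is frozen while the voltage saturates
    (conditional-integration anti-windup).
    """
    theta_ref = np.asarray(theta_ref, float)
    n = theta_ref.size
    dt = 1.0 / sample_rate
    kt_mA = motor.torque_constant / 1000.0  # N·m per mA
    beta = 1.0 - math.exp(-dt / motor.electrical_time_constant)
    inv_R = 1000.0 / motor.armature_resistance  # mA per V
    i_lim = motor.current_limit
    v_lim = motor.voltage_limit
    kp, kd, g = gains.kp_pos, gains.kd_pos, gains.pos_to_current_gain
    kpc, kic = gains.kp_cur, gains.ki_cur
    inv_J = 1.0 / motor.reflected_inertia
    b_visc = motor.viscous_friction
    k_spring, theta_c, c_damp = obj.spring_rate, obj.contact_angle, obj.contact_damping

    theta = 0.0
    omega = 0.0  # deg/s
    i_out = 0.0  # mA
    integ = 0.0  # mA·s accumulated current error
    prev_eps = theta_ref[0] - theta

    theta_arr = np.empty(n)
    i_arr = np.empty(n)
    for k in range(n):
        eps = theta_ref[k] - theta
        deps = (eps - prev_eps) * sample_rate
        prev_eps = eps
        i_ref = g * (kp * eps + kd * deps)
        if i_ref > i_lim:
            i_ref = i_lim
        elif i_ref < -i_lim:
            i_ref = -i_lim
        eps_i = i_ref - i_out
        integ_cand = integ + eps_i * dt
        v = kpc * eps_i + kic * integ_cand
        if -v_lim <= v <= v_lim:
            integ = integ_cand
        elif v > v_lim:
            v = v_lim
        else:
            v = -v_lim
        i_out += (v * inv_R - i_out) * beta
        if i_out > i_lim:
            i_out = i_lim
        elif i_out < -i_lim:
            i_out = -i_lim
        # torque balance at the output shaft (N·m)
        tau = kt_mA * i_out - b_visc * omega * DEG2RAD
        pen = theta - theta_c
        if pen > 0.0 and k_spring > 0.0:
            tau_contact = k_spring * pen
            if omega > 0.0:
                tau_contact += c_damp * omega
            tau -= tau_contact
        omega += tau * inv_J * RAD2DEG * dt
        if not omega == omega or abs(omega) > _OMEGA_DIVERGED:
            raise SimulationDiverged(
                f"velocity blew up at step {k} integrating motor={motor!r}, "
                f"gains={gains!r}, object={obj!r}"
            )
        theta += omega * dt
        if theta < 0.0:
            theta = 0.0
            if omega < 0.0:
                omega = 0.0
        elif theta > THETA_MAX:
            theta = THETA_MAX
            if omega > 0.0:
                omega = 0.0
        theta_arr[k] = theta
        i_arr[k] = i_out

    if not (np.isfinite(theta_arr).all() and np.isfinite(i_arr).all()):
        raise SimulationDiverged(
            f"non-finite state integrating motor={motor!r}, gains={gains!r}, object={obj!r}"
        )
    t = np.arange(n) / sample_rate
    return GraspTrace(
        t=t,
        theta_ref=theta_ref,
        theta_out=theta_arr,
        current=i_arr,
        sample_rate=sample_rate,
        object_meta=obj,
    )


def simulate_closure(
    motor: MotorParams,
    gains: ControllerGains,
    obj: ObjectModel,
    profile: ReferenceProfile,
    duration: float,
    seed: Optional[int] = None,
) -> GraspTrace:
    """Simulate one complete grasp closure; deterministic given ``seed``.

    ``seed`` overrides ``profile.seed`` when given.  Preconditions mirror the
    bench protocol: closures last at least 1 s and the control rate is at
    least 100 Hz.
    """
    if duration < 1.0:
        raise ValueError("closure duration must be at least 1 s")
    if gains.sample_rate < 100.0:
        raise ValueError("sample_rate must be at least 100 Hz")
    if seed is not None:
        profile = replace(profile, seed=int(seed))
    ref = make_reference(profile, duration, gains.sample_rate)
    return simulate_from_reference(motor, gains, obj, ref, gains.sample_rate)


def steady_state_grasp(
    motor: MotorParams,
    gains: ControllerGains,
    obj: ObjectModel,
    theta_ref_hold: float,
) -> tuple[float, float]:
    """Closed-form (current mA, angle deg) equilibrium for a held reference.

    At rest the PI loop enforces i_out = i_ref = g·kp·(theta_ref − theta) and
    the motor torque balances the spring:

        kt·i = k·(theta − theta_c)   =>   theta = (s·theta_ref + k·theta_c)/(s + k)

    with servo stiffness s = kt·g·kp (N·m/deg).  Valid while neither current
    nor voltage saturates and the object is engaged (for a void object the
    equilibrium is simply theta = theta_ref, i = 0).
    """
    s = motor.torque_constant / 1000.0 * gains.pos_to_current_gain * gains.kp_pos
    if obj.spring_rate == 0.0 or theta_ref_hold <= obj.contact_angle:
        return 0.0, min(theta_ref_hold, THETA_MAX)
    theta = (s * theta_ref_hold + obj.spring_rate * obj.contact_angle) / (
        s + obj.spring_rate
    )
    i = gains.pos_to_current_gain * gains.kp_pos * (theta_ref_hold - theta)
    i = min(i, motor.current_limit)
    return i, theta
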