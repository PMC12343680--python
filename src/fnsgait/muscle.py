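"""Hill-type muscle-tendon units.

Muscle force is the classic phenomenological decomposition

    F = F_max * (a * f_L(l~) * f_V(v~) + f_pas(l~)) * cos(pennation)

with smooth active force-length (sum of Gaussians), passive exponential
stiffness, and a log-form force-velocity curve.  The curve family follows the
smooth parameterizations that are standard in gradient-based muscle-driven
trajectory optimization; constants are module-level defaults and each curve is
normalized so that f_L(1) = 1 and f_V(0) = 1 exactly.

Activation dynamics are first order with distinct activation/deactivation time
constants, blended smoothly so the right-hand side is differentiable (a
requirement of the collocation solver).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuscleTendonUnit",
    "muscle_force",
    "activation_dynamics",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "rigid_tendon_kinematics",
]

# Active force-length Gaussian coefficients (b1, b2, b3, b4) per bump.
_FL_COEFFS = (
    (0.815, 1.055, 0.162, 0.0633),
    (0.433, 0.717, -0.0299, 0.200),
    (0.100, 1.000, 0.354, 0.0),
)
# Passive curve shape: strain at which passive force reaches 1.0, and exponent.
_KPE = 4.0
_E0 = 0.6
# Force-velocity coefficients (d1..d4), v~ normalized by v_max.
_FV_COEFFS = (-0.318, -8.149, -0.374, 0.886)

# Sharpness of the smooth activation/deactivation switch (dimensionless).
_ACT_SWITCH_GAIN = 50.0


def _fl_raw(lnorm):
    out = 0.0
    for b1, b2, b3, b4 in _FL_COEFFS:
        out = out + b1 * np.exp(-0.5 * (lnorm - b2) ** 2 / (b3 + b4 * lnorm) ** 2)
    return out


def active_force_length(lnorm):
    """Active force-length multiplier, normalized so the optimum (l~=1) is 1."""
    return _fl_raw(lnorm) / _fl_raw(1.0)


def passive_force_length(lnorm):
    """Passive force-length multiplier; zero at optimal fiber length."""
    return (np.exp(_KPE * (lnorm - 1.0) / _E0) - 1.0) / (np.exp(_KPE) - 1.0)


def _fv_raw(vnorm):
    d1, d2, d3, d4 = _FV_COEFFS
    arg = d2 * vnorm + d3
    return d1 * np.log(arg + np.sqrt(arg * arg + 1.0)) + d4


def force_velocity(vnorm):
    """Force-velocity multiplier, normalized so isometric (v~=0) is 1."""
    return _fv_raw(vnorm) / _fv_raw(0.0)


@dataclass
class MuscleTendonUnit:
    """One muscle-tendon actuator.

    ``moment_arms`` maps coordinate names to constant moment arms (m); the
    musculotendon length is ``reference_length - sum(r_j * q_j)``, so a
    positive moment arm produces a positive generalized force about that
    coordinate when the muscle is under tension.
    """

    name: str
    max_isometric_force: float  # N
    optimal_fiber_length: float  # m
    tendon_slack_length: float  # m
    pennation: float = 0.0  # rad, constant
    activation_time_constant: float = 0.015  # s
    deactivation_time_constant: float = 0.060  # s
    moment_arms: dict = field(default_factory=dict)  # coord name -> m
    reference_length: float | None = None  # l_MT at q = 0; default l_ts + l_opt*cos(penn)
    group_id: str = ""
    side: str = ""  # "left" | "right" | ""
    max_contraction_velocity: float = 10.0  # optimal fiber lengths / s

    def __post_init__(self):
        for label, value in (
            ("max_isometric_force", self.max_isometric_force),
            ("optimal_fiber_length", self.optimal_fiber_length),
            ("tendon_slack_length", self.tendon_slack_length),
            ("activation_time_constant", self.activation_time_constant),
            ("deactivation_time_constant", self.deactivation_time_constant),
        ):
            if not value > 0:
                raise ValueError(f"{self.name}: {label} must be > 0, got {value}")
        if self.reference_length is None:
            self.reference_length = (
                self.tendon_slack_length
                + self.optimal_fiber_length * np.cos(self.pennation)
            )


def muscle_force(activation, norm_fiber_length, norm_fiber_velocity, mtu):
    """Tensile musculotendon force (N) for given activation and fiber state.

    Accepts scalars or broadcastable arrays.  Inputs must be finite;
    activation must lie in [0, 1] and lengths must be positive.
    """
    a = np.asarray(activation, dtype=float)
    ln = np.asarray(norm_fiber_length, dtype=float)
    vn = np.asarray(norm_fiber_velocity, dtype=float)
    for label, arr in (("activation", a), ("norm_fiber_length", ln),
                       ("norm_fiber_velocity", vn)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"muscle_force: non-finite {label} for {mtu.name}")
    if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
        raise ValueError(f"muscle_force: activation outside [0, 1] for {mtu.name}")
    if np.any(ln <= 0):
        raise ValueError(f"muscle_force: non-positive fiber length for {mtu.name}")
    multiplier = a * active_force_length(ln) * force_velocity(vn) + passive_force_length(ln)
    return mtu.max_isometric_force * multiplier * np.cos(mtu.pennation)


def activation_dynamics(excitation, activation, mtu):
    """First-order activation rate da/dt (1/s).

    The rate is (e - a)/tau with tau switching smoothly between the
    activation time constant (e > a) and the deactivation time constant
    (e < a); the smooth switch keeps the dynamics differentiable.
    """
    e = np.asarray(excitation, dtype=float)
    a = np.asarray(activation, dtype=float)
    if np.any(e < -1e-9) or np.any(e > 1 + 1e-9):
        raise ValueError(f"activation_dynamics: excitation outside [0, 1] for {mtu.name}")
    if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
        raise ValueError(f"activation_dynamics: activation outside [0, 1] for {mtu.name}")
    return _activation_rate(
        e, a, mtu.activation_time_constant, mtu.deactivation_time_constant
    )


def _activation_rate(e, a, tau_act, tau_deact):
    """Unchecked activation rate; used batched inside the dynamics."""
    diff = e - a
    s = 0.5 * (1.0 + np.tanh(_ACT_SWITCH_GAIN * diff))
    inv_tau = s / tau_act + (1.0 - s) / tau_deact
    return diff * inv_tau


def rigid_tendon_kinematics(mtu, lmt, vmt):
    """Map musculotendon length/velocity to normalized fiber state.

    Rigid tendon: fiber length along the tendon is lmt - tendon_slack_length,
    divided by cos(pennation) for the fiber itself.  Velocity is normalized by
    the maximum contraction velocity.
    """
    cos_p = np.cos(mtu.pennation)
    fiber = (np.asarray(lmt, dtype=float) - mtu.tendon_slack_length) / cos_p
    # Keep the fiber length strictly positive and smooth: softplus floor at
    # 10% of optimal length so pathological poses stay differentiable.
    floor = 0.1 * mtu.optimal_fiber_length
    eps = 0.05 * mtu.optimal_fiber_length
    shifted = fiber - floor
    fiber = floor + 0.5 * (shifted + np.sqrt(shifted * shifted + eps * eps))
    lnorm = fiber / mtu.optimal_fiber_length
    vnorm = np.asarray(vmt, dtype=float) / (
        cos_p * mtu.optimal_fiber_length * mtu.max_contraction_velocity
    )
    return lnorm, vnorm
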