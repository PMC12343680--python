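"""Smoothed Hunt-Crossley sphere-on-plane ground contact.

The normal force is the Hunt-Crossley form k * d^p * (1 + 3/2 c * d_dot)
evaluated on a smoothed penetration depth so the force is defined, C1, and
strictly positive-tending for all signed penetrations — the property that
makes the contact compatible with gradient-based trajectory optimization.
Friction is a smooth Coulomb (tanh-regularized) plus viscous term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContactSphere", "contact_force"]


@dataclass
class ContactSphere:
    """A contact sphere rigidly attached to a segment.

    offset is the sphere-center position in the parent segment frame (m).
    stiffness has units N/m^exponent (Hertzian, exponent 3/2 by default).
    smoothing is the penetration scale (m) over which the force transitions
    near zero penetration.
    """

    parent_segment: str
    offset: tuple  # (x, y) in segment frame, m
    radius: float  # m
    stiffness: float = 1.0e5  # N / m^exponent
    dissipation: float = 2.0  # s/m
    exponent: float = 1.5
    mu_static: float = 0.8
    mu_dynamic: float = 0.8
    mu_viscous: float = 0.5  # s/m, multiplies normal force
    smoothing: float = 1.0e-4  # m
    transition_velocity: float = 0.05  # m/s, tanh friction scale

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"contact sphere on {self.parent_segment}: radius must be > 0")
        if not self.smoothing > 0:
            raise ValueError("smoothing must be > 0")


# Smoothing scale for clamping the dissipation factor to positive values.
_DISSIPATION_EPS = 0.05


def contact_force(penetration, penetration_rate, slip_velocity, sphere):
    """Tangential and normal ground-reaction force on the sphere (N).

    Defined for any signed penetration; decays smoothly to zero as the sphere
    separates from the plane.  Returns (tangential, normal), broadcast over
    array inputs.
    """
    d = np.asarray(penetration, dtype=float)
    ddot = np.asarray(penetration_rate, dtype=float)
    vslip = np.asarray(slip_velocity, dtype=float)

    eps = sphere.smoothing
    d_smooth = 0.5 * (d + np.sqrt(d * d + eps * eps))
    hc_factor = 1.0 + 1.5 * sphere.dissipation * ddot
    hc_smooth = 0.5 * (hc_factor + np.sqrt(hc_factor * hc_factor + _DISSIPATION_EPS**2))
    fn = sphere.stiffness * d_smooth**sphere.exponent * hc_smooth

    ft = -fn * (
        sphere.mu_dynamic * np.tanh(vslip / sphere.transition_velocity)
        + sphere.mu_viscous * vslip
    )
    return ft, fn
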