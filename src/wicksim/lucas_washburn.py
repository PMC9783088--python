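"""Closed-form Lucas-Washburn wicking model.

The wetted length of a dry porous strip in contact with a wetting-fluid
reservoir grows as the square root of time.  The permeability-based
form used here reads

    l(t) = sqrt( 2 K gamma cos(theta) t**alpha / (phi mu r_a) )

with permeability K (m^2), surface tension gamma (N/m), contact angle
theta, porosity phi, viscosity mu (Pa s) and mean pore radius r_a (m).
The exponent alpha defaults to 1, recovering the classical l ~ sqrt(t)
scaling.  A ``classic`` variant, the textbook single-capillary law
l = sqrt(gamma r_a cos(theta) t / (2 mu)), is provided for sensitivity
checks; it involves no permeability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .membranes import FluidSpec, StripGeometry


@dataclass(frozen=True)
class LWParams:
    """Parameters of the Lucas-Washburn front law."""

    permeability: float  # m^2, K
    surface_tension: float  # N/m, gamma
    contact_angle: float  # rad, theta
    porosity: float  # fraction, phi
    viscosity: float  # Pa s, mu
    pore_radius: float  # m, r_a
    exponent: float = 1.0  # alpha on t

    def __post_init__(self) -> None:
        for name in (
            "permeability",
            "surface_tension",
            "porosity",
            "viscosity",
            "pore_radius",
            "exponent",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.contact_angle < math.pi / 2:
            raise ValueError("contact_angle must lie in [0, pi/2)")

    @property
    def prefactor(self) -> float:
        """Coefficient c in l(t) = c * t**(alpha/2)."""
        return math.sqrt(
            2.0
            * self.permeability
            * self.surface_tension
            * math.cos(self.contact_angle)
            / (self.porosity * self.viscosity * self.pore_radius)
        )


def lw_front(params: LWParams, t, variant: str = "permeability"):
    """Front position l(t) in metres.

    Parameters
    ----------
    params : LWParams
    t : float or array of float
        Elapsed time in seconds, >= 0.
    variant : {"permeability", "classic"}
        ``"permeability"`` uses the permeability-based form above;
        ``"classic"`` the single-capillary textbook law (ignores K and
        phi).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if variant == "permeability":
        out = params.prefactor * t ** (params.exponent / 2.0)
    elif variant == "classic":
        c = math.sqrt(
            params.surface_tension
            * params.pore_radius
            * math.cos(params.contact_angle)
            / (2.0 * params.viscosity)
        )
        out = c * np.sqrt(t)
    else:
        raise ValueError("variant must be 'permeability' or 'classic'")
    return float(out) if out.ndim == 0 else out


def lw_time_to(params: LWParams, L: float) -> float:
    """Time at which the front reaches length ``L`` (exact inverse of
    :func:`lw_front` in the permeability variant)."""
    if L < 0:
        raise ValueError("length must be non-negative")
    if L == 0:
        return 0.0
    return float((L / params.prefactor) ** (2.0 / params.exponent))


def lw_mass(params: LWParams, geom: StripGeometry, fluid: FluidSpec, t):
    """Absorbed fluid mass at time t, kg.

    m(t) = rho * phi * width * thickness * min(l(t), L0): the wetted
    pore volume fills completely behind the front and uptake saturates
    once the front reaches the strip end.
    """
    l = np.minimum(np.asarray(lw_front(params, t)), geom.length)
    out = fluid.density * params.porosity * geom.width * geom.thickness * l
    return float(out) if out.ndim == 0 else out


def calibrated_params(
    *,
    anchor_length: float,
    anchor_time: float,
    surface_tension: float,
    contact_angle: float,
    porosity: float,
    viscosity: float,
    pore_radius: float,
    exponent: float = 1.0,
) -> LWParams:
    """LWParams whose permeability makes the front reach ``anchor_length``
    at exactly ``anchor_time`` (closed-form inversion of the front law)."""
    if anchor_length <= 0 or anchor_time <= 0:
        raise ValueError("anchor length and time must be positive")
    K = (
        anchor_length**2
        * porosity
        * viscosity
        * pore_radius
        / (2.0 * surface_tension * math.cos(contact_angle) * anchor_time**exponent)
    )
    return LWParams(
        permeability=K,
        surface_tension=surface_tension,
        contact_angle=contact_angle,
        porosity=porosity,
        viscosity=viscosity,
        pore_radius=pore_radius,
        exponent=exponent,
    )
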