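"""Physical parameters of paper membranes, fluids, and strip geometry.

Built-in presets cover three Whatman membranes commonly used in lateral
flow assays: CF4 (cotton linter), MF1 (bound glass fiber) and Fusion 5
(glass fiber / polymer matrix).  All quantities are stored in SI units;
manufacturer datasheet units (µm, mm, s/4cm, mN/m) are converted exactly
once, at the preset boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

# Anchor length for manufacturer wicking rates: time for the front to
# travel 4 cm along the strip.
WICKING_ANCHOR_LENGTH = 0.04  # m

# Surface tension used by the simulation parameter set (72 mN/m).  The
# rheometer characterisation instead assumed 52 mN/m from literature;
# both are exposed, the simulation value is the default.
SURFACE_TENSION_SIMULATION = 0.072  # N/m
SURFACE_TENSION_RHEOMETER = 0.052  # N/m

# CF4 entry capillary pressure as printed in the simulation parameter
# table; the contact angle below is back-computed from it (the angle
# itself is never stated).
CF4_ENTRY_CAPILLARY_PRESSURE = 47498.0  # Pa
CF4_PORE_RADIUS = 2.25e-6  # m

#: Contact angle (rad) such that 2*sigma*cos(theta)/Rc reproduces the
#: printed CF4 entry capillary pressure with sigma = 0.072 N/m and
#: Rc = 2.25 µm.  Evaluates to 42.07 degrees.
DEFAULT_CONTACT_ANGLE = math.acos(
    CF4_ENTRY_CAPILLARY_PRESSURE * CF4_PORE_RADIUS / (2 * SURFACE_TENSION_SIMULATION)
)


class UnknownMembraneError(KeyError):
    """Raised when a membrane name does not match any preset."""


@dataclass(frozen=True)
class MembraneSpec:
    """Manufacturer datasheet description of a paper membrane."""

    name: str
    material: str
    thickness: float  # m, measured at 53 kPa clamp pressure
    wicking_rate: float  # s per 4 cm
    pore_diameter: float | tuple[float, float]  # m, single value or (low, high)
    porosity: float  # fraction

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.wicking_rate <= 0:
            raise ValueError("wicking_rate must be positive")
        if not 0 < self.porosity < 1:
            raise ValueError("porosity must lie strictly between 0 and 1")
        if isinstance(self.pore_diameter, tuple):
            lo, hi = self.pore_diameter
            if not 0 < lo <= hi:
                raise ValueError("pore_diameter range must satisfy 0 < low <= high")
        elif self.pore_diameter <= 0:
            raise ValueError("pore_diameter must be positive")

    @property
    def mean_pore_diameter(self) -> float:
        """Pore diameter, taking the midpoint when a range is given."""
        if isinstance(self.pore_diameter, tuple):
            lo, hi = self.pore_diameter
            return 0.5 * (lo + hi)
        return self.pore_diameter


@dataclass(frozen=True)
class FluidSpec:
    """Bulk properties of one fluid phase."""

    density: float  # kg/m^3
    dynamic_viscosity: float  # Pa s
    surface_tension: float = SURFACE_TENSION_SIMULATION  # N/m
    contact_angle: float = DEFAULT_CONTACT_ANGLE  # rad, against the paper

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.dynamic_viscosity <= 0:
            raise ValueError("dynamic_viscosity must be positive")
        if self.surface_tension <= 0:
            raise ValueError("surface_tension must be positive")
        if not 0 <= self.contact_angle < math.pi / 2:
            raise ValueError(
                "contact_angle must lie in [0, pi/2) for a wetting fluid"
            )


@dataclass(frozen=True)
class StripGeometry:
    """Rectangular paper strip dimensions."""

    length: float  # m (L0)
    width: float  # m (W0)
    thickness: float  # m (th)

    def __post_init__(self) -> None:
        for name in ("length", "width", "thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cross_section_area(self) -> float:
        return self.width * self.thickness

    @property
    def volume(self) -> float:
        return self.length * self.width * self.thickness


@dataclass(frozen=True)
class PorousMediumParams:
    """Pore-scale parameters entering the flow models.

    ``permeability`` has no datasheet value; it is produced by the
    calibration routines from the manufacturer wicking rate and may be
    ``None`` until calibrated.
    """

    porosity: float  # fraction, epsilon_p
    pore_radius: float  # m, Rc
    entry_capillary_pressure: float  # Pa, pec
    pore_size_distribution_index: float  # dimensionless, lp
    permeability: float | None = None  # m^2, k
    initial_wetting_saturation: float = 0.01  # fraction at t = 0
    residual_saturations: tuple[float, float] = (0.0, 0.0)  # (wetting, nonwetting)

    def __post_init__(self) -> None:
        if not 0 < self.porosity < 1:
            raise ValueError("porosity must lie strictly between 0 and 1")
        if self.pore_radius <= 0:
            raise ValueError("pore_radius must be positive")
        if self.entry_capillary_pressure < 0:
            raise ValueError("entry_capillary_pressure must be non-negative")
        if self.pore_size_distribution_index <= 0:
            raise ValueError("pore_size_distribution_index must be positive")
        if self.permeability is not None and self.permeability <= 0:
            raise ValueError("permeability must be positive when given")
        if not 0 <= self.initial_wetting_saturation < 1:
            raise ValueError("initial_wetting_saturation must lie in [0, 1)")
        rw, rn = self.residual_saturations
        if rw < 0 or rn < 0 or rw + rn >= 1:
            raise ValueError("residual saturations must be >= 0 and sum below 1")

    def with_permeability(self, k: float) -> "PorousMediumParams":
        return replace(self, permeability=k)


@dataclass(frozen=True)
class AuxiliaryParams:
    """Parameters carried by the simulation parameter set but unused by
    the default solver: solute diffusion coefficients, gravity, and a
    secondary porosity whose role is unstated."""

    diffusion_coefficients: tuple[float, float] = (2.15e-6, 1e-5)  # m^2/s (D1, D2)
    gravity: float = 0.0  # m/s^2; horizontal strip, off by default
    secondary_porosity: float = 0.383  # epsilon1

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.diffusion_coefficients):
            raise ValueError("diffusion coefficients must be non-negative")
        if self.gravity < 0:
            raise ValueError("gravity must be non-negative")
        if self.secondary_porosity < 0:
            raise ValueError("secondary_porosity must be non-negative")


# --- fluid presets -------------------------------------------------------

#: Stimulated saliva as parameterised for the simulation.
SALIVA = FluidSpec(density=1000.0, dynamic_viscosity=0.002)

#: Air filling the dry pore space.
AIR = FluidSpec(
    density=1.0,
    dynamic_viscosity=1.76e-5,
    surface_tension=SURFACE_TENSION_SIMULATION,
    contact_angle=0.0,
)

#: Mean viscosities measured for stimulated vs unstimulated saliva (Pa s).
SALIVA_VISCOSITY = {"stimulated": 0.002, "unstimulated": 0.00234}


# --- membrane presets ----------------------------------------------------

_MEMBRANE_SPECS = {
    "cf4": MembraneSpec(
        name="CF4",
        material="100% cotton linter",
        thickness=482e-6,
        wicking_rate=67.3,
        pore_diameter=11e-6,
        porosity=0.80,
    ),
    "mf1": MembraneSpec(
        name="MF1",
        material="bound glass fiber",
        thickness=367e-6,
        wicking_rate=29.7,
        pore_diameter=0.45e-6,
        porosity=0.69,
    ),
    "fusion5": MembraneSpec(
        name="Fusion5",
        material="proprietary single-layer glass fiber / polymer matrix",
        thickness=370e-6,
        wicking_rate=43.9,
        pore_diameter=(21e-6, 181e-6),
        porosity=0.80,
    ),
}

_ALIASES = {"fusion 5": "fusion5", "fusion-5": "fusion5"}

DEFAULT_STRIP_LENGTH = 0.06  # m
DEFAULT_PORE_SIZE_DISTRIBUTION_INDEX = 2.0  # lp


def membrane_names() -> list[str]:
    return [spec.name for spec in _MEMBRANE_SPECS.values()]


def _canonical(name: str) -> str:
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in _MEMBRANE_SPECS:
        raise UnknownMembraneError(
            f"unknown membrane {name!r}; valid names: {', '.join(membrane_names())}"
        )
    return key


def derive_geometry(L0: float, thickness: float) -> StripGeometry:
    """Strip geometry from its length; width is fixed at L0/8.

    With the default L0 = 6 cm this yields the 0.0075 m strip width of
    the simulation parameter set.
    """
    if L0 <= 0:
        raise ValueError("strip length L0 must be positive")
    return StripGeometry(length=L0, width=L0 / 8.0, thickness=thickness)


def get_preset(
    name: str,
    *,
    L0: float = DEFAULT_STRIP_LENGTH,
    rc_policy: str = "paper",
    surface_tension: float = SURFACE_TENSION_SIMULATION,
    contact_angle: float = DEFAULT_CONTACT_ANGLE,
) -> tuple[MembraneSpec, PorousMediumParams, StripGeometry]:
    """Full parameter set for a named membrane.

    Parameters
    ----------
    name : str
        ``"CF4"``, ``"MF1"`` or ``"Fusion5"`` (case-insensitive).
    L0 : float
        Strip length in metres (default 6 cm).
    rc_policy : {"paper", "half_pore"}
        How the capillary radius Rc is derived.  ``"paper"`` keeps the
        published CF4 value Rc = 2.25 µm even though it contradicts the
        half-pore-diameter rule (which would give 5.5 µm);
        ``"half_pore"`` applies Rc = pore_diameter / 2 uniformly.  For
        MF1 and Fusion 5 no Rc is published, so both policies use half
        the datasheet pore diameter (midpoint of the range for
        Fusion 5).
    surface_tension, contact_angle : float
        Wetting-fluid interface properties used to derive the entry
        capillary pressure pec = 2*sigma*cos(theta)/Rc.

    Returns
    -------
    (MembraneSpec, PorousMediumParams, StripGeometry)
    """
    if rc_policy not in ("paper", "half_pore"):
        raise ValueError("rc_policy must be 'paper' or 'half_pore'")
    spec = _MEMBRANE_SPECS[_canonical(name)]
    if spec.name == "CF4" and rc_policy == "paper":
        rc = CF4_PORE_RADIUS
    else:
        rc = spec.mean_pore_diameter / 2.0
    pec = 2.0 * surface_tension * math.cos(contact_angle) / rc
    medium = PorousMediumParams(
        porosity=spec.porosity,
        pore_radius=rc,
        entry_capillary_pressure=pec,
        pore_size_distribution_index=DEFAULT_PORE_SIZE_DISTRIBUTION_INDEX,
    )
    geom = derive_geometry(L0, spec.thickness)
    return spec, medium, geom


# --- config (de)serialization -------------------------------------------

#: Mapping between config keys (named after the published parameter
#: table) and where each value lives in the preset tuple.
CONFIG_KEYS = (
    "sigma", "theta", "Rc", "lp", "por", "pec",
    "rho_saliva", "mu_saliva", "rho_air", "mu_air",
    "L0", "W0", "th", "s_initial",
    "D1", "D2", "epsilon1", "g",
)


def preset_to_config(
    spec: MembraneSpec,
    medium: PorousMediumParams,
    geom: StripGeometry,
    wetting: FluidSpec = SALIVA,
    nonwetting: FluidSpec = AIR,
    aux: AuxiliaryParams = AuxiliaryParams(),
) -> dict:
    """Flatten a preset into a config dictionary with datasheet key names."""
    return {
        "membrane": spec.name,
        "sigma": wetting.surface_tension,
        "theta": wetting.contact_angle,
        "Rc": medium.pore_radius,
        "lp": medium.pore_size_distribution_index,
        "por": medium.porosity,
        "pec": medium.entry_capillary_pressure,
        "rho_saliva": wetting.density,
        "mu_saliva": wetting.dynamic_viscosity,
        "rho_air": nonwetting.density,
        "mu_air": nonwetting.dynamic_viscosity,
        "L0": geom.length,
        "W0": geom.width,
        "th": geom.thickness,
        "s_initial": medium.initial_wetting_saturation,
        "D1": aux.diffusion_coefficients[0],
        "D2": aux.diffusion_coefficients[1],
        "epsilon1": aux.secondary_porosity,
        "g": aux.gravity,
    }


def config_to_preset(
    config: dict,
) -> tuple[MembraneSpec, PorousMediumParams, StripGeometry, FluidSpec, FluidSpec, AuxiliaryParams]:
    """Rebuild parameter objects from a config dictionary.

    Unknown keys are a hard error so that typos in overrides never pass
    silently.
    """
    known = set(CONFIG_KEYS) | {"membrane", "k"}
    unknown = set(config) - known
    if unknown:
        raise KeyError(
            f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    spec = _MEMBRANE_SPECS[_canonical(config["membrane"])]
    wetting = FluidSpec(
        density=config["rho_saliva"],
        dynamic_viscosity=config["mu_saliva"],
        surface_tension=config["sigma"],
        contact_angle=config["theta"],
    )
    nonwetting = FluidSpec(
        density=config["rho_air"],
        dynamic_viscosity=config["mu_air"],
        surface_tension=config["sigma"],
        contact_angle=0.0,
    )
    medium = PorousMediumParams(
        porosity=config["por"],
        pore_radius=config["Rc"],
        entry_capillary_pressure=config["pec"],
        pore_size_distribution_index=config["lp"],
        permeability=config.get("k"),
        initial_wetting_saturation=config["s_initial"],
    )
    geom = StripGeometry(
        length=config["L0"], width=config["W0"], thickness=config["th"]
    )
    aux = AuxiliaryParams(
        diffusion_coefficients=(config["D1"], config["D2"]),
        gravity=config["g"],
        secondary_porosity=config["epsilon1"],
    )
    return spec, medium, geom, wetting, nonwetting, aux
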