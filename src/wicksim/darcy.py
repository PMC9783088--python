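"""1-D finite-volume solver for two-phase (wetting/non-wetting) capillary
imbibition along a paper strip.

Model
-----
Each phase obeys Darcy's law, q_i = -(k kr_i / mu_i) grad p_i, and mass
conservation d/dt(eps_p rho_i S_i) + div(rho_i q_i) = 0 with no source
term.  Phases are incompressible and S_w + S_n = 1.  Capillary pressure
and relative permeabilities follow the Brooks-Corey closure with entry
pressure ``pec`` and pore-size-distribution index ``lp``:

    pc(Se)   = pec * Se**(-1/lp)
    kr_w(Se) = Se**((2 + 3 lp)/lp)
    kr_n(Se) = (1 - Se)**2 * (1 - Se**((2 + lp)/lp))

With incompressible phases and S_w + S_n = 1, the system reduces to a
single nonlinear saturation equation with an advective and a
capillary-diffusion term,

    eps_p dS/dt + d/dx( f_w(S) u_T ) = d/dx( D(S) dS/dx ),
    D(S)   = k * [lam_w lam_n / (lam_w + lam_n)] * (-dpc/dS),
    f_w(S) = lam_w / (lam_w + lam_n),

with phase mobilities lam_i = kr_i / mu_i and total velocity u_T.  The
strip is dipped in the reservoir at x = 0 (saturated inlet, S = 1) while
the far end is open to the atmosphere: displaced air vents through the
dry outlet (co-current imbibition), so u_T is nonzero and uniform along
the strip.  It follows from integrating the total-velocity Darcy
relation between the reservoir (wetting pressure 0, pc = pec) and the
outlet (air at atmospheric pressure):

    u_T = [ pec + A(1) - A(S_outlet) ] / R,   A(S) = int f_w (-dpc/dS) dS,
    R   = int dx / (k lam_t),

where R picks up the air-path resistance of the outlet face; u_T shuts
off as the strip saturates and air connectivity to the outlet is lost.
The wetting phase cannot leave through the outlet.

The solver integrates the saturation equation with a conservative
explicit finite-volume scheme (upwinded advective flux, chord-averaged
capillary-diffusion flux, CFL-controlled adaptive steps); an
independent two-pressure IMPES formulation in
:mod:`wicksim.twopressure` serves as a cross-check.

Initial condition: uniform wetting saturation S0 (0.01 by default: the
strip starts essentially dry).  Gravity is off by default (horizontal
strip); when enabled the gravity term enters the wetting-phase driving
force as rho_w * g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .membranes import FluidSpec, PorousMediumParams, StripGeometry
from .trace import WickingTrace

#: Floor on effective saturation inside the capillary pressure law; below
#: it pc is held at its (finite) capped value to regularize Se -> 0.
SE_FLOOR = 1e-6


class SolverError(RuntimeError):
    """Raised when the time integration cannot proceed."""


@dataclass(frozen=True)
class ClosureModel:
    """Brooks-Corey closure parameters."""

    entry_capillary_pressure: float  # Pa, pec
    pore_size_distribution_index: float  # dimensionless, lp

    def __post_init__(self) -> None:
        if self.entry_capillary_pressure < 0:
            raise ValueError("entry_capillary_pressure must be non-negative")
        if self.pore_size_distribution_index <= 0:
            raise ValueError("pore_size_distribution_index must be positive")


@dataclass(frozen=True)
class SolverConfig:
    """Discretization and output control for the saturation solver."""

    cell_count: int = 240
    end_time: float = 240.0  # s
    output_times: tuple[float, ...] = (20.0, 40.0, 60.0, 120.0, 180.0, 240.0)
    front_threshold: float = 0.5  # saturation defining the visible front
    cfl_safety: float = 0.8
    min_time_step: float = 1e-9  # s, hard failure below this
    gravity_enabled: bool = False
    gravity: float = 9.81  # m/s^2, used only if gravity_enabled
    seed: int | None = None  # reserved; the solver is deterministic

    def __post_init__(self) -> None:
        if self.cell_count < 8:
            raise ValueError("cell_count must be at least 8")
        if self.end_time <= 0:
            raise ValueError("end_time must be positive")
        if not 0 < self.front_threshold < 1:
            raise ValueError("front_threshold must lie strictly in (0, 1)")
        if not 0 < self.cfl_safety <= 1:
            raise ValueError("cfl_safety must lie in (0, 1]")


@dataclass
class SaturationField:
    """Wetting saturation S(x, t) on cell centers at the output times."""

    cell_centers: np.ndarray  # m, shape (n,)
    times: np.ndarray  # s, shape (m,)
    S: np.ndarray  # shape (m, n)
    geometry: StripGeometry | None = None
    mass_balance_error: float = 0.0  # max per-step relative budget error
    cumulative_influx: float = 0.0  # time-integrated inlet flux, m^3 per m^2
    step_count: int = 0
    initial_saturation: float = 0.01


# --- closure functions ---------------------------------------------------


def effective_saturation(S, residuals: tuple[float, float] = (0.0, 0.0)):
    """Normalize saturation between the residual values, clamped to [0, 1].

    Se = (S - Sr_w) / (1 - Sr_w - Sr_n)
    """
    rw, rn = residuals
    if rw < 0 or rn < 0 or rw + rn >= 1:
        raise ValueError("residual saturations must be >= 0 and sum below 1")
    Se = (np.asarray(S, dtype=float) - rw) / (1.0 - rw - rn)
    out = np.clip(Se, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def capillary_pressure(Se, closure: ClosureModel):
    """Brooks-Corey capillary pressure pc = pec * Se**(-1/lp), Pa.

    Se <= ``SE_FLOOR`` is capped at pc(SE_FLOOR) to regularize the
    divergence at vanishing saturation.
    """
    Se = np.asarray(Se, dtype=float)
    if np.any(Se > 1.0 + 1e-12):
        raise ValueError("effective saturation must not exceed 1")
    Se_reg = np.maximum(Se, SE_FLOOR)
    pc = closure.entry_capillary_pressure * Se_reg ** (
        -1.0 / closure.pore_size_distribution_index
    )
    return float(pc) if pc.ndim == 0 else pc


def capillary_pressure_derivative(Se, closure: ClosureModel):
    """dpc/dSe (negative), with the same Se floor as capillary_pressure."""
    Se = np.asarray(Se, dtype=float)
    lp = closure.pore_size_distribution_index
    Se_reg = np.maximum(Se, SE_FLOOR)
    d = -(closure.entry_capillary_pressure / lp) * Se_reg ** (-(1.0 + lp) / lp)
    return float(d) if d.ndim == 0 else d


def rel_perm(Se, lp: float):
    """Brooks-Corey relative permeability pair (kr_wetting, kr_nonwetting)."""
    Se = np.asarray(Se, dtype=float)
    if np.any((Se < -1e-12) | (Se > 1.0 + 1e-12)):
        raise ValueError("effective saturation must lie in [0, 1]")
    Se = np.clip(Se, 0.0, 1.0)
    kr_w = Se ** ((2.0 + 3.0 * lp) / lp)
    kr_n = (1.0 - Se) ** 2 * (1.0 - Se ** ((2.0 + lp) / lp))
    if kr_w.ndim == 0:
        return float(kr_w), float(kr_n)
    return kr_w, kr_n


def darcy_flux(k: float, kr, mu: float, pressure_gradient):
    """Single-phase Darcy flux q = -(k kr / mu) * grad p, m/s.

    Positive flux points toward increasing x.
    """
    if k <= 0 or mu <= 0:
        raise ValueError("permeability and viscosity must be positive")
    out = -(k * np.asarray(kr, dtype=float) / mu) * np.asarray(
        pressure_gradient, dtype=float
    )
    return float(out) if out.ndim == 0 else out


def capillary_diffusivity(
    S,
    medium: PorousMediumParams,
    wetting: FluidSpec,
    nonwetting: FluidSpec,
    closure: ClosureModel,
):
    """Capillary diffusion coefficient D(S), m^2/s.

    D = k * lam_w lam_n / (lam_w + lam_n) * (-dpc/dS); degenerate (zero)
    at both saturation end points, which keeps the imbibition front
    sharp and at finite speed.
    """
    k = medium.permeability
    if k is None:
        raise ValueError("medium.permeability is not set; calibrate first")
    Se = effective_saturation(S, medium.residual_saturations)
    kr_w, kr_n = rel_perm(Se, closure.pore_size_distribution_index)
    lam_w = kr_w / wetting.dynamic_viscosity
    lam_n = kr_n / nonwetting.dynamic_viscosity
    lam_sum = lam_w + lam_n
    frac = np.where(lam_sum > 0, lam_w * lam_n / np.maximum(lam_sum, 1e-300), 0.0)
    rw, rn = medium.residual_saturations
    dSe_dS = 1.0 / (1.0 - rw - rn)
    D = k * frac * (-capillary_pressure_derivative(Se, closure)) * dSe_dS
    return float(D) if np.ndim(D) == 0 else D


# --- solver --------------------------------------------------------------


class _Stepper:
    """Explicit conservative finite-volume stepper for the saturation
    equation, shared by :func:`simulate` and :func:`time_to_front`.

    The diffusion term is discretized through the Kirchhoff transform
    K(S) = int_0^S D(s) ds, with face fluxes

        q_{i+1/2} = -(K(S_{i+1}) - K(S_i)) / dx,

    which remains accurate across the sharp imbibition front where D
    varies by orders of magnitude between neighbouring cells (an
    arithmetic mean of D would shut the flux off at the front and at
    the saturated-inlet face, where D(1) = 0).  K is tabulated once on
    a fine saturation grid and interpolated.

    The time step comes from the monotonicity bound of the frozen-
    coefficient scheme,

        dt <= safety * phi * dx / max_i( Dc_l/d_l + Dc_r/d_r ),

    where Dc are the face chord diffusivities (K(S_r)-K(S_l))/(S_r-S_l)
    and d the center-to-center distances (dx interior, dx/2 for the
    Dirichlet inlet face).  Under that bound every updated value is a
    convex combination of current values and the ghost value 1, so the
    saturation stays in [S0, 1] by construction and the scheme is
    conservative to round-off.
    """

    TABLE_SIZE = 8193

    def __init__(self, medium, wetting, nonwetting, geom, closure, config):
        if medium.permeability is None:
            raise ValueError("medium.permeability is not set; calibrate first")
        self.n = config.cell_count
        self.dx = geom.length / self.n
        self.x = (np.arange(self.n) + 0.5) * self.dx
        self.phi = medium.porosity
        self.S0 = medium.initial_wetting_saturation
        self.S = np.full(self.n, self.S0, dtype=float)
        self.config = config
        self.t = 0.0
        self.steps = 0
        self.max_budget_err = 0.0
        self.cum_influx = 0.0  # integral of (q_in - q_out) dt

        # frozen scalars for the fast closure evaluation
        rw, rn = medium.residual_saturations
        self._rw = rw
        self._inv_span = 1.0 / (1.0 - rw - rn)
        lp = closure.pore_size_distribution_index
        self._e_w = (2.0 + 3.0 * lp) / lp
        self._e_n = (2.0 + lp) / lp
        self._e_pc = -(1.0 + lp) / lp
        self._pc_scale = closure.entry_capillary_pressure / lp
        self._inv_mu_w = 1.0 / wetting.dynamic_viscosity
        self._inv_mu_n = 1.0 / nonwetting.dynamic_viscosity
        self._k = medium.permeability
        self._rho_g = (
            wetting.density * config.gravity if config.gravity_enabled else 0.0
        )
        self._lam_w_of = (
            lambda Se: self._k * Se**self._e_w * self._inv_mu_w
        )  # for the gravity term only

        # tabulated closures on a fine saturation grid
        self._S_grid = np.linspace(0.0, 1.0, self.TABLE_SIZE)
        S_grid = self._S_grid
        dS_grid = S_grid[1] - S_grid[0]
        D_grid = self._diffusivity(S_grid)
        # Kirchhoff potential K(S) = int D ds for the diffusive flux
        K = np.empty_like(D_grid)
        K[0] = 0.0
        np.cumsum(0.5 * (D_grid[:-1] + D_grid[1:]) * dS_grid, out=K[1:])
        self._K_grid = K
        self._K_sat = float(K[-1])  # K(1)
        # phase mobilities, fractional flow, and the capillary drive
        # potential A(S) = int f_w (-dpc/dS) ds for the total velocity
        Se_g = np.clip((S_grid - self._rw) * self._inv_span, SE_FLOOR, 1.0)
        lam_w_g = Se_g**self._e_w * self._inv_mu_w
        lam_n_g = (1.0 - Se_g) ** 2 * (1.0 - Se_g**self._e_n) * self._inv_mu_n
        self._lam_t_grid = lam_w_g + lam_n_g
        self._lam_n_grid = lam_n_g
        fw = lam_w_g / (lam_w_g + lam_n_g + 1e-300)
        self._fw_grid = fw
        self._fw_lipschitz = float(np.max(np.abs(np.diff(fw)))) / dS_grid
        minus_dpc_dS = self._pc_scale * Se_g**self._e_pc * self._inv_span
        a_int = fw * minus_dpc_dS
        A = np.empty_like(a_int)
        A[0] = 0.0
        np.cumsum(0.5 * (a_int[:-1] + a_int[1:]) * dS_grid, out=A[1:])
        self._A_grid = A
        self._A_sat = float(A[-1])  # A(1)
        self._pec = closure.entry_capillary_pressure
        self._lam_w_sat = self._inv_mu_w  # kr_w(1) = 1
        # Lipschitz bound of the gravity flux -k lam_w rho g for the CFL
        self._grav_lip = (
            self._rho_g * self._k * float(np.max(np.diff(lam_w_g))) / dS_grid
            if self._rho_g
            else 0.0
        )

    def _diffusivity(self, S):
        """D(S) on cells; fast path of :func:`capillary_diffusivity`."""
        Se = (S - self._rw) * self._inv_span
        Se = np.clip(Se, SE_FLOOR, 1.0)
        lam_w = Se**self._e_w * self._inv_mu_w
        lam_n = (1.0 - Se) ** 2 * (1.0 - Se**self._e_n) * self._inv_mu_n
        frac = lam_w * lam_n / (lam_w + lam_n + 1e-300)
        return self._k * frac * self._pc_scale * Se**self._e_pc * self._inv_span

    def _kirchhoff(self, S):
        return np.interp(S, self._S_grid, self._K_grid)

    def total_velocity(self, S) -> float:
        """Uniform total velocity u_T from the quasi-static pressure
        balance between the reservoir and the vented outlet."""
        lam_t = np.interp(S, self._S_grid, self._lam_t_grid)
        k, dx = self._k, self.dx
        R = float(np.sum(dx / (k * lam_t)))
        R += 0.5 * dx / (k * self._lam_w_sat)  # inlet half-cell, wetting only
        lam_n_out = float(np.interp(S[-1], self._S_grid, self._lam_n_grid))
        if lam_n_out <= 0.0:
            return 0.0  # outlet air connectivity lost: flow stops
        R += 0.5 * dx / (k * lam_n_out)  # outlet half-cell, air only
        drive = self._pec + self._A_sat - float(
            np.interp(S[-1], self._S_grid, self._A_grid)
        )
        return max(0.0, drive / R)

    def fluxes(self):
        """Face fluxes q (n+1,) and the stability denominator."""
        n, dx, S = self.n, self.dx, self.S
        K = self._kirchhoff(S)
        q = np.empty(n + 1)
        q[1:-1] = -(K[1:] - K[:-1]) / dx
        q[0] = -(K[0] - self._K_sat) / (0.5 * dx)  # ghost S = 1 at the inlet
        q[-1] = 0.0  # wetting phase cannot leave through the outlet
        # advective co-current term: upwind fractional flow times u_T
        # (u_T >= 0, so the upwind side is always the inlet side)
        u_T = self.total_velocity(S)
        if u_T > 0.0:
            fw = np.interp(S, self._S_grid, self._fw_grid)
            q[0] += u_T  # f_w(ghost = 1) = 1
            q[1:-1] += u_T * fw[:-1]
        if self._rho_g:
            # vertical strip, inlet at the bottom: gravity drags the
            # wetting phase back toward the reservoir (flux <= 0, so the
            # upwind side is the outlet side); the inlet face carries
            # the same drainage term so the first cell can shed back
            # into the reservoir
            Se = np.clip((S - self._rw) * self._inv_span, 0.0, 1.0)
            adv = -self._lam_w_of(Se) * self._rho_g
            q[1:-1] += adv[1:]
            q[0] += adv[0]
        # chord diffusivities (K(S_r)-K(S_l))/(S_r-S_l) at faces
        Dc = np.empty(n + 1)
        dS = S[1:] - S[:-1]
        small = np.abs(dS) < 1e-12
        Dc[1:-1] = np.where(
            small, 0.0, (K[1:] - K[:-1]) / np.where(small, 1.0, dS)
        )
        dS0 = S[0] - 1.0
        Dc[0] = (K[0] - self._K_sat) / dS0 if abs(dS0) > 1e-12 else 0.0
        Dc[-1] = 0.0
        # per-cell monotonicity denominator Dc_l/d_l + Dc_r/d_r, plus the
        # Lipschitz bound of the upwinded advective flux
        inv_d = np.full(n + 1, 1.0 / dx)
        inv_d[0] = 2.0 / dx
        w = Dc * inv_d
        denom = (
            float(np.max(w[:-1] + w[1:]))
            + u_T * self._fw_lipschitz
            + self._grav_lip
        )
        return q, denom

    def advance(self, t_stop: float) -> None:
        """One explicit step, landing exactly on ``t_stop`` if reached."""
        cfg = self.config
        q, denom = self.fluxes()
        dt = cfg.cfl_safety * self.phi * self.dx / max(denom, 1e-300)
        if dt < cfg.min_time_step:
            raise SolverError(
                f"time step collapsed to {dt:.3e} s at t = {self.t:.4f} s"
            )
        dt = min(dt, t_stop - self.t)
        dS = -(dt / (self.phi * self.dx)) * np.diff(q)
        S_new = self.S + dS
        storage_change = self.phi * self.dx * float(np.sum(dS))
        boundary_influx = dt * float(q[0] - q[-1])
        scale = max(abs(self.phi * self.dx * float(np.sum(S_new))), 1e-300)
        self.max_budget_err = max(
            self.max_budget_err, abs(storage_change - boundary_influx) / scale
        )
        if np.any(S_new > 1.0 + 1e-9) or np.any(S_new < self.S0 - 1e-9):
            raise SolverError(
                f"non-physical saturation at t = {self.t:.4f} s: "
                f"range [{S_new.min():.6f}, {S_new.max():.6f}]"
            )
        self.S = S_new
        self.t += dt
        self.steps += 1
        self.cum_influx += boundary_influx


def simulate(
    medium: PorousMediumParams,
    wetting: FluidSpec,
    nonwetting: FluidSpec,
    geom: StripGeometry,
    closure: ClosureModel | None = None,
    config: SolverConfig | None = None,
) -> SaturationField:
    """Integrate the saturation equation and return S(x, t) at the
    requested output times.

    The scheme is conservative by construction: the per-step storage
    change equals the net boundary influx to round-off, and the largest
    relative budget violation over the run is reported on the returned
    field.
    """
    if closure is None:
        closure = ClosureModel(
            entry_capillary_pressure=medium.entry_capillary_pressure,
            pore_size_distribution_index=medium.pore_size_distribution_index,
        )
    if config is None:
        config = SolverConfig()
    stepper = _Stepper(medium, wetting, nonwetting, geom, closure, config)

    out_times = np.array(sorted(set(config.output_times) | {config.end_time}))
    out_times = out_times[out_times <= config.end_time + 1e-12]
    snapshots = np.empty((len(out_times), stepper.n))
    next_out = 0

    while stepper.t < config.end_time - 1e-12:
        t_stop = out_times[next_out] if next_out < len(out_times) else config.end_time
        stepper.advance(t_stop)
        while next_out < len(out_times) and stepper.t >= out_times[next_out] - 1e-12:
            snapshots[next_out] = stepper.S
            next_out += 1

    while next_out < len(out_times):  # end_time landed exactly
        snapshots[next_out] = stepper.S
        next_out += 1

    return SaturationField(
        cell_centers=stepper.x,
        times=out_times,
        S=snapshots,
        geometry=geom,
        mass_balance_error=stepper.max_budget_err,
        cumulative_influx=stepper.cum_influx,
        step_count=stepper.steps,
        initial_saturation=stepper.S0,
    )


def _front_from_profile(x: np.ndarray, S: np.ndarray, threshold: float) -> float:
    """Largest x where the linearly interpolated saturation >= threshold."""
    above = S >= threshold
    if not above.any():
        return 0.0
    i = int(np.max(np.nonzero(above)))
    if i == len(S) - 1:
        return float(x[-1])
    # interpolate between the last cell above and the next cell below
    s1, s2 = S[i], S[i + 1]
    if s1 == s2:
        return float(x[i])
    frac = (s1 - threshold) / (s1 - s2)
    return float(x[i] + frac * (x[i + 1] - x[i]))


def front_position(field: SaturationField, threshold: float = 0.5) -> WickingTrace:
    """Visible-front trajectory: for each output time, the largest x whose
    interpolated saturation is at least ``threshold`` (0 if none)."""
    if not field.initial_saturation < threshold < 1:
        raise ValueError(
            "front threshold must lie strictly between the initial saturation and 1"
        )
    fronts = np.array(
        [
            _front_from_profile(field.cell_centers, field.S[j], threshold)
            for j in range(len(field.times))
        ]
    )
    L = field.geometry.length if field.geometry is not None else None
    return WickingTrace(
        times=field.times, front=fronts, source="simulated", strip_length=L
    )


def absorbed_mass(
    field: SaturationField,
    geom: StripGeometry,
    medium: PorousMediumParams,
    fluid: FluidSpec,
) -> WickingTrace:
    """Cumulative absorbed wetting-fluid mass m(t), kg.

    m(t) = rho * eps_p * width * thickness * sum_cells (S - S0) dx;
    bounded above by the fluid mass that fills the whole pore space.
    """
    dx = geom.length / field.S.shape[1]
    excess = np.clip(field.S - field.initial_saturation, 0.0, None)
    mass = (
        fluid.density
        * medium.porosity
        * geom.width
        * geom.thickness
        * np.sum(excess, axis=1)
        * dx
    )
    fronts = np.array(
        [
            _front_from_profile(field.cell_centers, field.S[j], 0.5)
            for j in range(len(field.times))
        ]
    )
    return WickingTrace(
        times=field.times,
        front=fronts,
        mass=mass,
        source="simulated",
        strip_length=geom.length,
    )


def time_to_front(
    medium: PorousMediumParams,
    wetting: FluidSpec,
    nonwetting: FluidSpec,
    geom: StripGeometry,
    target_length: float,
    closure: ClosureModel | None = None,
    config: SolverConfig | None = None,
) -> float:
    """Time at which the simulated front first reaches ``target_length``.

    Steps the solver until the threshold front crosses the target and
    interpolates the crossing time linearly; returns ``inf`` if the
    front never arrives within ``config.end_time``.
    """
    if closure is None:
        closure = ClosureModel(
            entry_capillary_pressure=medium.entry_capillary_pressure,
            pore_size_distribution_index=medium.pore_size_distribution_index,
        )
    if config is None:
        config = SolverConfig()
    stepper = _Stepper(medium, wetting, nonwetting, geom, closure, config)
    thr = config.front_threshold

    front_prev, t_prev = 0.0, 0.0
    check_every = 8  # front readoff is cheap but not free
    while stepper.t < config.end_time:
        stepper.advance(config.end_time)
        if stepper.steps % check_every == 0 or stepper.t >= config.end_time:
            front = _front_from_profile(stepper.x, stepper.S, thr)
            if front >= target_length:
                if front == front_prev:
                    return stepper.t
                frac = (target_length - front_prev) / (front - front_prev)
                return t_prev + frac * (stepper.t - t_prev)
            front_prev, t_prev = front, stepper.t
    return float("inf")
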