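"""Independent two-pressure (IMPES) formulation of the imbibition problem.

Rather than reducing the two-phase system to the single saturation
equation of :mod:`wicksim.darcy`, this solver keeps the non-wetting
(air) pressure as an unknown: each step solves the incompressibility
condition div(u_T) = 0 on a tridiagonal system (implicit pressure),
then advances the wetting saturation explicitly from the wetting-phase
Darcy flux (explicit saturation).  No uniform-total-velocity argument
is used; u_T emerges from the pressure solve.  It serves as the
cross-check oracle for the main solver on coarse grids.

Discretization notes: viscous fluxes use phase mobilities upwinded by
the solved pressure field (a first pass with arithmetic means supplies
the upwind directions, a second pass recomputes pressures with the
upwinded mobilities); the capillary contribution k lam_w dpc/dx is
integrated through its own Kirchhoff-style potential
B(S) = int k lam_w (-dpc/dS) dS and discretized by chords, which keeps
it finite across the sharp front where a pointwise mobility times the
(enormous) pc jump would wildly overshoot.

Boundary conditions mirror the main solver: at the inlet the strip
touches the reservoir (ghost state S = 1, wetting pressure 0, air
pressure pc(1) = pec); at the outlet the wetting phase cannot leave
while air vents to the atmosphere (p_n = 0) through its upstream
mobility, so flow shuts off once the outlet region saturates.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

from .darcy import (
    ClosureModel,
    SaturationField,
    SolverConfig,
    SolverError,
    _Stepper,
    capillary_pressure,
)
from .membranes import FluidSpec, PorousMediumParams, StripGeometry


def simulate_two_pressure(
    medium: PorousMediumParams,
    wetting: FluidSpec,
    nonwetting: FluidSpec,
    geom: StripGeometry,
    closure: ClosureModel | None = None,
    config: SolverConfig | None = None,
) -> SaturationField:
    """IMPES integration of the two-phase system; same outputs as
    :func:`wicksim.darcy.simulate`."""
    if closure is None:
        closure = ClosureModel(
            entry_capillary_pressure=medium.entry_capillary_pressure,
            pore_size_distribution_index=medium.pore_size_distribution_index,
        )
    if config is None:
        config = SolverConfig()
    k = medium.permeability
    if k is None:
        raise ValueError("medium.permeability is not set; calibrate first")

    n = config.cell_count
    dx = geom.length / n
    x = (np.arange(n) + 0.5) * dx
    phi = medium.porosity
    S0 = medium.initial_wetting_saturation
    mu_w = wetting.dynamic_viscosity
    mu_n = nonwetting.dynamic_viscosity
    rw, rn = medium.residual_saturations
    inv_span = 1.0 / (1.0 - rw - rn)
    lp = closure.pore_size_distribution_index
    e_w = (2.0 + 3.0 * lp) / lp
    e_n = (2.0 + lp) / lp
    S = np.full(n, S0, dtype=float)

    # chord potential B(S) = int k lam_w (-dpc/dS) dS for the capillary flux
    S_grid = np.linspace(0.0, 1.0, _Stepper.TABLE_SIZE)
    Se_g = np.clip((S_grid - rw) * inv_span, 1e-6, 1.0)
    lam_w_g = Se_g**e_w / mu_w
    minus_dpc = (
        (closure.entry_capillary_pressure / lp)
        * Se_g ** (-(1.0 + lp) / lp)
        * inv_span
    )
    b_int = k * lam_w_g * minus_dpc
    dS_grid = S_grid[1] - S_grid[0]
    B = np.empty_like(b_int)
    B[0] = 0.0
    np.cumsum(0.5 * (b_int[:-1] + b_int[1:]) * dS_grid, out=B[1:])
    B_sat = float(B[-1])

    # ghost (reservoir) state at the inlet face
    pc_ghost = capillary_pressure(1.0, closure)  # = pec
    lam_w_ghost = 1.0 / mu_w  # kr_w(1) = 1
    lam_n_ghost = 0.0
    p_n_ghost = pc_ghost  # p_w_ghost = 0

    out_times = np.array(sorted(set(config.output_times) | {config.end_time}))
    out_times = out_times[out_times <= config.end_time + 1e-12]
    snapshots = np.empty((len(out_times), n))
    next_out = 0

    # time-step control borrowed from the main solver's chord bound
    helper = _Stepper(medium, wetting, nonwetting, geom, closure, config)

    t = 0.0
    max_budget_err = 0.0
    steps = 0
    while t < config.end_time - 1e-12:
        Se = np.clip((S - rw) * inv_span, 1e-12, 1.0)
        lam_w = Se**e_w / mu_w
        lam_n = (1.0 - Se) ** 2 * (1.0 - Se**e_n) / mu_n
        Bc = np.interp(S, S_grid, B)

        # capillary term per interior face: q_cap = -(B_r - B_l)/dx
        q_cap = -(Bc[1:] - Bc[:-1]) / dx
        q_cap_in = -(Bc[0] - B_sat) / (0.5 * dx)

        def solve_pressure(lw_f, ln_f, lw_in, ln_in, ln_out):
            # assemble div(u_T) = 0 with
            #   u_T(face) = -k lt_f (p_r - p_l)/d + q_cap(face)
            T_int = k * (lw_f + ln_f) / dx
            T_in = k * (lw_in + ln_in) / (0.5 * dx)
            T_out = k * ln_out / (0.5 * dx)
            diag = np.zeros(n)
            rhs = np.zeros(n)
            diag[:-1] += T_int
            diag[1:] += T_int
            rhs[:-1] -= q_cap  # +div contribution of the right face
            rhs[1:] += q_cap  # -div contribution of the left face
            diag[0] += T_in
            rhs[0] += T_in * p_n_ghost - q_cap_in
            diag[-1] += T_out  # atmospheric air (p = 0) at the outlet
            ab = np.zeros((3, n))
            ab[0, 1:] = -T_int
            ab[1, :] = diag
            ab[2, :-1] = -T_int
            return solve_banded((1, 1), ab, rhs)

        # pass 1: arithmetic means give a provisional pressure field
        p = solve_pressure(
            0.5 * (lam_w[:-1] + lam_w[1:]),
            0.5 * (lam_n[:-1] + lam_n[1:]),
            0.5 * (lam_w_ghost + lam_w[0]),
            0.5 * (lam_n_ghost + lam_n[0]),
            lam_n[-1],
        )
        # pass 2: upwind both phase mobilities by the provisional
        # pressures (an air-free saturated cell then transmits no air)
        left_up = p[:-1] >= p[1:]
        lw_f = np.where(left_up, lam_w[:-1], lam_w[1:])
        ln_f = np.where(left_up, lam_n[:-1], lam_n[1:])
        lw_in = lam_w_ghost if p_n_ghost >= p[0] else lam_w[0]
        ln_in = lam_n_ghost if p_n_ghost >= p[0] else lam_n[0]
        ln_out = lam_n[-1]
        p = solve_pressure(lw_f, ln_f, lw_in, ln_in, ln_out)

        # wetting flux: viscous part from the solved air pressure plus
        # the chorded capillary part
        q_w = np.empty(n + 1)
        q_w[1:-1] = -k * lw_f * (p[1:] - p[:-1]) / dx + q_cap
        q_w[0] = -k * lw_in * (p[0] - p_n_ghost) / (0.5 * dx) + q_cap_in
        q_w[-1] = 0.0  # wetting phase trapped at the outlet

        # time step: chord bound of the equivalent saturation equation
        # with an extra margin for the differing mobility averaging
        helper.S = S
        _, denom = helper.fluxes()
        dt = 0.25 * config.cfl_safety * phi * dx / max(denom, 1e-300)
        if dt < config.min_time_step:
            raise SolverError(f"time step collapsed to {dt:.3e} s at t = {t:.4f} s")
        t_stop = out_times[next_out] if next_out < len(out_times) else config.end_time
        dt = min(dt, t_stop - t, config.end_time - t)

        dS = -(dt / (phi * dx)) * np.diff(q_w)
        S_new = np.clip(S + dS, S0, 1.0)
        clip_err = float(np.sum(np.abs(S_new - (S + dS))))
        storage_change = phi * dx * float(np.sum(dS))
        boundary_influx = dt * float(q_w[0] - q_w[-1])
        scale = max(abs(phi * dx * float(np.sum(S_new))), 1e-300)
        max_budget_err = max(
            max_budget_err,
            (abs(storage_change - boundary_influx) + phi * dx * clip_err) / scale,
        )
        S = S_new
        t += dt
        steps += 1
        while next_out < len(out_times) and t >= out_times[next_out] - 1e-12:
            snapshots[next_out] = S
            next_out += 1

    while next_out < len(out_times):
        snapshots[next_out] = S
        next_out += 1

    return SaturationField(
        cell_centers=x,
        times=out_times,
        S=snapshots,
        geometry=geom,
        mass_balance_error=max_budget_err,
        step_count=steps,
        initial_saturation=S0,
    )
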