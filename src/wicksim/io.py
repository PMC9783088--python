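"""Delimited-text readers/writers, config handling, and the end-to-end
pipeline.

All files are comma-separated with a header row and SI units encoded in
the column names (time_s, front_m, mass_kg).  Configs are YAML with the
key names of the published parameter table (sigma, Rc, lp, por, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, membranes
from .comparison import ComparisonReport
from .trace import WickingTrace

logger = logging.getLogger("wicksim")


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed."""


def read_trace(path, source: str = "observed") -> WickingTrace:
    """Read a trace table with columns time_s, front_m (optional mass_kg)."""
    path = Path(path)
    if not path.exists():
        raise TraceParseError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    for col in ("time_s", "front_m"):
        if col not in df.columns:
            raise TraceParseError(f"missing column {col!r} in {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise TraceParseError(f"non-numeric cell in column {col!r} of {path}")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise TraceParseError(f"non-monotone time column in {path}")
    mass = df["mass_kg"].to_numpy(dtype=float) if "mass_kg" in df.columns else None
    return WickingTrace(
        times=times, front=df["front_m"].to_numpy(dtype=float), mass=mass,
        source=source,
    )


def write_trace(trace: WickingTrace, path) -> None:
    """Write a trace as a comma-separated table with a header row."""
    trace.to_frame().to_csv(path, index=False, float_format="%.12g")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    membrane: str = "CF4"
    model: str = "lw"  # "lw" | "solver"
    output_dir: Path | None = None
    tolerance: float = comparison.DEFAULT_TOLERANCE
    overrides: dict = field(default_factory=dict)
    cell_count: int = 240
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.model not in ("lw", "solver"):
            raise ValueError("model must be 'lw' or 'solver'")
        membranes._canonical(self.membrane)  # raises on unknown membrane
        unknown = set(self.overrides) - set(membranes.CONFIG_KEYS) - {"k"}
        if unknown:
            raise KeyError(
                f"unknown override keys: {sorted(unknown)}; "
                f"valid keys: {sorted(membranes.CONFIG_KEYS)}"
            )


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Preset -> calibrate -> predict/simulate -> compare against the
    observed fixtures; writes intermediate tables when an output
    directory is configured.  Deterministic given the config."""
    from . import calibration, darcy, lucas_washburn as lw

    spec, medium, geom = membranes.get_preset(config.membrane)
    base = membranes.preset_to_config(spec, medium, geom)
    base.update(config.overrides)
    spec, medium, geom, wetting, nonwetting, aux = membranes.config_to_preset(base)
    logger.info("pipeline parameters in effect: %s", base)

    observed = comparison.load_paper_fixtures(config.membrane)
    times = observed.times

    if config.model == "lw":
        cal = calibration.permeability_from_wicking_rate(
            spec, wetting, medium, "lw"
        )
        params = lw.LWParams(
            permeability=cal.value,
            surface_tension=wetting.surface_tension,
            contact_angle=wetting.contact_angle,
            porosity=medium.porosity,
            viscosity=wetting.dynamic_viscosity,
            pore_radius=medium.pore_radius,
        )
        front = np.minimum(lw.lw_front(params, times), geom.length)
        mass = lw.lw_mass(params, geom, wetting, times)
        simulated = WickingTrace(
            times=times, front=front, mass=mass, source="simulated",
            strip_length=geom.length,
        )
    else:
        cal = calibration.permeability_from_wicking_rate(
            spec, wetting, medium, "solver",
            geom=geom, nonwetting=nonwetting,
            solver_config=darcy.SolverConfig(
                cell_count=config.cell_count,
                end_time=20.0 * spec.wicking_rate,
            ),
        )
        medium = medium.with_permeability(cal.value)
        sim_cfg = darcy.SolverConfig(
            cell_count=config.cell_count,
            end_time=float(times[-1]),
            output_times=tuple(times),
        )
        fld = darcy.simulate(medium, wetting, nonwetting, geom, config=sim_cfg)
        simulated = darcy.absorbed_mass(fld, geom, medium, wetting)

    report = comparison.compare(
        observed,
        simulated,
        tolerance=config.tolerance,
        membrane=spec.name,
        exclude_saturated_beyond=0.995 * geom.length,
    )
    logger.info("calibrated %s = %.6e (%s)", cal.parameter_name, cal.value, cal.anchor)
    logger.info("%s", report.summary())

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trace(observed, outdir / "observed.csv")
        write_trace(simulated, outdir / "simulated.csv")
        report.table.to_csv(outdir / "report.csv", index=False, float_format="%.12g")
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(report.summary() + "\n")
    return report
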