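"""Synthetic bench-style observations.

Emulates the structure of the study's three kinds of measurements so
that every pipeline stage is testable without external data:

* wicking fronts read off with a millimetre ruler and a timer over a
  6 cm strip (additive Gaussian noise plus quantization to the ruler
  grid);
* DNA/RNA/protein concentration per 1 cm strip segment measured by
  fluorometry (piecewise mean profile times lognormal noise);
* 21-point saliva viscosity series for stimulated vs unstimulated
  saliva.

The analyte generator is explicitly phenomenological: the study defines
no capture/elution mechanism for nucleic acids on paper, so segment
means are pinned to the concentrations stated in its text (400 ng/uL
over the first 2 cm for CF4 and Fusion 5, a 700 ng/uL peak at 5 cm on
CF4, and at most 200 ng/uL over the first 4 cm on MF1).  RNA and
protein levels are never stated numerically and are generated as scaled
copies of the DNA profile; those scalings are unanchored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .membranes import DEFAULT_STRIP_LENGTH, SALIVA_VISCOSITY, UnknownMembraneError, _canonical
from .trace import WickingTrace

ANALYTES = ("DNA", "RNA", "protein")
SALIVA_TYPES = ("stimulated", "unstimulated")

#: Number of rheometer readings per viscosity series (one per minute).
VISCOSITY_SERIES_LENGTH = 21


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description shared by the generators.

    front_noise_sd: ruler-reading scatter, m (default 2 mm, matching the
    0.1-0.5 cm run-to-run oscillations of the bench traces).
    quantization: ruler resolution, m (default 1 mm).
    concentration_cv: coefficient of variation of the lognormal
    multiplicative noise on analyte concentrations.
    """

    front_noise_sd: float = 0.002  # m
    quantization: float = 0.001  # m
    concentration_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.front_noise_sd < 0 or self.quantization < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.concentration_cv < 0:
            raise ValueError("concentration_cv must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class AnalyteProfile:
    """Concentration of one analyte per 1 cm strip segment."""

    analyte: str
    saliva_type: str
    membrane: str
    segment_edges: np.ndarray  # m, length n_segments + 1
    concentration: np.ndarray  # ng/uL per segment

    def __post_init__(self) -> None:
        self.segment_edges = np.asarray(self.segment_edges, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if len(self.segment_edges) != len(self.concentration) + 1:
            raise ValueError("need one more edge than segments")
        if np.any(np.diff(self.segment_edges) <= 0):
            raise ValueError("segment edges must be strictly increasing")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be non-negative")


def generate_wicking_observations(
    true_trace: WickingTrace,
    noise: NoiseModel,
    strip_length: float | None = None,
) -> WickingTrace:
    """Ruler-and-timer reading of a true front trajectory.

    Adds zero-mean Gaussian noise (sd ``front_noise_sd``), rounds to the
    quantization grid, and clamps to [0, L0].  Reproducible under a
    fixed seed.
    """
    L0 = strip_length or true_trace.strip_length or DEFAULT_STRIP_LENGTH
    rng = noise.rng()
    front = true_trace.front + rng.normal(0.0, noise.front_noise_sd, len(true_trace))
    if noise.quantization > 0:
        front = np.round(front / noise.quantization) * noise.quantization
    front = np.clip(front, 0.0, L0)
    return WickingTrace(
        times=true_trace.times.copy(),
        front=front,
        source="synthetic",
        strip_length=L0,
    )


# segment means in ng/uL over the six 1 cm segments, DNA, stimulated saliva
_DNA_SEGMENT_MEANS = {
    # 400 on the first 2 cm, rising to the 700 peak at the 5 cm segment;
    # the front stalled at 5 cm on CF4, so the last segment is nearly dry
    "cf4": (400.0, 400.0, 450.0, 550.0, 700.0, 50.0),
    # 400 on the first 2 cm, declining along the strip
    "fusion5": (400.0, 400.0, 350.0, 300.0, 250.0, 200.0),
    # capped at 200 over the first 4 cm, never reaching 400
    "mf1": (200.0, 200.0, 200.0, 200.0, 300.0, 250.0),
}

# unanchored relative scalings for analytes other than DNA; MF1 extracts
# RNA and protein best in the study's qualitative account
_ANALYTE_SCALE = {
    ("DNA", "cf4"): 1.0,
    ("DNA", "fusion5"): 1.0,
    ("DNA", "mf1"): 1.0,
    ("RNA", "cf4"): 0.25,
    ("RNA", "fusion5"): 0.3,
    ("RNA", "mf1"): 0.5,
    ("protein", "cf4"): 0.4,
    ("protein", "fusion5"): 0.4,
    ("protein", "mf1"): 0.6,
}

# RNA extraction was reported higher from stimulated saliva; DNA showed
# no SS/US difference
_SALIVA_TYPE_SCALE = {
    ("RNA", "stimulated"): 1.1,
    ("RNA", "unstimulated"): 0.9,
}


def generate_analyte_profile(
    membrane: str,
    analyte: str = "DNA",
    saliva_type: str = "stimulated",
    noise: NoiseModel | None = None,
) -> AnalyteProfile:
    """Per-segment analyte concentrations with lognormal noise.

    With ``concentration_cv = 0`` the profile is the deterministic mean,
    identical across seeds.
    """
    key = _canonical(membrane)
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}; valid: {ANALYTES}")
    if saliva_type not in SALIVA_TYPES:
        raise ValueError(f"unknown saliva type {saliva_type!r}; valid: {SALIVA_TYPES}")
    if noise is None:
        noise = NoiseModel()
    mean = np.array(_DNA_SEGMENT_MEANS[key])
    mean = mean * _ANALYTE_SCALE[(analyte, key)]
    mean = mean * _SALIVA_TYPE_SCALE.get((analyte, saliva_type), 1.0)
    cv = noise.concentration_cv
    if cv > 0:
        # lognormal factor with unit mean and the requested cv
        sigma2 = math.log(1.0 + cv * cv)
        factors = noise.rng().lognormal(-0.5 * sigma2, math.sqrt(sigma2), len(mean))
        conc = mean * factors
    else:
        conc = mean.copy()
    edges = np.arange(len(mean) + 1) * 0.01  # 1 cm segments over 6 cm
    return AnalyteProfile(
        analyte=analyte,
        saliva_type=saliva_type,
        membrane=key,
        segment_edges=edges,
        concentration=conc,
    )


def generate_viscosity_series(
    saliva_type: str,
    noise: NoiseModel | None = None,
) -> np.ndarray:
    """21-point viscosity series (Pa s) around the measured means:
    0.002 for stimulated, 0.00234 for unstimulated saliva."""
    if saliva_type not in SALIVA_TYPES:
        raise ValueError(f"unknown saliva type {saliva_type!r}; valid: {SALIVA_TYPES}")
    if noise is None:
        noise = NoiseModel()
    mean = SALIVA_VISCOSITY[saliva_type]
    cv = noise.concentration_cv
    if cv > 0:
        sigma2 = math.log(1.0 + cv * cv)
        factors = noise.rng().lognormal(
            -0.5 * sigma2, math.sqrt(sigma2), VISCOSITY_SERIES_LENGTH
        )
        return mean * factors
    return np.full(VISCOSITY_SERIES_LENGTH, mean)
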