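"""Time series of a wicking experiment: front position and absorbed mass."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_SOURCES = ("simulated", "observed", "synthetic")


@dataclass
class WickingTrace:
    """Front position (and optionally absorbed mass) versus time.

    Parameters
    ----------
    times : array-like of float
        Sample times in seconds, strictly increasing.
    front : array-like of float
        Front position in metres at each sample time.
    mass : array-like of float, optional
        Absorbed fluid mass in kilograms at each sample time.
    source : {"simulated", "observed", "synthetic"}
        Provenance of the trace.  Simulated traces must have a
        non-decreasing front; observed/synthetic traces may not,
        because of measurement noise.
    """

    times: np.ndarray
    front: np.ndarray
    mass: np.ndarray | None = None
    source: str = "simulated"
    strip_length: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.front = np.asarray(self.front, dtype=float)
        if self.mass is not None:
            self.mass = np.asarray(self.mass, dtype=float)
        if self.source not in VALID_SOURCES:
            raise ValueError(
                f"source must be one of {VALID_SOURCES}, got {self.source!r}"
            )
        if self.times.ndim != 1 or self.front.shape != self.times.shape:
            raise ValueError("times and front must be 1-D arrays of equal length")
        if self.mass is not None and self.mass.shape != self.times.shape:
            raise ValueError("mass must match times in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.front < 0):
            raise ValueError("front positions must be non-negative")
        if self.strip_length is not None and np.any(
            self.front > self.strip_length * (1 + 1e-9)
        ):
            raise ValueError("front positions exceed the strip length")
        if self.source == "simulated" and len(self.times) > 1:
            if np.any(np.diff(self.front) < -1e-12):
                raise ValueError("simulated front must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        """Return the trace as a pandas DataFrame with SI-unit column names."""
        import pandas as pd

        data = {"time_s": self.times, "front_m": self.front}
        if self.mass is not None:
            data["mass_kg"] = self.mass
        return pd.DataFrame(data)
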