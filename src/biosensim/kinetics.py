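"""Reversible first-order surface binding on the sensor strip.

Per sensor node the bound surface concentration obeys

    db/dt = kon * c_eff * (bmax - b) - koff * b

with ``c_eff`` either the local wall concentration (default; required
for the Neumann coupling of the bulk to be self-consistent) or the inlet
concentration (the literal rate equation as printed, kept as an option
for comparison).  With ``c_eff`` frozen over a time step the ODE is
linear in ``b`` and is advanced by its exact exponential solution, which
keeps ``b`` in [0, bmax] unconditionally for any step size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurfaceKineticsParams",
    "SurfaceState",
    "langmuir_rate",
    "advance_surface",
    "sensor_flux_values",
    "mean_normalized_coverage",
]


@dataclass(frozen=True)
class SurfaceKineticsParams:
    kon: float  # m^3 mol^-1 s^-1
    koff: float  # s^-1
    bmax: float  # mol m^-2  (surface site density)
    concentration_source: str = "local"  # "local" | "inlet"

    def __post_init__(self) -> None:
        if self.kon < 0 or self.koff < 0:
            raise ValueError("rate constants must be non-negative")
        if self.bmax <= 0:
            raise ValueError("bmax must be positive")
        if self.concentration_source not in ("local", "inlet"):
            raise ValueError("concentration_source must be 'local' or 'inlet'")


@dataclass
class SurfaceState:
    b: np.ndarray  # mol m^-2, one entry per sensor node
    t: float = 0.0


def langmuir_rate(
    c_w: np.ndarray | float, b: np.ndarray | float, params: SurfaceKineticsParams
) -> np.ndarray | float:
    """db/dt at the given wall concentration and coverage."""
    return params.kon * c_w * (params.bmax - b) - params.koff * b


def advance_surface(
    b: np.ndarray, c_eff: np.ndarray | float, params: SurfaceKineticsParams, dt: float
) -> np.ndarray:
    """Exact exponential update of the linear-in-b ODE over one step.

    ``b_new = b_eq + (b - b_eq) * exp(-k*dt)`` with
    ``k = kon*c_eff + koff`` and ``b_eq = bmax*kon*c_eff / k``; when the
    total rate k vanishes the state is unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    b = np.asarray(b, dtype=float)
    c_eff = np.broadcast_to(np.asarray(c_eff, dtype=float), b.shape)
    k = params.kon * c_eff + params.koff
    with np.errstate(divide="ignore", invalid="ignore"):
        b_eq = np.where(k > 0, params.bmax * params.kon * c_eff / np.where(k > 0, k, 1.0), b)
    return b_eq + (b - b_eq) * np.exp(-k * dt)


def sensor_flux_values(b_old: np.ndarray, b_new: np.ndarray, dt: float) -> np.ndarray:
    """Mean uptake rate over the step, handed to the transport sink."""
    b_old = np.asarray(b_old)
    b_new = np.asarray(b_new)
    if b_old.shape != b_new.shape:
        raise ValueError("inconsistent sensor node lists")
    return (b_new - b_old) / dt


def mean_normalized_coverage(b: np.ndarray, bmax: float, lengths: np.ndarray) -> float:
    """Length-weighted mean of b over the strip, normalized by bmax."""
    lengths = np.asarray(lengths, dtype=float)
    total = lengths.sum()
    if b.size == 0 or total <= 0:
        raise ValueError("empty sensor")
    return float(np.sum(np.asarray(b) * lengths) / total / bmax)
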