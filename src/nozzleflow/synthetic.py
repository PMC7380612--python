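"""Synthetic test inputs: noisy flow curves and rheometer-like viscosity tables.

Everything here is a pure function of (parameters, seed), so the test suite
and examples build with no external data.  The standard experimental design
emulated throughout the package is a bioprinter capillary-rheometry run:
a 21G blunt steel needle (28 mm long, 551 um inner diameter) with the
driving pressure stepped from 20 kPa to 200 kPa in 20 kPa increments.

Noise is multiplicative with a fixed coefficient of variation: flow rates
span roughly three decades across that pressure sweep, so constant-cv noise
is the realistic scale model (a constant additive error would drown the
low-pressure points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rheometry import FlowCurveMeasurement, predict_flow_curve
from .solver import ChannelGeometry
from .viscosity import (
    DEFAULT_FIT_GRID,
    ShearRateGrid,
    TabulatedViscosity,
    ViscosityModel,
)

__all__ = [
    "NoiseSpec",
    "generate_flow_curve_data",
    "generate_viscosity_table",
    "STANDARD_NEEDLE",
    "STANDARD_PRESSURE_SWEEP",
]

#: 21G blunt cannula: 28 mm length, 551 um inner diameter.
STANDARD_NEEDLE = ChannelGeometry(radius=275.5e-6, length=28e-3)

#: Stepwise pressure ramp, 20..200 kPa in 20 kPa steps.
STANDARD_PRESSURE_SWEEP = np.arange(20e3, 200e3 + 1.0, 20e3)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative noise level (coefficient of variation) plus RNG seed."""

    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("coefficient of variation must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_flow_curve_data(
    true_params: ViscosityModel,
    geometry: ChannelGeometry = STANDARD_NEEDLE,
    pressures: np.ndarray = STANDARD_PRESSURE_SWEEP,
    noise: NoiseSpec = NoiseSpec(),
    grid: ShearRateGrid = DEFAULT_FIT_GRID,
) -> FlowCurveMeasurement:
    """Synthetic flow curve: Q_j = Q_model(p_j) * (1 + eps_j), eps ~ N(0, cv).

    ``cv`` must stay below 0.5 so the multiplicative factor cannot plausibly
    go non-positive (factors are floored at 0.05 as a guard).
    """
    if noise.cv >= 0.5:
        raise ValueError("cv must be below 0.5 for multiplicative noise")
    pressures = np.asarray(pressures, dtype=float)
    Q = predict_flow_curve(true_params, geometry, pressures, grid=grid, auto_extend=True)
    factors = 1.0 + noise.rng().normal(0.0, noise.cv, size=Q.size) if noise.cv > 0 else np.ones_like(Q)
    factors = np.maximum(factors, 0.05)
    return FlowCurveMeasurement(pressures, Q * factors, geometry)


def generate_viscosity_table(
    model: ViscosityModel,
    grid: ShearRateGrid = DEFAULT_FIT_GRID,
    noise: NoiseSpec = NoiseSpec(),
) -> TabulatedViscosity:
    """Rheometer-like table: log-normal multiplicative noise on eta at the nodes."""
    nodes = grid.nodes()
    eta = np.asarray(model.viscosity(nodes), dtype=float)
    if noise.cv > 0:
        eta = eta * np.exp(noise.rng().normal(0.0, noise.cv, size=eta.size))
    return TabulatedViscosity(nodes, eta)
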