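"""Generalized-Newtonian material laws and their piecewise power-law interpolation.

A generalized Newtonian fluid is an inelastic fluid whose viscosity depends
only on the instantaneous shear rate, ``eta(gammadot)``.  Shear-thinning
bioinks (alginate, chitosan and other hydrogels) are usually characterised by
a Carreau--Yasuda law: a Newtonian plateau at low shear rates, a power-law
thinning region, and (in the five-parameter form) a second plateau at high
shear rates.

The central construction of this module interpolates *any* such law by a set
of continuous power-law segments

    eta_i(gammadot) = K_i * gammadot**(n_i - 1),   Gamma_{i-1} <= gammadot <= Gamma_i,

on a logarithmically spaced shear-rate grid.  Demanding continuity of the
reconstructed viscosity at every interior grid node, together with exactness
at the nodes, uniquely fixes the consistency ``K_i`` and exponent ``n_i`` of
every segment:

    n_i = 1 + ln(eta(Gamma_i)/eta(Gamma_{i-1})) / ln(Gamma_i/Gamma_{i-1})
    K_i = eta(Gamma_i) / Gamma_i**(n_i - 1)

The piecewise representation is what makes an exact analytic solution of the
pipe-flow problem possible (see :mod:`nozzleflow.solver`).

All quantities are SI: shear rates in 1/s, viscosities in Pa*s.
"""

from __future__ import annotations

import abc
import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "ViscosityModel",
    "Newtonian",
    "PowerLaw",
    "SimplifiedCarreauYasuda",
    "CarreauYasuda3",
    "CarreauYasuda5",
    "TabulatedViscosity",
    "ShearRateGrid",
    "PiecewisePowerLaw",
    "interpolate_piecewise",
    "DEFAULT_PROFILE_GRID",
    "DEFAULT_FIT_GRID",
    "TABLE_CSV_COLUMNS",
]

ArrayLike = Union[float, np.ndarray]

#: Column names of the tabulated-viscosity CSV dialect.
TABLE_CSV_COLUMNS = ("shear_rate_per_s", "viscosity_Pa_s")


def _as_shear_rate(gammadot: ArrayLike) -> np.ndarray:
    g = np.asarray(gammadot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    return g


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


class ViscosityModel(abc.ABC):
    """Base class for material laws ``eta(gammadot)``.

    Subclasses implement :meth:`_viscosity` on a positive float array;
    :meth:`viscosity` handles validation and scalar round-tripping.
    """

    @abc.abstractmethod
    def _viscosity(self, gammadot: np.ndarray) -> np.ndarray:
        """Evaluate eta on a validated array of shear rates."""

    def viscosity(self, gammadot: ArrayLike) -> ArrayLike:
        """Viscosity in Pa*s at shear rate(s) ``gammadot`` in 1/s.

        Raises
        ------
        ValueError
            If any shear rate is negative.
        """
        g = _as_shear_rate(gammadot)
        out = self._viscosity(np.atleast_1d(g).astype(float))
        if np.ndim(gammadot) == 0:
            return float(out[0])
        return out

    # Convenience: eta(gammadot) via call syntax.
    __call__ = viscosity


@dataclass(frozen=True)
class Newtonian(ViscosityModel):
    """Constant-viscosity fluid, ``eta(gammadot) = eta``."""

    eta: float

    def __post_init__(self) -> None:
        _require(self.eta > 0, "eta must be positive")

    def _viscosity(self, gammadot: np.ndarray) -> np.ndarray:
        return np.full_like(gammadot, self.eta)


@dataclass(frozen=True)
class PowerLaw(ViscosityModel):
    """Ostwald-de Waele power law, ``eta = K * gammadot**(n-1)``.

    Parameters
    ----------
    K : float
        Consistency index, Pa*s**n.
    n : float
        Flow index (dimensionless); n < 1 is shear thinning.
    """

    K: float
    n: float

    def __post_init__(self) -> None:
        _require(self.K > 0, "consistency K must be positive")
        _require(self.n > 0, "flow index n must be positive")

    def _viscosity(self, gammadot: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return self.K * gammadot ** (self.n - 1.0)


@dataclass(frozen=True)
class SimplifiedCarreauYasuda(ViscosityModel):
    """Two-parameter shear-thinning law ``eta = eta_0 / (1 + K*gammadot)``.

    ``eta_0`` is the zero-shear viscosity (Pa*s) and ``K`` a time constant (s).
    The corresponding shear stress ``eta*gammadot`` saturates at ``eta_0/K``
    for large shear rates, which admits an exact global pipe-flow solution
    (see :func:`nozzleflow.oracles.simplified_cy_profile`).
    """

    eta_0: float
    K: float

    def __post_init__(self) -> None:
        _require(self.eta_0 > 0, "eta_0 must be positive")
        _require(self.K >= 0, "time constant K must be non-negative")

    def _viscosity(self, gammadot: np.ndarray) -> np.ndarray:
        return self.eta_0 / (1.0 + self.K * gammadot)


@dataclass(frozen=True)
class CarreauYasuda3(ViscosityModel):
    """Three-parameter Carreau--Yasuda law.

    ``eta = eta_0 * [1 + (gammadot/gammadot_c)**alpha]**(-1)``

    Parameters
    ----------
    eta_0 : float
        Zero-shear viscosity, Pa*s.
    gammadot_c : float
        Corner shear rate, 1/s — the transition from the Newtonian plateau to
        power-law thinning (reciprocal of the CY time constant).
    alpha : float
        Shear-thinning exponent (dimensionless); the high-shear viscosity
        decays as gammadot**(-alpha).
    """

    eta_0: float
    gammadot_c: float
    alpha: float

    def __post_init__(self) -> None:
        _require(self.eta_0 > 0, "eta_0 must be positive")
        _require(self.gammadot_c > 0, "gammadot_c must be positive")
        _require(self.alpha > 0, "alpha must be positive")

    def _viscosity(self, gammadot: np.ndarray) -> np.ndarray:
        return self.eta_0 / (1.0 + (gammadot / self.gammadot_c) ** self.alpha)

    def as_parameter_array(self) -> np.ndarray:
        return np.array([self.eta_0, self.gammadot_c, self.alpha])


@dataclass(frozen=True)
class CarreauYasuda5(ViscosityModel):
    """Five-parameter Carreau--Yasuda law.

    ``eta = eta_inf + (eta_0 - eta_inf) * [1 + (K*gammadot)**a1]**(-a2/a1)``

    ``eta_0`` / ``eta_inf`` are the zero- and infinite-shear plateau
    viscosities (Pa*s), ``K`` the time constant (s), and the exponents ``a1``
    and ``a2`` shape the plateau-to-power-law transition and the thinning
    slope.  With ``eta_inf = 0`` and ``a1 = a2 = alpha`` this reduces to
    :class:`CarreauYasuda3` with ``gammadot_c = 1/K``.
    """

    eta_inf: float
    eta_0: float
    K: float
    a1: float
    a2: float

    def __post_init__(self) -> None:
        _require(self.eta_inf >= 0, "eta_inf must be non-negative")
        _require(self.eta_0 > self.eta_inf, "eta_0 must exceed eta_inf")
        _require(self.K > 0, "time constant K must be positive")
        _require(self.a1 > 0, "a1 must be positive")
        _require(self.a2 > 0, "a2 must be positive")

    def _viscosity(self, gammadot: np.ndarray) -> np.ndarray:
        bracket = 1.0 + (self.K * gammadot) ** self.a1
        return self.eta_inf + (self.eta_0 - self.eta_inf) * bracket ** (
            -self.a2 / self.a1
        )


@dataclass(frozen=True)
class TabulatedViscosity(ViscosityModel):
    """Measured flow curve, e.g. from a rotational rheometer.

    Between tabulated points the viscosity is interpolated linearly in
    log-log space — i.e. the table is itself treated as piecewise power-law.
    Outside the measured range the end viscosities are held constant
    (Newtonian plateaus, the safest physical extrapolation).
    """

    shear_rates: np.ndarray
    viscosities: np.ndarray

    def __post_init__(self) -> None:
        sr = np.asarray(self.shear_rates, dtype=float)
        eta = np.asarray(self.viscosities, dtype=float)
        _require(sr.ndim == 1 and eta.ndim == 1, "expected 1-D arrays")
        _require(sr.size == eta.size, "shear rates and viscosities differ in length")
        _require(sr.size >= 2, "need at least 2 tabulated points")
        _require(np.all(sr > 0), "tabulated shear rates must be positive")
        _require(np.all(np.diff(sr) > 0), "tabulated shear rates must be strictly increasing")
        _require(np.all(eta > 0), "tabulated viscosities must be positive")
        object.__setattr__(self, "shear_rates", sr)
        object.__setattr__(self, "viscosities", eta)

    def _viscosity(self, gammadot: np.ndarray) -> np.ndarray:
        # Clip into the measured range: constant extrapolation of the ends.
        g = np.clip(gammadot, self.shear_rates[0], self.shear_rates[-1])
        return np.exp(
            np.interp(np.log(g), np.log(self.shear_rates), np.log(self.viscosities))
        )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TabulatedViscosity":
        """Read the two-column CSV dialect (``#`` lines are comments)."""
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        if tuple(df.columns) != TABLE_CSV_COLUMNS:
            raise ValueError(
                f"viscosity table {path}: expected header "
                f"{','.join(TABLE_CSV_COLUMNS)!r}, got {','.join(df.columns)!r}"
            )
        return cls(df[TABLE_CSV_COLUMNS[0]].to_numpy(), df[TABLE_CSV_COLUMNS[1]].to_numpy())

    def to_csv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(
            {TABLE_CSV_COLUMNS[0]: self.shear_rates, TABLE_CSV_COLUMNS[1]: self.viscosities}
        )
        df.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class ShearRateGrid:
    """Log-spaced shear-rate grid ``Gamma_0 .. Gamma_N`` for interpolation.

    Defaults span 1e-6 to 1e8 1/s, wide enough that the sub-grid core of the
    channel is vanishingly thin and realistic wall shear rates stay in range.
    """

    gammadot_min: float = 1e-6
    gammadot_max: float = 1e8
    n_intervals: int = 1000

    def __post_init__(self) -> None:
        _require(self.gammadot_min > 0, "gammadot_min must be positive")
        _require(
            self.gammadot_max > self.gammadot_min,
            "gammadot_max must exceed gammadot_min",
        )
        _require(int(self.n_intervals) >= 1, "need at least one interval")
        object.__setattr__(self, "n_intervals", int(self.n_intervals))

    def nodes(self) -> np.ndarray:
        """The N+1 grid nodes, log-spaced."""
        return np.geomspace(self.gammadot_min, self.gammadot_max, self.n_intervals + 1)

    def with_max(self, gammadot_max: float) -> "ShearRateGrid":
        return dataclasses.replace(self, gammadot_max=gammadot_max)


#: Grid used for profile computations (fine, matches typical usage).
DEFAULT_PROFILE_GRID = ShearRateGrid(1e-6, 1e8, 1000)
#: Coarser grid used inside capillary-rheometry fitting.
DEFAULT_FIT_GRID = ShearRateGrid(1e-6, 1e8, 150)

# Relative viscosity jump tolerated at interior bounds before the interpolant
# is considered discontinuous (constructed interpolants sit at ~1e-15).
_CONTINUITY_RTOL = 1e-12


@dataclass(frozen=True)
class PiecewisePowerLaw:
    """Continuous piecewise power-law viscosity ``K_i * gammadot**(n_i-1)``.

    ``bounds`` holds the N+1 shear-rate nodes; ``log_K`` and ``n`` the per-
    interval parameters.  The consistency is stored as ``log(K)`` and all
    evaluation happens in log space, which avoids overflow when ``n_i`` is
    small and the shear rate large.
    """

    bounds: np.ndarray
    log_K: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        bounds = np.asarray(self.bounds, dtype=float)
        log_K = np.asarray(self.log_K, dtype=float)
        n = np.asarray(self.n, dtype=float)
        _require(bounds.ndim == 1 and bounds.size >= 2, "need at least one interval")
        _require(np.all(bounds > 0), "bounds must be positive")
        _require(np.all(np.diff(bounds) > 0), "bounds must be strictly increasing")
        _require(log_K.size == n.size == bounds.size - 1, "inconsistent array lengths")
        _require(np.all(np.isfinite(log_K)), "non-finite consistency")
        _require(np.all(np.isfinite(n)), "non-finite exponent")
        object.__setattr__(self, "bounds", bounds)
        object.__setattr__(self, "log_K", log_K)
        object.__setattr__(self, "n", n)
        if n.size > 1:
            lg = np.log(bounds[1:-1])
            left = log_K[:-1] + (n[:-1] - 1.0) * lg
            right = log_K[1:] + (n[1:] - 1.0) * lg
            jump = np.max(np.abs(left - right))
            _require(
                jump <= _CONTINUITY_RTOL,
                f"viscosity discontinuous at an interior bound "
                f"(relative jump {jump:.3e} > {_CONTINUITY_RTOL:.0e})",
            )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_model(
        cls, model: ViscosityModel, grid: ShearRateGrid = DEFAULT_PROFILE_GRID
    ) -> "PiecewisePowerLaw":
        """Interpolate ``model`` on ``grid``.

        Each segment is anchored to match the model exactly at both of its
        endpoint nodes; this is equivalent to global continuity plus node
        exactness and fixes K_i and n_i uniquely.
        """
        nodes = grid.nodes()
        eta_nodes = np.asarray(model.viscosity(nodes), dtype=float)
        if not np.all(np.isfinite(eta_nodes)) or np.any(eta_nodes <= 0):
            bad = nodes[~(np.isfinite(eta_nodes) & (eta_nodes > 0))][0]
            raise ValueError(
                f"model viscosity is not positive and finite at shear rate {bad:g} 1/s"
            )
        log_nodes = np.log(nodes)
        log_eta = np.log(eta_nodes)
        n = 1.0 + np.diff(log_eta) / np.diff(log_nodes)
        log_K = log_eta[1:] - (n - 1.0) * log_nodes[1:]
        return cls(bounds=nodes, log_K=log_K, n=n)

    # -- basic queries -----------------------------------------------------

    @property
    def n_intervals(self) -> int:
        return self.n.size

    @property
    def K(self) -> np.ndarray:
        """Per-interval consistency indices, Pa*s**n_i."""
        return np.exp(self.log_K)

    def interval_of(self, gammadot: ArrayLike) -> np.ndarray:
        """0-based interval index containing each shear rate (in range)."""
        g = np.atleast_1d(np.asarray(gammadot, dtype=float))
        idx = np.searchsorted(self.bounds, g, side="right") - 1
        return np.clip(idx, 0, self.n_intervals - 1)

    def viscosity(self, gammadot: ArrayLike) -> ArrayLike:
        """Evaluate the interpolant; shear rate must lie within the grid.

        Raises
        ------
        ValueError
            If a shear rate falls outside ``[bounds[0], bounds[-1]]`` (the
            message names the violated bound).
        """
        g = np.atleast_1d(_as_shear_rate(gammadot))
        lo, hi = self.bounds[0], self.bounds[-1]
        if np.any(g < lo * (1.0 - 1e-12)):
            raise ValueError(
                f"shear rate {g[g < lo * (1 - 1e-12)][0]:g} 1/s below grid minimum {lo:g} 1/s"
            )
        if np.any(g > hi * (1.0 + 1e-12)):
            raise ValueError(
                f"shear rate {g[g > hi * (1 + 1e-12)][0]:g} 1/s above grid maximum {hi:g} 1/s"
            )
        g = np.clip(g, lo, hi)
        idx = self.interval_of(g)
        out = np.exp(self.log_K[idx] + (self.n[idx] - 1.0) * np.log(g))
        if np.ndim(gammadot) == 0:
            return float(out[0])
        return out

    __call__ = viscosity

    def to_frame(self) -> pd.DataFrame:
        """Segment table (one row per interval) for inspection/dumping."""
        return pd.DataFrame(
            {
                "gammadot_lo_per_s": self.bounds[:-1],
                "gammadot_hi_per_s": self.bounds[1:],
                "K_Pa_sn": self.K,
                "n": self.n,
            }
        )


def interpolate_piecewise(
    model: ViscosityModel, grid: ShearRateGrid = DEFAULT_PROFILE_GRID
) -> PiecewisePowerLaw:
    """Interpolate a material law by continuous power-law segments."""
    return PiecewisePowerLaw.from_model(model, grid)


def as_piecewise(
    model: Union[ViscosityModel, PiecewisePowerLaw],
    grid: ShearRateGrid = DEFAULT_PROFILE_GRID,
) -> PiecewisePowerLaw:
    """Pass through a ready interpolant or build one from a model."""
    if isinstance(model, PiecewisePowerLaw):
        return model
    return PiecewisePowerLaw.from_model(model, grid)
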