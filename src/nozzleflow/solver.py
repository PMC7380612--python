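"""Exact piecewise solution of generalized-Newtonian flow in a cylindrical nozzle.

For stationary, laminar, pressure-driven axial flow of a generalized
Newtonian fluid in a cylinder, the incompressible Navier--Stokes equations
reduce to

    G = (1/r) d/dr [ r * eta(gammadot) * du/dr ],        gammadot = -du/dr,

with a constant axial pressure gradient G = dp/dz = (p_0 - p_L)/L < 0 for
flow in +z.  With the viscosity interpolated by continuous power-law
segments (:class:`~nozzleflow.viscosity.PiecewisePowerLaw`), the equation is
solvable exactly in every radial shell where one segment applies:

    shear rate   gammadot_i(r) = (-G r / (2 K_i))**(1/n_i)
    stress       sigma(r)      = -G r / 2          (material independent)

The radial shells are delimited by the radii R_i at which the local shear
rate equals a grid node, R_i = 2 K_i Gamma_i**n_i / (-G).  Integrating the
shear rate inward from the no-slip wall and matching velocity across shells
gives, for r in shell i and the wall lying in shell k,

    u_i(r) = w_k * gd_w * A - w_i * gammadot_i(r) * r
             - sum_{b=i+1..k} R_b * Gamma_b * (w_b - w_{b-1}),

where w_i = n_i/(n_i+1), A is the channel radius and gd_w the wall shear
rate.  Flow rate and cross-sectional averages follow as closed-form sums
over shells.  All powers are evaluated in log space for robustness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .viscosity import (
    DEFAULT_PROFILE_GRID,
    PiecewisePowerLaw,
    ShearRateGrid,
    ViscosityModel,
    as_piecewise,
)

__all__ = [
    "ChannelGeometry",
    "DrivingCondition",
    "FlowSolution",
    "ProfileAverages",
    "GridExhaustedError",
    "SignConventionError",
    "interval_radii",
    "solve_pressure_driven",
    "solve_flow_driven",
    "solve",
    "PROFILE_CSV_COLUMNS",
]

PROFILE_CSV_COLUMNS = (
    "r_m",
    "u_m_per_s",
    "shear_rate_per_s",
    "viscosity_Pa_s",
    "shear_stress_Pa",
)


class SignConventionError(ValueError):
    """Raised when a driving pressure gradient has the wrong sign.

    The solver uses the convention G = (p_0 - p_L)/L < 0 for flow in the
    +z direction; a positive G would make (-G r / 2K_i) negative in the
    shear-rate solution.
    """


class GridExhaustedError(RuntimeError):
    """The wall shear rate exceeds the interpolation grid maximum.

    Attributes hold the grid maximum and the (approximate) wall shear rate
    the driving condition requires, so callers can re-interpolate on a wider
    grid (see ``auto_extend``).
    """

    def __init__(self, gammadot_max: float, wall_shear_rate: float):
        self.gammadot_max = gammadot_max
        self.wall_shear_rate = wall_shear_rate
        super().__init__(
            f"wall shear rate ~{wall_shear_rate:.4g} 1/s exceeds the interpolation "
            f"grid maximum {gammadot_max:.4g} 1/s; re-interpolate with a larger "
            f"gammadot_max (or pass auto_extend=True)"
        )


@dataclass(frozen=True)
class ChannelGeometry:
    """Cylindrical nozzle: radius ``A`` and length ``L``, both in metres."""

    radius: float
    length: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("channel radius must be positive")
        if not self.length > 0:
            raise ValueError("channel length must be positive")


@dataclass(frozen=True)
class DrivingCondition:
    """Exactly one of: pressure gradient G (Pa/m, G < 0 drives +z flow),
    pressure drop dp = p_0 - p_L (Pa, negative), or flow rate Q (m^3/s)."""

    pressure_gradient: Optional[float] = None
    pressure_drop: Optional[float] = None
    flow_rate: Optional[float] = None

    def __post_init__(self) -> None:
        given = [
            v
            for v in (self.pressure_gradient, self.pressure_drop, self.flow_rate)
            if v is not None
        ]
        if len(given) != 1:
            raise ValueError(
                "exactly one of pressure_gradient, pressure_drop, flow_rate required"
            )

    @classmethod
    def from_pressure_gradient(cls, G: float) -> "DrivingCondition":
        return cls(pressure_gradient=G)

    @classmethod
    def from_pressure_drop(cls, dp: float) -> "DrivingCondition":
        return cls(pressure_drop=dp)

    @classmethod
    def from_applied_pressure(cls, p: float) -> "DrivingCondition":
        """Positive applied pressure magnitude (p_0 - p_L = -p)."""
        if p < 0:
            raise ValueError("applied pressure magnitude must be non-negative")
        return cls(pressure_drop=-p)

    @classmethod
    def from_flow_rate(cls, Q: float) -> "DrivingCondition":
        return cls(flow_rate=Q)

    def gradient(self, geometry: ChannelGeometry) -> Optional[float]:
        """The pressure gradient, or None if flow-rate driven."""
        if self.pressure_gradient is not None:
            return self.pressure_gradient
        if self.pressure_drop is not None:
            return self.pressure_drop / geometry.length
        return None


@dataclass(frozen=True)
class ProfileAverages:
    """Cross-sectional (area-weighted) averages and the peak velocity."""

    u_avg: float
    gammadot_avg: float
    eta_avg: float
    sigma_avg: float
    u_max: float

    def as_dict(self) -> dict:
        return {
            "u_avg_m_per_s": self.u_avg,
            "gammadot_avg_per_s": self.gammadot_avg,
            "eta_avg_Pa_s": self.eta_avg,
            "sigma_avg_Pa": self.sigma_avg,
            "u_max_m_per_s": self.u_max,
        }


def interval_radii(pw: PiecewisePowerLaw, G: float) -> np.ndarray:
    """Radii R_j (j = 0..N) at which the shear rate equals grid node Gamma_j.

    R_j = 2 K_j Gamma_j**n_j / (-G), using the segment below node j (by
    continuity the segment above gives the same radius).  R_0 uses segment 0.
    Strictly increasing because the stress -G r/2 is monotone in r.
    """
    if not G < 0:
        raise SignConventionError("pressure gradient G must be negative (flow in +z)")
    ln_negG = math.log(-G)
    log_bounds = np.log(pw.bounds)
    # node j >= 1 -> segment j-1; node 0 -> segment 0
    seg = np.concatenate(([0], np.arange(pw.n_intervals)))
    lnR = (
        math.log(2.0)
        + pw.log_K[seg]
        + pw.n[seg] * log_bounds
        - ln_negG
    )
    return np.exp(lnR)


class FlowSolution:
    """Exact piecewise flow solution in a cylindrical nozzle.

    Carries the interpolant, geometry and pressure gradient, and exposes the
    radial profiles (velocity, shear rate, viscosity, shear stress), the
    flow rate, and the cross-sectional averages, all in closed form.

    Not constructed directly — use :func:`solve_pressure_driven`,
    :func:`solve_flow_driven` or :func:`solve`.
    """

    def __init__(
        self,
        pw: PiecewisePowerLaw,
        geometry: ChannelGeometry,
        G: float,
    ):
        if G > 0:
            raise SignConventionError(
                "pressure gradient G must be <= 0 (G < 0 drives flow in +z)"
            )
        self.pw = pw
        self.geometry = geometry
        self.G = float(G)
        A = geometry.radius
        if G == 0.0:
            # Quiescent fluid: all profiles vanish.
            self.wall_index = 0
            self.interval_radii = np.zeros(0)
            self.wall_shear_rate = 0.0
            self.wall_shear_stress = 0.0
            self._zero = True
            return
        self._zero = False
        if np.any(pw.n <= 0):
            raise ValueError(
                "piecewise stress K_i*gammadot**n_i is non-increasing in at least "
                "one interval (n_i <= 0): the stress balance cannot be inverted "
                "uniquely, so no laminar pipe-flow solution exists for this law"
            )
        self._ln_cs = math.log(-G / 2.0)  # log of stress/radius slope
        R_all = interval_radii(pw, G)
        if A > R_all[-1]:
            # Wall shear rate beyond the grid: estimate it from the last segment.
            ln_gd = (self._ln_cs + math.log(A) - pw.log_K[-1]) / pw.n[-1]
            gd_wall = math.exp(ln_gd) if ln_gd < 700.0 else math.inf
            raise GridExhaustedError(pw.bounds[-1], gd_wall)
        # wall shell k: smallest i with R_{i+1} >= A
        k = int(np.searchsorted(R_all[1:], A, side="left"))
        self.wall_index = k
        self._R_all = R_all
        #: interior shell radii R_1..R_k (those below the wall)
        self.interval_radii = R_all[1 : k + 1]
        n = pw.n[: k + 1]
        self._n = n
        self._log_K = pw.log_K[: k + 1]
        self._w = n / (n + 1.0)
        self.wall_shear_rate = float(self._gammadot_in(np.array([A]), np.array([k]))[0])
        self.wall_shear_stress = -G * A / 2.0
        # suffix sums of the shell-matching terms
        if k > 0:
            T = R_all[1 : k + 1] * pw.bounds[1 : k + 1] * np.diff(self._w)
            S = np.concatenate((np.cumsum(T[::-1])[::-1], [0.0]))
        else:
            S = np.zeros(1)
        #: per-shell velocity offset D_i = w_k * gd_w * A - S_i
        self._D = self._w[k] * self.wall_shear_rate * A - S
        # radial integration bounds per shell (shell 0 absorbs the core)
        lo = np.concatenate(([0.0], self.interval_radii))
        hi = np.concatenate((self.interval_radii, [A]))
        self._lo, self._hi = lo, hi

    # -- internals ---------------------------------------------------------

    def _shell_of(self, r: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.interval_radii, r, side="right")

    def _gammadot_in(self, r: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Shear rate at radii ``r`` using the power law of shell ``idx``."""
        out = np.zeros_like(r)
        pos = r > 0
        if np.any(pos):
            out[pos] = np.exp(
                (self._ln_cs + np.log(r[pos]) - self._log_K[idx[pos]]) / self._n[idx[pos]]
            )
        return out

    def _check_radius(self, r: np.ndarray) -> None:
        A = self.geometry.radius
        if np.any(r < 0) or np.any(r > A * (1 + 1e-12)):
            raise ValueError(f"radius outside the channel [0, {A:g}] m")

    def _u_interval(self, r: ArrayLikeFloat, i: int) -> float:
        """Velocity at ``r`` evaluated with shell ``i``'s closed form.

        Exposed for continuity verification; shells agree at shared bounds.
        """
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        idx = np.full(r_arr.shape, i, dtype=int)
        u = self._D[idx] - self._w[idx] * self._gammadot_in(r_arr, idx) * r_arr
        return float(u[0]) if np.ndim(r) == 0 else u

    # -- profiles ----------------------------------------------------------

    def shear_rate(self, r) -> Union[float, np.ndarray]:
        """Shear rate profile gammadot(r), 1/s."""
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        self._check_radius(r_arr)
        if self._zero:
            out = np.zeros_like(r_arr)
        else:
            out = self._gammadot_in(r_arr, self._shell_of(r_arr))
        return float(out[0]) if np.ndim(r) == 0 else out

    def velocity(self, r) -> Union[float, np.ndarray]:
        """Axial velocity profile u(r), m/s; u(A) = 0 (no slip)."""
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        self._check_radius(r_arr)
        if self._zero:
            out = np.zeros_like(r_arr)
        else:
            idx = self._shell_of(r_arr)
            out = self._D[idx] - self._w[idx] * self._gammadot_in(r_arr, idx) * r_arr
        return float(out[0]) if np.ndim(r) == 0 else out

    def stress(self, r) -> Union[float, np.ndarray]:
        """Shear stress sigma(r) = -G r / 2, Pa — independent of the material."""
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        self._check_radius(r_arr)
        out = -self.G * r_arr / 2.0
        return float(out[0]) if np.ndim(r) == 0 else out

    def viscosity(self, r) -> Union[float, np.ndarray]:
        """Local viscosity eta(gammadot(r)), Pa*s.

        At the centreline the shear rate vanishes; the reported value there is
        the shell-0 power law evaluated at the grid minimum (for plateaued
        laws this is the zero-shear viscosity to interpolation accuracy).
        """
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        self._check_radius(r_arr)
        if self._zero:
            out = np.full_like(r_arr, math.exp(
                self.pw.log_K[0] + (self.pw.n[0] - 1.0) * math.log(self.pw.bounds[0])
            ))
        else:
            idx = self._shell_of(r_arr)
            gd = self._gammadot_in(r_arr, idx)
            out = np.empty_like(r_arr)
            pos = gd > 0
            out[pos] = np.exp(
                self._log_K[idx[pos]] + (self._n[idx[pos]] - 1.0) * np.log(gd[pos])
            )
            out[~pos] = math.exp(
                self._log_K[0] + (self._n[0] - 1.0) * math.log(self.pw.bounds[0])
            )
        return float(out[0]) if np.ndim(r) == 0 else out

    # -- aggregates --------------------------------------------------------

    def flow_rate(self) -> float:
        """Volumetric flow rate Q = int_0^A 2 pi r u(r) dr, m^3/s.

        Evaluated via the shear-rate route Q = pi * int_0^A r^2 gammadot dr
        (integration by parts with no slip), closed form per shell.  The
        direct velocity-integral route is available as a self-check through
        :meth:`_flow_rate_velocity_route`.
        """
        if self._zero:
            return 0.0
        idx = np.arange(self.wall_index + 1)
        g_hi = self._gammadot_in(self._hi, idx)
        g_lo = self._gammadot_in(self._lo, idx)
        terms = self._n / (3.0 * self._n + 1.0) * (
            g_hi * self._hi**3 - g_lo * self._lo**3
        )
        return float(math.pi * np.sum(terms))

    def _flow_rate_velocity_route(self) -> float:
        """Q from the direct velocity integral (independent closed form)."""
        if self._zero:
            return 0.0
        idx = np.arange(self.wall_index + 1)
        g_hi = self._gammadot_in(self._hi, idx)
        g_lo = self._gammadot_in(self._lo, idx)
        n = self._n
        coeff = n * n / ((n + 1.0) * (3.0 * n + 1.0))
        terms = (
            -coeff * (g_hi * self._hi**3 - g_lo * self._lo**3)
            + self._D * (self._hi**2 - self._lo**2) / 2.0
        )
        return float(2.0 * math.pi * np.sum(terms))

    def max_velocity(self) -> float:
        """Centreline velocity u(0), the profile maximum."""
        return float(self.velocity(0.0))

    def averages(self) -> ProfileAverages:
        """Area-weighted cross-sectional averages (2/A^2) int_0^A f(r) r dr."""
        A = self.geometry.radius
        if self._zero:
            eta0 = float(self.viscosity(0.0))
            return ProfileAverages(0.0, 0.0, eta0, 0.0, 0.0)
        Q = self.flow_rate()
        u_avg = Q / (math.pi * A * A)
        idx = np.arange(self.wall_index + 1)
        g_hi = self._gammadot_in(self._hi, idx)
        g_lo = self._gammadot_in(self._lo, idx)
        gd_terms = self._n / (2.0 * self._n + 1.0) * (
            g_hi * self._hi**2 - g_lo * self._lo**2
        )
        gammadot_avg = 2.0 / (A * A) * float(np.sum(gd_terms))
        # int eta r dr per shell: [eta(r) r^2] / (3 - 1/n), with a log form
        # at the removable exponent n = 1/3.
        cs = -self.G / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            eta_hi = np.where(g_hi > 0, cs * self._hi / np.where(g_hi > 0, g_hi, 1.0), 0.0)
            eta_lo = np.where(g_lo > 0, cs * self._lo / np.where(g_lo > 0, g_lo, 1.0), 0.0)
        denom = 3.0 - 1.0 / self._n
        eta_terms = np.empty_like(denom)
        regular = np.abs(denom) > 1e-12
        eta_terms[regular] = (
            eta_hi[regular] * self._hi[regular] ** 2
            - eta_lo[regular] * self._lo[regular] ** 2
        ) / denom[regular]
        if np.any(~regular):
            # n = 1/3 exactly: int r^{-1} dr -> log(hi/lo); diverges if lo = 0.
            for i in np.nonzero(~regular)[0]:
                c_ratio = cs / math.exp((self._ln_cs - self._log_K[i]) / self._n[i])
                if self._lo[i] == 0.0:
                    eta_terms[i] = math.inf
                else:
                    eta_terms[i] = c_ratio * math.log(self._hi[i] / self._lo[i])
        # shell 0 lower limit r=0: exponent 3 - 1/n < 0 diverges for n < 1/3
        if self._n[0] < 1.0 / 3.0 and self._lo[0] == 0.0:
            eta_terms[0] = math.inf
        eta_avg = 2.0 / (A * A) * float(np.sum(eta_terms))
        sigma_avg = -self.G * A / 3.0
        return ProfileAverages(
            u_avg=u_avg,
            gammadot_avg=gammadot_avg,
            eta_avg=eta_avg,
            sigma_avg=sigma_avg,
            u_max=self.max_velocity(),
        )

    # -- output ------------------------------------------------------------

    def sample_profile(self, n_points: int = 200) -> pd.DataFrame:
        """Profile table at ``n_points`` uniform radii plus every shell bound.

        Including the interior radii R_i < A guarantees plots show the exact
        kink locations of the piecewise solution.
        """
        if n_points < 2:
            raise ValueError("n_points must be at least 2")
        A = self.geometry.radius
        r = np.linspace(0.0, A, int(n_points))
        if not self._zero:
            interior = self.interval_radii[self.interval_radii < A]
            r = np.unique(np.concatenate((r, interior)))
        return pd.DataFrame(
            {
                "r_m": r,
                "u_m_per_s": self.velocity(r),
                "shear_rate_per_s": self.shear_rate(r),
                "viscosity_Pa_s": self.viscosity(r),
                "shear_stress_Pa": self.stress(r),
            }
        )

    def write_profile_csv(self, path: Union[str, Path], n_points: int = 200) -> None:
        """Write the sampled profile with a metadata comment line."""
        df = self.sample_profile(n_points)
        with open(path, "w") as fh:
            fh.write(
                f"# G_Pa_per_m={self.G:.17g} A_m={self.geometry.radius:.17g} "
                f"N={self.pw.n_intervals}\n"
            )
            df.to_csv(fh, index=False, float_format="%.17g")

    def summary(self) -> dict:
        """Headline scalars of the solution (SI units)."""
        av = self.averages()
        return {
            "G_Pa_per_m": self.G,
            "radius_m": self.geometry.radius,
            "length_m": self.geometry.length,
            "n_intervals": self.pw.n_intervals,
            "flow_rate_m3_per_s": self.flow_rate(),
            "wall_shear_rate_per_s": self.wall_shear_rate,
            "wall_shear_stress_Pa": self.wall_shear_stress,
            **av.as_dict(),
        }


ArrayLikeFloat = Union[float, np.ndarray]


def solve_pressure_driven(
    model: Union[ViscosityModel, PiecewisePowerLaw],
    geometry: ChannelGeometry,
    G: float,
    grid: ShearRateGrid = DEFAULT_PROFILE_GRID,
    auto_extend: bool = False,
) -> FlowSolution:
    """Solve the nozzle flow for a given pressure gradient ``G`` (Pa/m).

    ``G`` must be negative (G = 0 returns the quiescent solution).  If the
    wall shear rate exceeds the grid and ``auto_extend`` is true, the model
    is re-interpolated with a 10x larger ``gammadot_max`` (up to 4 times)
    rather than extrapolating a segment silently.
    """
    if G > 0:
        raise SignConventionError(
            "pressure gradient G must be <= 0 (G < 0 drives flow in +z); "
            "pass the negated magnitude"
        )
    pw = as_piecewise(model, grid)
    for attempt in range(5):
        try:
            return FlowSolution(pw, geometry, G)
        except GridExhaustedError:
            if not auto_extend or isinstance(model, PiecewisePowerLaw) or attempt == 4:
                raise
            grid = grid.with_max(grid.gammadot_max * 10.0)
            pw = as_piecewise(model, grid)
    raise AssertionError("unreachable")


def solve_flow_driven(
    model: Union[ViscosityModel, PiecewisePowerLaw],
    geometry: ChannelGeometry,
    Q_target: float,
    grid: ShearRateGrid = DEFAULT_PROFILE_GRID,
    rtol: float = 1e-8,
    max_expansions: int = 60,
    auto_extend: bool = False,
) -> FlowSolution:
    """Find the pressure gradient producing flow rate ``Q_target`` (m^3/s).

    Exploits strict monotonicity of Q(|G|): bracket by geometric expansion
    from a Newtonian initial guess, then refine with Brent's method on
    log|G| until ``|Q - Q_target| <= rtol * Q_target``.
    """
    if Q_target < 0:
        raise ValueError("flow rate must be non-negative")
    pw = as_piecewise(model, grid)
    if Q_target == 0.0:
        return FlowSolution(pw, geometry, 0.0)
    A = geometry.radius

    def Q_of(lnG: float) -> float:
        return solve_pressure_driven(
            model if auto_extend else pw,
            geometry,
            -math.exp(lnG),
            grid=grid,
            auto_extend=auto_extend,
        ).flow_rate()

    last_exhausted: list[GridExhaustedError] = []

    def f(lnG: float) -> float:
        # Q is strictly increasing in |G|; a gradient that pushes the wall
        # shear rate off the grid is therefore "above target" for bracketing.
        try:
            return Q_of(lnG) - Q_target
        except GridExhaustedError as err:
            last_exhausted.append(err)
            return math.inf

    # Newtonian guess at the zero-shear end of the grid (overestimates the
    # viscosity of a shear-thinning fluid, so Q(x0) >= Q_target typically).
    eta_low = pw.viscosity(pw.bounds[0])
    x0 = math.log(8.0 * eta_low * Q_target / (math.pi * A**4))
    step = math.log(10.0)
    x_lo = x_hi = x0
    f_lo = f_hi = f(x0)
    n_exp = 0
    while f_lo > 0:  # shrink |G| until Q below target
        x_hi, f_hi = x_lo, f_lo
        x_lo -= step
        f_lo = f(x_lo)
        n_exp += 1
        if n_exp > max_expansions:
            raise RuntimeError(
                f"could not bracket the pressure gradient: Q still above target at "
                f"|G|=exp({x_lo:.3g}) Pa/m"
            )
    while f_hi < 0:  # grow |G| until Q above target
        x_lo, f_lo = x_hi, f_hi
        x_hi += step
        f_hi = f(x_hi)
        n_exp += 1
        if n_exp > max_expansions:
            raise RuntimeError(
                f"could not bracket the pressure gradient: Q still below target at "
                f"|G|=exp({x_hi:.3g}) Pa/m"
            )
    # Pull the top of the bracket back onto the grid if it landed beyond it.
    while math.isinf(f_hi):
        if x_hi - x_lo < 1e-12:
            raise last_exhausted[-1]
        x_mid = 0.5 * (x_lo + x_hi)
        f_mid = f(x_mid)
        if f_mid >= 0:
            x_hi, f_hi = x_mid, f_mid
        else:
            x_lo, f_lo = x_mid, f_mid
    if x_lo == x_hi or f_hi == 0.0:
        x_root = x_hi
    elif f_lo == 0.0:
        x_root = x_lo
    else:
        x_root = brentq(f, x_lo, x_hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    sol = solve_pressure_driven(
        model if auto_extend else pw, geometry, -math.exp(x_root),
        grid=grid, auto_extend=auto_extend,
    )
    Q = sol.flow_rate()
    if abs(Q - Q_target) > rtol * Q_target:
        raise RuntimeError(
            f"flow-rate solve did not converge: |Q - Q_target|/Q_target = "
            f"{abs(Q - Q_target) / Q_target:.3e} > {rtol:g} "
            f"(bracket lnG in [{x_lo:.6g}, {x_hi:.6g}])"
        )
    return sol


def solve(
    model: Union[ViscosityModel, PiecewisePowerLaw],
    geometry: ChannelGeometry,
    driving: DrivingCondition,
    grid: ShearRateGrid = DEFAULT_PROFILE_GRID,
    auto_extend: bool = False,
) -> FlowSolution:
    """Dispatch on the driving condition (pressure- or flow-rate-driven)."""
    G = driving.gradient(geometry)
    if G is not None:
        return solve_pressure_driven(model, geometry, G, grid=grid, auto_extend=auto_extend)
    return solve_flow_driven(
        model, geometry, driving.flow_rate, grid=grid, auto_extend=auto_extend
    )
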