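"""Independent reference solutions used to validate the piecewise solver.

Two routes are provided:

* :func:`simplified_cy_profile` — the exact global solution for the
  two-parameter law ``eta = eta_0/(1 + K*gammadot)``.  Its shear stress
  ``sigma = eta_0*gammadot/(1 + K*gammadot)`` saturates at ``eta_0/K``, so
  the stress relation inverts in closed form, and the velocity follows from
  an elementary (logarithmic) antiderivative.  The antiderivative used here
  is re-derived below and unit-tested against numeric quadrature before it
  is relied upon as truth.

* :func:`numeric_profile` / :func:`numeric_flow_rate` — a brute-force
  reference valid for any supported law: at each radius the scalar stress
  balance ``eta(gammadot)*gammadot = -G r/2`` is solved by bracketed root
  finding (the left side is strictly increasing for the supported models),
  and the velocity follows by high-order quadrature of the shear rate from
  ``r`` to the wall.

Neither route touches the piecewise machinery, so agreement between solver
and oracle is a genuine cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .solver import ChannelGeometry
from .viscosity import Newtonian, ViscosityModel

__all__ = [
    "OracleProfile",
    "ValidityError",
    "simplified_cy_profile",
    "numeric_profile",
    "numeric_flow_rate",
    "gammadot_from_stress",
]


class ValidityError(ValueError):
    """Driving condition outside a model's admissible stress range."""


@dataclass(frozen=True)
class OracleProfile:
    """Reference radial profile: u(A) = 0, non-negative shear rates."""

    radii: np.ndarray
    velocities: np.ndarray
    shear_rates: np.ndarray
    method: str  # "closed-form" | "numeric"


def _simplified_cy_velocity(
    eta_0: float, K: float, A: float, G: float, r: np.ndarray
) -> np.ndarray:
    """Exact velocity for eta = eta_0/(1+K*gammadot).

    With s(r) = c*r (c = -G/2) the stress balance inverts to
    gammadot(r) = c*r / (eta_0 - b*r), b = K*c.  Integrating from r to the
    wall (no slip):

        u(r) = (c/b) * [ (eta_0/b) * ln((eta_0 - b*r)/(eta_0 - b*A)) - (A - r) ]

    valid while eta_0 - b*A > 0, i.e. wall stress below eta_0/K.  Verified by
    differentiation (du/dr = -gammadot) and against quadrature in the tests.
    """
    c = -G / 2.0
    if K == 0.0:
        return c * (A * A - r * r) / (2.0 * eta_0)  # Newtonian limit
    b = K * c
    return (c / b) * ((eta_0 / b) * np.log((eta_0 - b * r) / (eta_0 - b * A)) - (A - r))


def simplified_cy_profile(
    eta_0: float,
    K: float,
    geometry: ChannelGeometry,
    G: float,
    n_points: int = 1001,
) -> OracleProfile:
    """Closed-form profile for the simplified two-parameter CY fluid.

    Raises
    ------
    ValidityError
        If the wall stress ``-G*A/2`` reaches the model's saturation stress
        ``eta_0/K`` — beyond it no finite shear rate balances the stress.
    """
    if not G < 0:
        raise ValueError("pressure gradient G must be negative")
    A = geometry.radius
    s_wall = -G * A / 2.0
    if K > 0 and s_wall >= eta_0 / K:
        raise ValidityError(
            f"wall stress {s_wall:.4g} Pa >= stress bound eta_0/K = {eta_0 / K:.4g} Pa: "
            f"the simplified Carreau-Yasuda stress saturates and the flow problem "
            f"has no bounded solution at this pressure gradient"
        )
    r = np.linspace(0.0, A, int(n_points))
    s = -G * r / 2.0
    gammadot = s / (eta_0 - K * s)
    u = _simplified_cy_velocity(eta_0, K, A, G, r)
    return OracleProfile(r, u, gammadot, "closed-form")


def gammadot_from_stress(
    model: ViscosityModel,
    stress: float,
    bracket_max: float = 1e8,
    rtol: float = 1e-13,
) -> float:
    """Invert the stress balance eta(gd)*gd = stress by bracketed root finding.

    The bracket is expanded geometrically from ``bracket_max`` up to 1e12 1/s.
    """
    if stress < 0:
        raise ValueError("stress must be non-negative")
    if stress == 0.0:
        return 0.0
    if isinstance(model, Newtonian):
        return stress / model.eta

    def f(gd: float) -> float:
        # sigma(gd) = eta(gd)*gd, with the physical limit sigma(0) = 0 (for a
        # power law eta diverges at rest but the stress K*gd**n still vanishes).
        if gd == 0.0:
            return -stress
        return model.viscosity(gd) * gd - stress

    hi = bracket_max
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            raise RuntimeError(
                f"stress {stress:.4g} Pa not reachable below 1e12 1/s for {model!r}"
            )
    return brentq(f, 0.0, hi, xtol=1e-300, rtol=max(rtol, 8.9e-16), maxiter=300)


def numeric_profile(
    model: ViscosityModel,
    geometry: ChannelGeometry,
    G: float,
    n_grid: int = 2001,
) -> OracleProfile:
    """Brute-force profile: pointwise stress inversion + spline quadrature.

    The shear rate is solved independently at each of ``n_grid`` uniform
    radii; the velocity is the antiderivative of a cubic spline through
    those values, evaluated from each radius to the wall.
    """
    if n_grid < 100:
        raise ValueError("n_grid must be at least 100")
    if G > 0:
        raise ValueError("pressure gradient G must be <= 0")
    A = geometry.radius
    r = np.linspace(0.0, A, int(n_grid))
    if G == 0.0:
        z = np.zeros_like(r)
        return OracleProfile(r, z.copy(), z.copy(), "numeric")
    gd = np.array([gammadot_from_stress(model, -G * ri / 2.0) for ri in r])
    anti = CubicSpline(r, gd).antiderivative()
    u = float(anti(A)) - anti(r)
    return OracleProfile(r, u, gd, "numeric")


def numeric_flow_rate(
    model: ViscosityModel,
    geometry: ChannelGeometry,
    G: float,
    epsrel: float = 1e-10,
) -> float:
    """Flow rate by adaptive quadrature of the stress integral.

    Substituting s = -G r/2 into Q = pi * int_0^A r^2 gammadot(r) dr gives
    Q = (pi/c^3) * int_0^{cA} gammadot(s) s^2 ds with c = -G/2, where
    gammadot(s) comes from the pointwise stress inversion.  Fully
    independent of the piecewise machinery.
    """
    if G > 0:
        raise ValueError("pressure gradient G must be <= 0")
    if G == 0.0:
        return 0.0
    c = -G / 2.0
    s_wall = c * geometry.radius

    def integrand(s: float) -> float:
        return gammadot_from_stress(model, s) * s * s

    val, _ = quad(integrand, 0.0, s_wall, epsrel=epsrel, epsabs=0.0, limit=200)
    return math.pi * val / c**3
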