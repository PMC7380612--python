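"""Capillary rheometry: fit Carreau--Yasuda parameters from a flow curve.

A bioprinter plus a laboratory scale acts as a capillary rheometer: the ink
is extruded through a needle of known radius ``A`` and length ``L`` at a
series of driving pressures ``p_j``, and the flow rates ``Q_j`` are
measured.  Each pressure maps to a gradient ``G_j = -p_j/L`` (the pressure
drop along the wide cartridge is neglected), and the forward solver predicts
``Q(G_j)`` for any candidate three-parameter Carreau--Yasuda law

    eta(gammadot) = eta_0 * [1 + (gammadot/gammadot_c)**alpha]**(-1).

Fitting minimises the sum of squared flow-rate residuals with a
Levenberg--Marquardt least-squares method, parameterised in log space so
positivity of (eta_0, gammadot_c, alpha) is built in.

The module follows the familiar model/results pattern:

>>> model = CapillaryRheometry(measurement)
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .solver import ChannelGeometry, GridExhaustedError, solve_pressure_driven
from .viscosity import (
    DEFAULT_FIT_GRID,
    CarreauYasuda3,
    PiecewisePowerLaw,
    ShearRateGrid,
    ViscosityModel,
    as_piecewise,
)

__all__ = [
    "FlowCurveMeasurement",
    "CapillaryRheometry",
    "CapillaryFitResult",
    "predict_flow_curve",
    "fit_cy3",
    "FLOW_CURVE_CSV_COLUMNS",
]

FLOW_CURVE_CSV_COLUMNS = ("pressure_Pa", "flow_rate_m3_per_s")

_PARAM_NAMES = ("eta_0", "gammadot_c", "alpha")
_PARAM_UNITS = ("Pa s", "1/s", "-")


@dataclass(frozen=True)
class FlowCurveMeasurement:
    """Measured (pressure, flow rate) pairs for a needle of known geometry.

    Pressures are positive applied-pressure magnitudes in Pa, strictly
    increasing; flow rates in m^3/s, positive.
    """

    pressures: np.ndarray
    flow_rates: np.ndarray
    geometry: ChannelGeometry

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        q = np.asarray(self.flow_rates, dtype=float)
        if p.ndim != 1 or q.ndim != 1 or p.size != q.size:
            raise ValueError("pressures and flow rates must be 1-D and equal length")
        if p.size < 1:
            raise ValueError("need at least one measurement")
        if np.any(p <= 0):
            raise ValueError("pressures must be positive")
        if np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be strictly increasing")
        if np.any(q <= 0):
            raise ValueError("flow rates must be positive")
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "flow_rates", q)

    def __len__(self) -> int:
        return self.pressures.size

    @classmethod
    def from_csv(
        cls, path: Union[str, Path], geometry: ChannelGeometry
    ) -> "FlowCurveMeasurement":
        """Read the two-column flow-curve CSV dialect (``#`` = comment)."""
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        if tuple(df.columns) != FLOW_CURVE_CSV_COLUMNS:
            raise ValueError(
                f"flow-curve CSV {path}: line 1: expected header "
                f"{','.join(FLOW_CURVE_CSV_COLUMNS)!r}, got {','.join(df.columns)!r}"
            )
        return cls(
            df[FLOW_CURVE_CSV_COLUMNS[0]].to_numpy(),
            df[FLOW_CURVE_CSV_COLUMNS[1]].to_numpy(),
            geometry,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, geometry: ChannelGeometry
    ) -> "FlowCurveMeasurement":
        return cls(
            df[FLOW_CURVE_CSV_COLUMNS[0]].to_numpy(),
            df[FLOW_CURVE_CSV_COLUMNS[1]].to_numpy(),
            geometry,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {
                FLOW_CURVE_CSV_COLUMNS[0]: self.pressures,
                FLOW_CURVE_CSV_COLUMNS[1]: self.flow_rates,
            }
        ).to_csv(path, index=False, float_format="%.17g")


def predict_flow_curve(
    params: Union[CarreauYasuda3, ViscosityModel, PiecewisePowerLaw],
    geometry: ChannelGeometry,
    pressures: Sequence[float],
    grid: ShearRateGrid = DEFAULT_FIT_GRID,
    auto_extend: bool = False,
) -> np.ndarray:
    """Predicted flow rates (m^3/s) at applied pressures (Pa, magnitudes).

    Each pressure p maps to the gradient G = -p/L across the needle.  The
    interpolation is done once and reused across pressures.
    """
    p = np.asarray(pressures, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressures must be non-negative")
    pw = as_piecewise(params, grid) if not auto_extend else None
    out = np.empty_like(p)
    for j, pj in enumerate(p):
        if pj == 0.0:
            out[j] = 0.0
            continue
        try:
            sol = solve_pressure_driven(
                pw if pw is not None else params,
                geometry,
                -pj / geometry.length,
                grid=grid,
                auto_extend=auto_extend,
            )
        except GridExhaustedError as err:
            err.args = (f"{err.args[0]} (at pressure {pj:g} Pa)",)
            raise
        out[j] = sol.flow_rate()
    return out


class CapillaryRheometry:
    """Model object: three-parameter Carreau--Yasuda fit to a flow curve.

    Parameters
    ----------
    data : FlowCurveMeasurement
        At least 3 points are required to identify the 3 parameters.
    grid : ShearRateGrid, optional
        Interpolation grid used by the forward solver during fitting
        (default: 150 log-spaced intervals over 1e-6..1e8 1/s).
    relative_residuals : bool, optional
        If true, minimise relative instead of absolute flow-rate residuals.
        Off by default: the objective is the plain squared difference
        between measured and computed flow rates.
    """

    def __init__(
        self,
        data: FlowCurveMeasurement,
        grid: ShearRateGrid = DEFAULT_FIT_GRID,
        relative_residuals: bool = False,
    ):
        if len(data) < 3:
            raise ValueError(
                f"under-determined fit: {len(data)} data point(s) for 3 parameters; "
                f"need at least 3"
            )
        self.data = data
        self.grid = grid
        self.relative_residuals = relative_residuals

    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        radius: float,
        length: float,
        **kwargs,
    ) -> "CapillaryRheometry":
        geometry = ChannelGeometry(radius=radius, length=length)
        return cls(FlowCurveMeasurement.from_csv(path, geometry), **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, geometry: ChannelGeometry, **kwargs
    ) -> "CapillaryRheometry":
        return cls(FlowCurveMeasurement.from_dataframe(df, geometry), **kwargs)

    # -- prediction --------------------------------------------------------

    def predict(
        self,
        params: CarreauYasuda3,
        pressures: Optional[Sequence[float]] = None,
    ) -> np.ndarray:
        if pressures is None:
            pressures = self.data.pressures
        return predict_flow_curve(
            params, self.data.geometry, pressures, grid=self.grid, auto_extend=True
        )

    # -- initialisation ----------------------------------------------------

    def auto_initial_params(self) -> CarreauYasuda3:
        """Automatic starting point.

        eta_0 from the lowest-pressure point assuming Newtonian
        Hagen--Poiseuille; gammadot_c as the Newtonian wall shear rate at
        that point; alpha = 0.7 (typical for hydrogel inks).
        """
        p0 = self.data.pressures[0]
        Q0 = self.data.flow_rates[0]
        A = self.data.geometry.radius
        L = self.data.geometry.length
        eta_0 = math.pi * A**4 * p0 / (8.0 * L * Q0)
        gammadot_c = 4.0 * Q0 / (math.pi * A**3)
        return CarreauYasuda3(eta_0=eta_0, gammadot_c=gammadot_c, alpha=0.7)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        start: Optional[CarreauYasuda3] = None,
        xtol: float = 1e-12,
        ftol: float = 1e-12,
        gtol: float = 1e-12,
        max_nfev: Optional[int] = None,
    ) -> "CapillaryFitResult":
        """Levenberg--Marquardt least squares in log-parameter space."""
        if start is None:
            start = self.auto_initial_params()
        theta0 = np.log(start.as_parameter_array())
        Q_meas = self.data.flow_rates
        cost_history: list[float] = []

        # Penalty for infeasible trial parameters (e.g. alpha >= 1 makes the
        # stress law non-monotone; extreme trials can push the wall shear rate
        # beyond any grid).  A large flat residual makes LM reject the step.
        scale = np.ones_like(Q_meas) if self.relative_residuals else Q_meas
        penalty = 1e6 * scale

        def residuals(theta: np.ndarray) -> np.ndarray:
            params = CarreauYasuda3(*np.exp(theta))
            try:
                Q_pred = self.predict(params)
            except (GridExhaustedError, ValueError, RuntimeError):
                cost_history.append(float(np.dot(penalty, penalty)))
                return penalty
            res = Q_pred - Q_meas
            if self.relative_residuals:
                res = res / Q_meas
            cost_history.append(float(np.dot(res, res)))
            return res

        ls = least_squares(
            residuals,
            theta0,
            method="lm",
            xtol=xtol,
            ftol=ftol,
            gtol=gtol,
            max_nfev=max_nfev,
        )
        theta = ls.x
        params = CarreauYasuda3(*np.exp(theta))
        res = ls.fun
        rss = float(np.dot(res, res))
        m = len(self.data)
        dof = m - 3
        # Covariance of the log parameters from the Gauss-Newton Hessian.
        JtJ = ls.jac.T @ ls.jac
        try:
            cov_log = np.linalg.inv(JtJ) * (rss / dof if dof > 0 else np.nan)
            se_log = np.sqrt(np.diag(cov_log))
        except np.linalg.LinAlgError:
            cov_log = np.full((3, 3), np.inf)
            se_log = np.full(3, np.inf)
        fitted = self.predict(params)
        return CapillaryFitResult(
            model=self,
            params=params,
            rss=rss,
            residuals=fitted - Q_meas,
            fitted_values=fitted,
            converged=bool(ls.success),
            n_func_evals=int(ls.nfev),
            cost_history=np.asarray(cost_history),
            se_log=se_log,
            cov_log=cov_log,
            optimizer_status=ls.status,
            optimizer_message=ls.message,
        )


@dataclass
class CapillaryFitResult:
    """Fitted three-parameter Carreau--Yasuda law with diagnostics.

    ``se_log`` are standard errors of the *log* parameters, i.e. approximate
    relative standard errors of the parameters themselves; large values
    (>> 0.1) indicate a weakly identified parameter (e.g. gammadot_c and
    alpha for a nearly Newtonian flow curve).
    """

    model: CapillaryRheometry
    params: CarreauYasuda3
    rss: float
    residuals: np.ndarray
    fitted_values: np.ndarray
    converged: bool
    n_func_evals: int
    cost_history: np.ndarray
    se_log: np.ndarray
    cov_log: np.ndarray
    optimizer_status: int
    optimizer_message: str

    # convenient parameter accessors
    @property
    def eta_0(self) -> float:
        return self.params.eta_0

    @property
    def gammadot_c(self) -> float:
        return self.params.gammadot_c

    @property
    def alpha(self) -> float:
        return self.params.alpha

    def predict(self, pressures: Optional[Sequence[float]] = None) -> np.ndarray:
        return self.model.predict(self.params, pressures)

    def summary(self) -> str:
        g = self.model.grid
        geo = self.model.data.geometry
        lines = [
            "Capillary rheometry fit (3-parameter Carreau-Yasuda)",
            "=" * 56,
            f"{'needle radius':<22}{geo.radius:.6g} m",
            f"{'needle length':<22}{geo.length:.6g} m",
            f"{'data points':<22}{len(self.model.data)}",
            f"{'grid':<22}{g.n_intervals} intervals, "
            f"{g.gammadot_min:g}..{g.gammadot_max:g} 1/s",
            "-" * 56,
            f"{'parameter':<14}{'estimate':>14}{'rel. std err':>14}  unit",
        ]
        values = self.params.as_parameter_array()
        for name, unit, val, se in zip(_PARAM_NAMES, _PARAM_UNITS, values, self.se_log):
            lines.append(f"{name:<14}{val:>14.6g}{se:>14.3g}  {unit}")
        lines += [
            "-" * 56,
            f"{'RSS':<22}{self.rss:.6g} "
            + ("(relative)" if self.model.relative_residuals else "(m^3/s)^2"),
            f"{'converged':<22}{self.converged}",
            f"{'function evals':<22}{self.n_func_evals}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        g = self.model.grid
        geo = self.model.data.geometry
        return {
            "parameters": {
                "eta_0_Pa_s": self.eta_0,
                "gammadot_c_per_s": self.gammadot_c,
                "alpha": self.alpha,
            },
            "relative_standard_errors": {
                name: float(se) for name, se in zip(_PARAM_NAMES, self.se_log)
            },
            "rss_m6_per_s2": self.rss,
            "residuals_m3_per_s": [float(x) for x in self.residuals],
            "converged": self.converged,
            "n_func_evals": self.n_func_evals,
            "optimizer_status": int(self.optimizer_status),
            "optimizer_message": self.optimizer_message,
            "grid": {
                "gammadot_min_per_s": g.gammadot_min,
                "gammadot_max_per_s": g.gammadot_max,
                "n_intervals": g.n_intervals,
            },
            "geometry": {"radius_m": geo.radius, "length_m": geo.length},
        }

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_cy3(
    data: FlowCurveMeasurement,
    init: Optional[CarreauYasuda3] = None,
    grid: ShearRateGrid = DEFAULT_FIT_GRID,
    relative_residuals: bool = False,
    **fit_options,
) -> CapillaryFitResult:
    """Functional wrapper: fit a CY3 law to a measured flow curve."""
    model = CapillaryRheometry(data, grid=grid, relative_residuals=relative_residuals)
    return model.fit(start=init, **fit_options)
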