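"""Parameter estimation by Nelder-Mead maximisation of summed R².

The objective is the sum, over every measured component, of the coefficient
of determination between the measured series and the simulated trajectory
evaluated at the measurement times (concentration scale, unweighted).  It is
not a likelihood; the "standard errors" derived from the inverse of the
finite-difference Hessian of the negated objective at the optimum are a
curvature-based uncertainty measure, reported the way practitioners commonly
do for this workflow, and the min/max prediction envelope samples parameters
from independent normals around the estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .design import ExperimentDesign
from .kinetics import COMPONENTS
from .parameters import ModelParameters, ParameterError, SIGN_FREE
from .rates import MeasurementSeries
from .simulate import SimulationError, SolverOptions, Trajectory, simulate

__all__ = ["FitResult", "PredictionEnvelope", "r_squared", "objective",
           "objective_components", "fit_nelder_mead", "standard_errors",
           "finite_difference_hessian", "curvature_standard_errors",
           "prediction_envelope"]

#: Objective value substituted when a simulation fails (we maximise).
FAILURE_PENALTY = -1.0e6


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def objective_components(
    params: ModelParameters,
    datasets: Mapping[str, MeasurementSeries],
    design: ExperimentDesign,
    solver: Optional[SolverOptions] = None,
) -> Tuple[Dict[str, float], Optional[Trajectory]]:
    """Per-component R² of the model against the datasets (None on failure)."""
    all_times = np.unique(np.concatenate(
        [s.retained()[0] for s in datasets.values()]))
    try:
        traj = simulate(params, design, options=solver, extra_times=all_times)
    except (SimulationError, ParameterError, ValueError, ArithmeticError):
        return {}, None
    r2 = {}
    for comp, series in datasets.items():
        t, v = series.retained()
        r2[comp] = r_squared(v, traj.at(comp, t))
    return r2, traj


def objective(params, datasets, design,
              solver: Optional[SolverOptions] = None) -> float:
    """Summed R² over measured components; large penalty on solver failure."""
    r2, traj = objective_components(params, datasets, design, solver)
    if traj is None:
        return FAILURE_PENALTY
    return float(sum(r2.values()))


@dataclass
class FitResult:
    """Outcome of one Nelder-Mead fit."""

    params: ModelParameters
    free: Tuple[str, ...]
    start: Dict[str, float]
    objective: float
    r2: Dict[str, float]
    n_iterations: int
    n_evaluations: int
    converged: bool
    message: str
    standard_errors: Optional[Dict[str, float]] = None
    se_flags: Dict[str, str] = field(default_factory=dict)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(list(self.r2.values())))

    def estimates(self) -> Dict[str, float]:
        return {name: self.params.get(name) for name in self.free}

    def to_dict(self) -> dict:
        return {
            "free": list(self.free),
            "start": self.start,
            "estimates": self.estimates(),
            "standard_errors": self.standard_errors,
            "se_flags": self.se_flags,
            "objective": self.objective,
            "r2": self.r2,
            "mean_r2": self.mean_r2,
            "n_iterations": self.n_iterations,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "message": self.message,
            "parameters": self.params.to_dict(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _transforms(start: ModelParameters, free: Sequence[str]):
    """Per-parameter (to_x, from_x) maps: log scale for positive parameters."""
    use_log = []
    for name in free:
        value = start.get(name)
        use_log.append(name not in SIGN_FREE and value > 0)
    def to_x(values):
        return np.array([math.log(v) if lg else v
                         for v, lg in zip(values, use_log)])
    def from_x(x):
        return [math.exp(xi) if lg else float(xi)
                for xi, lg in zip(x, use_log)]
    return to_x, from_x


def fit_nelder_mead(
    start: ModelParameters,
    free: Sequence[str],
    datasets: Mapping[str, MeasurementSeries],
    design: ExperimentDesign,
    solver: Optional[SolverOptions] = None,
    maxiter: int = 600,
    fatol: float = 1e-6,
    xatol: float = 1e-4,
) -> FitResult:
    """Maximise the summed R² over the ``free`` parameters.

    Positive-constrained parameters are optimised on a log scale (positivity
    enforced by construction); sign-free offsets stay on a linear scale.  The
    run is deterministic given the start point and options.
    """
    free = tuple(free)
    if not free:
        raise ValueError("free parameter list must be non-empty")
    start_values = {name: start.get(name) for name in free}
    if maxiter == 0:
        r2, _ = objective_components(start, datasets, design, solver)
        return FitResult(start, free, start_values,
                         float(sum(r2.values())) if r2 else FAILURE_PENALTY,
                         r2, 0, 0, False, "maxiter=0: start returned unchanged")

    to_x, from_x = _transforms(start, free)

    def build(x) -> Optional[ModelParameters]:
        try:
            return start.with_values(**dict(zip(free, from_x(x))))
        except ParameterError:
            return None

    def neg_obj(x) -> float:
        p = build(x)
        if p is None:
            return -FAILURE_PENALTY
        return -objective(p, datasets, design, solver)

    x0 = to_x([start_values[name] for name in free])
    res = minimize(neg_obj, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "fatol": fatol,
                            "xatol": xatol, "adaptive": len(free) > 3})
    best = build(res.x) or start
    r2, _ = objective_components(best, datasets, design, solver)
    return FitResult(
        params=best, free=free, start=start_values,
        objective=-float(res.fun), r2=r2,
        n_iterations=int(res.nit), n_evaluations=int(res.nfev),
        converged=bool(res.success), message=str(res.message),
    )


def finite_difference_hessian(f, theta: np.ndarray,
                              rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of a scalar function at ``theta``."""
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1e-300)
    f0 = f(theta)
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def curvature_standard_errors(f, theta: np.ndarray, rel_step: float = 1e-3):
    """SEs as sqrt of the inverse-Hessian diagonal of a minimised scalar ``f``.

    Returns ``(ses, flags)``; non-positive-definite or singular curvature
    yields NaN entries flagged per parameter instead of a silent repair.
    """
    H = finite_difference_hessian(f, theta, rel_step)
    n = H.shape[0]
    ses = np.full(n, np.nan)
    flags = [None] * n
    try:
        diag = np.diag(np.linalg.inv(H))
    except np.linalg.LinAlgError:
        return ses, ["singular_hessian"] * n
    for i, d in enumerate(diag):
        if d > 0 and np.isfinite(d):
            ses[i] = math.sqrt(d)
        else:
            flags[i] = "hessian_not_positive_definite"
    return ses, flags


def standard_errors(
    result: FitResult,
    datasets: Mapping[str, MeasurementSeries],
    design: ExperimentDesign,
    solver: Optional[SolverOptions] = None,
    rel_step: float = 1e-3,
) -> Dict[str, float]:
    """Curvature-based SEs from the inverse Hessian of the negated objective.

    The Hessian is built by central finite differences in the parameters'
    native scale at the fitted optimum.  If it is not positive definite the
    affected parameters are reported as NaN and flagged in
    ``result.se_flags`` rather than silently repaired.
    """
    free = result.free
    theta = np.array([result.params.get(name) for name in free])

    def f(vec) -> float:
        try:
            p = result.params.with_values(**dict(zip(free, vec)))
        except ParameterError:
            return -FAILURE_PENALTY
        return -objective(p, datasets, design, solver)

    ses_arr, flag_list = curvature_standard_errors(f, theta, rel_step)
    result.standard_errors = {name: float(se) for name, se in zip(free, ses_arr)}
    result.se_flags = {name: fl for name, fl in zip(free, flag_list) if fl}
    return result.standard_errors


@dataclass
class PredictionEnvelope:
    """Pointwise min/max band of trajectories sampled around the estimate."""

    t: np.ndarray
    lower: Dict[str, np.ndarray]
    upper: Dict[str, np.ndarray]
    point: Dict[str, np.ndarray]
    n_samples: int
    seed: int
    n_rejected: int = 0

    def width(self, component: str) -> np.ndarray:
        return self.upper[component] - self.lower[component]


def prediction_envelope(
    result: FitResult,
    design: ExperimentDesign,
    n_samples: int = 200,
    seed: int = 0,
    solver: Optional[SolverOptions] = None,
    grid_dt: float = 1.0,
    standard_errors: Optional[Mapping[str, float]] = None,
) -> PredictionEnvelope:
    """Min/max predicted profiles under normal parameter uncertainty.

    Each sample draws the free parameters independently from
    N(estimate, SE) (draws violating parameter invariants are redrawn, i.e.
    the normals are truncated at the feasible boundary), simulates the run,
    and the envelope is the pointwise min/max over all samples including the
    point-estimate trajectory.  Reproducible by ``seed``.
    """
    ses = dict(standard_errors) if standard_errors is not None else result.standard_errors
    if ses is None:
        raise ValueError("standard errors are required; compute them first")
    sampled = [(name, ses[name]) for name in result.free
               if name in ses and np.isfinite(ses[name])]
    rng = np.random.default_rng(seed)
    solver = solver or SolverOptions(rtol=1e-6, atol=1e-8, max_step=2.0,
                                     grid_dt=grid_dt)

    grid = np.arange(0.0, design.duration + 1e-9, grid_dt)
    point_traj = simulate(result.params, design, options=solver, extra_times=grid)
    comps = (*COMPONENTS, "V")
    point = {c: point_traj.at(c, grid) for c in comps}
    lower = {c: arr.copy() for c, arr in point.items()}
    upper = {c: arr.copy() for c, arr in point.items()}

    n_rejected = 0
    n_done = 0
    while n_done < n_samples:
        draw = {}
        ok = True
        for name, se in sampled:
            est = result.params.get(name)
            for _ in range(1000):
                v = rng.normal(est, se)
                try:
                    result.params.with_values(**{name: v})
                except ParameterError:
                    n_rejected += 1
                    continue
                draw[name] = v
                break
            else:
                ok = False
                break
        if not ok:
            raise RuntimeError(f"could not draw a feasible value for {name}")
        try:
            p = result.params.with_values(**draw)
            traj = simulate(p, design, options=solver, extra_times=grid)
        except (SimulationError, ParameterError):
            n_rejected += 1
            if n_rejected > 100 * max(n_samples, 1):
                raise RuntimeError("all parameter draws were infeasible")
            continue
        for c in comps:
            vals = traj.at(c, grid)
            np.minimum(lower[c], vals, out=lower[c])
            np.maximum(upper[c], vals, out=upper[c])
        n_done += 1

    return PredictionEnvelope(grid, lower, upper, point, n_samples, seed,
                              n_rejected)
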