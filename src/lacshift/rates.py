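"""Recover time-resolved specific rates from sparse offline measurements.

Daily measurements of viable cell density and component concentrations are
interpolated with the shape-preserving PCHIP scheme (monotone data give a
monotone interpolant, so the derivative never overshoots between samples) and
the fed-batch balances are inverted for the apparent per-cell rates:

    Q_lac(t)    =  d(V*LAC)/dt / (V*Xv)
    Q_gln(t)    = [Fin*cin_gln - d(V*GLN)/dt] / (V*Xv)
    Q_p(t)      =  d(V*P)/dt / (V*Xv)
    (mu-mu_d)(t) = d(V*Xv)/dt / (V*Xv)

The solution volume is reconstructed analytically from the design's feed
profile (fed-batch: dV/dt = Fin), so d(V*c)/dt = Fin*c + V*dc/dt with dc/dt
taken from the interpolant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .design import ExperimentDesign, feed_rate, volume_at
from .kinetics import COMPONENT_UNITS, COMPONENTS

__all__ = ["MeasurementSeries", "RateSeries", "interpolate_pchip",
           "estimate_specific_rates", "reestimate_excluding", "RATE_UNITS"]

RATE_UNITS = {
    "Q_lac": "mmol/cell/h",
    "Q_gln": "mmol/cell/h",
    "Q_p": "g/cell/h",
    "mu_app": "1/h",
}


@dataclass(frozen=True)
class MeasurementSeries:
    """Timestamped offline observations of one culture component."""

    component: str
    times: np.ndarray          # h
    values: np.ndarray
    unit: str = ""
    exclude: Optional[np.ndarray] = None  # bool mask of points to drop

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        mask = (np.zeros(t.size, dtype=bool) if self.exclude is None
                else np.asarray(self.exclude, dtype=bool))
        if mask.shape != t.shape:
            raise ValueError("exclude mask must match times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "exclude", mask)
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if not self.unit:
            object.__setattr__(self, "unit", COMPONENT_UNITS[self.component])

    def retained(self):
        """(times, values) with excluded points dropped (>= 2 required)."""
        keep = ~self.exclude
        if keep.sum() < 2:
            raise ValueError(
                f"{self.component}: need at least 2 unexcluded points")
        return self.times[keep], self.values[keep]

    def excluding(self, indices: Sequence[int]) -> "MeasurementSeries":
        mask = self.exclude.copy()
        mask[np.asarray(indices, dtype=int)] = True
        return replace(self, exclude=mask)

    @property
    def n_retained(self) -> int:
        return int((~self.exclude).sum())


@dataclass(frozen=True)
class RateSeries:
    """One estimated specific-rate profile with its provenance."""

    name: str
    times: np.ndarray
    values: np.ndarray
    unit: str
    provenance: dict = field(default_factory=dict)

    def at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)

    def zero_crossings(self):
        """Times where the rate changes sign (linear interpolation).

        Nodes that are exactly zero count once, not once per neighbour.
        """
        s = np.sign(self.values)
        idx = np.nonzero(np.diff(s) != 0)[0]
        out: list = []
        for i in idx:
            v0, v1 = self.values[i], self.values[i + 1]
            t0, t1 = self.times[i], self.times[i + 1]
            tc = t0 if v1 == v0 else t0 - v0 * (t1 - t0) / (v1 - v0)
            if not out or abs(tc - out[-1]) > 1e-9:
                out.append(float(tc))
        return out


def interpolate_pchip(series: MeasurementSeries) -> PchipInterpolator:
    """Shape-preserving cubic interpolant through the retained points."""
    t, v = series.retained()
    return PchipInterpolator(t, v, extrapolate=False)


def _default_grid(times: np.ndarray, dt: float) -> np.ndarray:
    # Trim half a sampling interval at each end: PCHIP end derivatives are
    # one-sided and noticeably less accurate there.
    pad = 0.5 * float(np.median(np.diff(times)))
    lo, hi = times[0] + pad, times[-1] - pad
    if hi <= lo:
        raise ValueError("measurement span too short for the evaluation grid")
    return np.arange(lo, hi + 1e-9, dt)


def estimate_specific_rates(
    measurements: Mapping[str, MeasurementSeries],
    design: ExperimentDesign,
    grid: Optional[np.ndarray] = None,
    grid_dt: float = 1.0,
) -> Dict[str, RateSeries]:
    """Invert the fed-batch balances for the apparent specific rates.

    Requires an ``"Xv"`` series; produces ``Q_lac``/``Q_gln``/``Q_p`` for
    whichever of ``LAC``/``GLN``/``P`` is measured, and the apparent growth
    rate ``mu_app`` (= mu - mu_d) from ``Xv`` itself.  The volume and feed
    rate are reconstructed from the design.
    """
    if "Xv" not in measurements:
        raise ValueError("an Xv measurement series is required")
    xv_series = measurements["Xv"]
    t_xv, _ = xv_series.retained()
    if grid is None:
        grid = _default_grid(t_xv, grid_dt)
    grid = np.asarray(grid, dtype=float)
    if grid[0] < t_xv[0] or grid[-1] > t_xv[-1]:
        raise ValueError("evaluation grid extends beyond the measured span")

    V = volume_at(design, grid)
    fin = np.array([feed_rate(design, t) for t in grid])
    xv_interp = interpolate_pchip(xv_series)
    xv = xv_interp(grid)
    vxv = V * xv
    if np.any(vxv <= 0):
        raise ValueError("V*Xv must stay positive on the evaluation grid")

    def _extensive_derivative(series: MeasurementSeries) -> np.ndarray:
        f = interpolate_pchip(series)
        c = f(grid)
        dc = f.derivative()(grid)
        if np.any(np.isnan(c)):
            raise ValueError(
                f"{series.component}: grid extends beyond this series' span")
        return fin * c + V * dc  # d(V c)/dt with dV/dt = Fin

    def _prov(series: MeasurementSeries) -> dict:
        return {
            "components": [series.component, "Xv"],
            "excluded": {series.component: np.nonzero(series.exclude)[0].tolist(),
                         "Xv": np.nonzero(xv_series.exclude)[0].tolist()},
        }

    out: Dict[str, RateSeries] = {}
    dxv = xv_interp.derivative()(grid)
    out["mu_app"] = RateSeries(
        "mu_app", grid, (fin * xv + V * dxv) / vxv, RATE_UNITS["mu_app"],
        _prov(xv_series))
    if "LAC" in measurements:
        out["Q_lac"] = RateSeries(
            "Q_lac", grid, _extensive_derivative(measurements["LAC"]) / vxv,
            RATE_UNITS["Q_lac"], _prov(measurements["LAC"]))
    if "GLN" in measurements:
        dvgln = _extensive_derivative(measurements["GLN"])
        out["Q_gln"] = RateSeries(
            "Q_gln", grid, (fin * design.cin_gln - dvgln) / vxv,
            RATE_UNITS["Q_gln"], _prov(measurements["GLN"]))
    if "P" in measurements:
        out["Q_p"] = RateSeries(
            "Q_p", grid, _extensive_derivative(measurements["P"]) / vxv,
            RATE_UNITS["Q_p"], _prov(measurements["P"]))
    return out


def reestimate_excluding(
    measurements: Mapping[str, MeasurementSeries],
    exclusions: Mapping[str, Sequence[int]],
    design: ExperimentDesign,
    grid: Optional[np.ndarray] = None,
    grid_dt: float = 1.0,
) -> Dict[str, RateSeries]:
    """Re-run the rate estimation with extra points excluded per component.

    Used to flag single-point artifacts (e.g. a spurious first-day lactate
    spike): compare the returned series against the full-data estimate.
    """
    updated = dict(measurements)
    for comp, idx in exclusions.items():
        updated[comp] = updated[comp].excluding(idx)
    return estimate_specific_rates(updated, design, grid=grid, grid_dt=grid_dt)
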