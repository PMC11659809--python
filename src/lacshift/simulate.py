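"""Forward integration of a cultivation run under an operating design.

The model's right-hand side is discontinuous at three kinds of points: feed
schedule boundaries (Fin steps), the DO setpoint shift (regime change), and
the sign change of the high-DO specific lactate rate (growth-branch switch,
which happens at an analytically known glutamine level).  The integrator
splits the run into segments at the known boundaries and uses terminal
``solve_ivp`` events for the state-dependent ones (DO-shift trigger and the
Q_lac sign change), restarting cleanly at each, so the adaptive solver never
steps across a discontinuity.

A deliberately independent fixed-step RK4 integrator with local step
refinement around switching points is provided as a cross-check
(:func:`simulate_rk4`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import kinetics
from .design import (ExperimentDesign, feed_breakpoints, feed_rate,
                     initial_state, regime_breakpoints, scheduled_regime)
from .kinetics import (COMPONENT_UNITS, COMPONENTS, HIGH, LOW, FlowSnapshot,
                       RegimeContext, STATE_NAMES, mass_balance_rhs,
                       qlac_zero_gln, specific_rates)
from .parameters import ModelParameters

__all__ = ["SolverOptions", "Trajectory", "SimulationError", "simulate",
           "simulate_rk4"]

RATE_NAMES = ("mu", "mu_d", "Q_lac", "Q_gln", "Q_p")


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive-solver settings (defaults favour accuracy over speed)."""

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = 0.5   # h; bounds the smear of any remaining kink
    method: str = "LSODA"
    grid_dt: Optional[float] = 0.1  # h; None = report only requested times


#: Loose, fast settings for inner-loop work (fitting, envelopes).
FAST = SolverOptions(rtol=1e-6, atol=1e-8, max_step=2.0, grid_dt=1.0)


class SimulationError(RuntimeError):
    """Integration failed; carries the last valid partial trajectory."""

    def __init__(self, message: str, partial: Optional["Trajectory"] = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class Trajectory:
    """Time-resolved result of one simulated run.

    ``states`` holds the extensive quantities (order ``STATE_NAMES``); the
    concentration view, per-cell rates and DO-regime label per time point are
    derived lazily.
    """

    t: np.ndarray                 # (n,), h
    states: np.ndarray            # (n, 10), extensive
    regimes: np.ndarray           # (n,), "high"/"low"
    params: ModelParameters
    design: ExperimentDesign
    events: dict = field(default_factory=dict)
    _conc: Optional[dict] = field(default=None, repr=False)
    _rates: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def volume(self) -> np.ndarray:
        return self.states[:, 9]

    def concentrations(self) -> dict:
        """Per-component concentration arrays (clipped at zero) plus V."""
        if self._conc is None:
            v = self.volume
            conc = {name: np.clip(self.states[:, i] / v, 0.0, None)
                    for i, name in enumerate(COMPONENTS)}
            conc["V"] = v
            self._conc = conc
        return self._conc

    def rates(self) -> dict:
        """Specific rates re-evaluated along the stored trajectory."""
        if self._rates is None:
            c = self.concentrations()
            out = {name: np.empty(self.t.size) for name in RATE_NAMES}
            for i in range(self.t.size):
                regime = (kinetics.HIGH_REGIME if self.regimes[i] == HIGH
                          else kinetics.LOW_REGIME)
                r = specific_rates(c["GLC"][i], c["GLN"][i], c["LAC"][i],
                                   c["AMM"][i], regime, self.params)
                out["mu"][i] = r.mu
                out["mu_d"][i] = r.mu_d
                out["Q_lac"][i] = r.Q_lac
                out["Q_gln"][i] = r.Q_gln
                out["Q_p"][i] = r.Q_p
            self._rates = out
        return self._rates

    def component(self, name: str) -> np.ndarray:
        return self.concentrations()[name]

    def at(self, name: str, times) -> np.ndarray:
        """Concentration of one component linearly interpolated at ``times``.

        Exact at stored grid points; ask for measurement times via the
        ``extra_times`` argument of :func:`simulate` to avoid interpolation
        error.
        """
        return np.interp(np.asarray(times, dtype=float), self.t,
                         self.component(name))

    def qlac_sign_change_times(self) -> List[float]:
        q = self.rates()["Q_lac"]
        idx = np.nonzero(np.diff(np.sign(q)) != 0)[0]
        out = []
        for i in idx:
            t0, t1, q0, q1 = self.t[i], self.t[i + 1], q[i], q[i + 1]
            out.append(t0 if q1 == q0 else t0 + (0.0 - q0) * (t1 - t0) / (q1 - q0))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Wide table: time, regime, concentrations, volume, specific rates."""
        data = {"time_h": self.t, "regime": self.regimes}
        data.update({name: arr for name, arr in self.concentrations().items()})
        data.update(self.rates())
        return pd.DataFrame(data)

    def to_tidy(self) -> pd.DataFrame:
        """Tidy export: time_h, variable, value, unit, regime."""
        rows = []
        conc = self.concentrations()
        for name in (*COMPONENTS, "V"):
            rows.append(pd.DataFrame({
                "time_h": self.t, "variable": name, "value": conc[name],
                "unit": COMPONENT_UNITS[name], "regime": self.regimes,
            }))
        return pd.concat(rows, ignore_index=True)


def _requested_times(design: ExperimentDesign, options: SolverOptions,
                     extra_times) -> np.ndarray:
    pts = [np.array([0.0, design.duration])]
    if options.grid_dt:
        pts.append(np.arange(0.0, design.duration, options.grid_dt))
    pts.append(feed_breakpoints(design))
    if extra_times is not None:
        pts.append(np.asarray(extra_times, dtype=float))
    times = np.unique(np.concatenate(pts))
    if times[0] < 0 or times[-1] > design.duration:
        raise ValueError("requested times must lie within [0, duration]")
    return times


def simulate(params: ModelParameters, design: ExperimentDesign,
             options: Optional[SolverOptions] = None,
             extra_times=None) -> Trajectory:
    """Integrate the model over ``[0, design.duration]``.

    Returns a :class:`Trajectory` sampled on the dense output grid
    (``options.grid_dt``) plus any ``extra_times`` requested (e.g. measurement
    times), with regime changes resolved by events.
    """
    if params.reactor_type != design.reactor_type:
        raise ValueError(
            f"parameter set is for a {params.reactor_type} tank but the design "
            f"is for a {design.reactor_type} tank"
        )
    options = options or SolverOptions()
    wanted = _requested_times(design, options, extra_times)

    regime_ctx = design.regime_thresholds
    high = RegimeContext(HIGH, regime_ctx.DO_high_threshold, regime_ctx.DO_low_threshold)
    low = RegimeContext(LOW, regime_ctx.DO_high_threshold, regime_ctx.DO_low_threshold)
    gln_root = qlac_zero_gln(params)

    schedule_mode = design.do_mode == "schedule"
    edges = np.unique(np.concatenate([
        [0.0, design.duration], feed_breakpoints(design),
        regime_breakpoints(design) if schedule_mode else (
            [design.do_check_time]
            if 0.0 < design.do_check_time < design.duration else []),
    ]))

    t_list: List[float] = [0.0]
    y_list: List[np.ndarray] = [initial_state(design)]
    regime_list: List[str] = []
    latched = False
    events_log: dict = {"do_shift_time": None, "qlac_event_times": []}
    y = initial_state(design)

    def _partial() -> Optional[Trajectory]:
        if len(t_list) < 2:
            return None
        return Trajectory(np.array(t_list), np.vstack(y_list),
                          np.array(regime_list + ["?"] * (len(t_list) - len(regime_list))),
                          params, design, events_log)

    if schedule_mode:
        latched = scheduled_regime(design, 0.0) == LOW
    elif 0.0 >= design.do_check_time and y[0] / y[9] >= design.do_trigger:
        latched = True
    regime_list.append(LOW if latched else HIGH)

    for a, b in zip(edges[:-1], edges[1:]):
        ta = a
        gln_restarts = 0
        while ta < b - 1e-12:
            if schedule_mode:
                was_low = latched
                latched = scheduled_regime(design, 0.5 * (ta + b)) == LOW
                if latched and not was_low:
                    events_log["do_shift_time"] = ta
                    regime_list[-1] = LOW
            elif not latched and ta >= design.do_check_time - 1e-12 \
                    and y[0] / y[9] >= design.do_trigger:
                latched = True
                if events_log["do_shift_time"] is None:
                    events_log["do_shift_time"] = ta
                regime_list[-1] = LOW  # boundary point belongs to the new regime
            regime = low if latched else high
            flows = FlowSnapshot(
                fin=feed_rate(design, 0.5 * (ta + b)),
                cin_glc=design.cin_glc, cin_gln=design.cin_gln,
            )

            events = []
            if (not schedule_mode and not latched
                    and ta >= design.do_check_time - 1e-12):
                def ev_shift(t, yv):
                    return yv[0] / yv[9] - design.do_trigger
                ev_shift.terminal = True
                ev_shift.direction = 1.0
                events.append(("shift", ev_shift))
            if not latched and gln_root is not None and gln_restarts < 50:
                # Only the downward crossing switches the growth branch in
                # practice; hovering at the root is handled by the step cap.
                def ev_gln(t, yv, root=gln_root):
                    return yv[4] / yv[9] - root
                ev_gln.terminal = True
                ev_gln.direction = -1.0
                events.append(("qlac", ev_gln))

            t_eval = wanted[(wanted > ta + 1e-12) & (wanted <= b + 1e-12)]
            try:
                sol = solve_ivp(
                    lambda t, yv: mass_balance_rhs(yv, regime, flows, params),
                    (ta, b), y, method=options.method, rtol=options.rtol,
                    atol=options.atol, max_step=options.max_step,
                    t_eval=t_eval if t_eval.size else None,
                    events=[ev for _, ev in events] or None,
                )
            except ValueError:
                # Event localisation can fail when the trajectory grazes a
                # switching surface; fall back to eventless integration, where
                # max_step bounds the smear of the branch change.
                events = []
                gln_restarts = 50
                sol = solve_ivp(
                    lambda t, yv: mass_balance_rhs(yv, regime, flows, params),
                    (ta, b), y, method=options.method, rtol=options.rtol,
                    atol=options.atol, max_step=options.max_step,
                    t_eval=t_eval if t_eval.size else None,
                )
            sol_t = np.asarray(sol.t, dtype=float)
            sol_y = (np.asarray(sol.y, dtype=float) if len(sol.t)
                     else np.empty((10, 0)))
            if sol.status == -1:
                raise SimulationError(
                    f"solver failed at t={sol_t[-1] if sol_t.size else ta:.3f} h: "
                    f"{sol.message}", _partial())

            for tt, yy in zip(sol_t, sol_y.T):
                if tt > t_list[-1] + 1e-12:
                    t_list.append(float(tt))
                    y_list.append(yy.copy())
                    regime_list.append(regime.do_regime)

            if sol.status == 1:  # a terminal event fired
                fired = next(i for i, te in enumerate(sol.t_events) if te.size)
                te = float(sol.t_events[fired][0])
                ye = sol.y_events[fired][0].copy()
                label = events[fired][0]
                if te > t_list[-1] + 1e-12:
                    t_list.append(te)
                    y_list.append(ye)
                    regime_list.append(regime.do_regime)
                if label == "shift":
                    latched = True
                    events_log["do_shift_time"] = te
                    regime_list[-1] = LOW
                else:
                    known = events_log["qlac_event_times"]
                    if not known or abs(known[-1] - te) > 1e-9:
                        known.append(te)
                    gln_restarts += 1
                if te <= ta + 1e-9:  # no progress; drop events and push on
                    gln_restarts = 50
                y = ye
                ta = te
            else:
                y = sol_y[:, -1] if sol_t.size else y
                # ensure we land exactly on the segment edge
                if sol_t.size and sol_t[-1] < b - 1e-12:
                    # t_eval did not include b; integrate silently to the edge
                    tail = solve_ivp(
                        lambda t, yv: mass_balance_rhs(yv, regime, flows, params),
                        (sol_t[-1], b), y, method=options.method,
                        rtol=options.rtol, atol=options.atol,
                        max_step=options.max_step)
                    if tail.status != 0:
                        raise SimulationError("solver failed closing a segment",
                                              _partial())
                    y = tail.y[:, -1]
                ta = b

    traj = Trajectory(np.array(t_list), np.vstack(y_list),
                      np.array(regime_list), params, design, events_log)
    return traj


# -- independent fixed-step cross-check ---------------------------------------

def _rk4_step(f, t, y, h):
    k1 = f(t, y)
    k2 = f(t + 0.5 * h, y + 0.5 * h * k1)
    k3 = f(t + 0.5 * h, y + 0.5 * h * k2)
    k4 = f(t + h, y + h * k3)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate_rk4(params: ModelParameters, design: ExperimentDesign,
                 h: float = 0.01, t_end: Optional[float] = None,
                 refine: int = 100) -> Trajectory:
    """Fixed-step classical RK4 integration (independent cross-check).

    Steps are aligned to the feed and DO-check boundaries; any step that
    crosses a switching point (the Q_lac sign-change glutamine level or the
    DO-shift cell-density trigger) is re-taken as ``refine`` micro-steps so
    the discontinuity is localised to ``h/refine``.
    """
    t_end = design.duration if t_end is None else t_end
    gln_root = qlac_zero_gln(params)
    schedule_mode = design.do_mode == "schedule"
    edges = np.unique(np.concatenate([
        feed_breakpoints(design),
        regime_breakpoints(design) if schedule_mode else (
            [design.do_check_time] if 0 < design.do_check_time < t_end else []),
        [t_end],
    ]))
    edges = edges[edges <= t_end + 1e-12]

    y = initial_state(design)
    t = 0.0
    latched = False
    ts, ys, regs = [0.0], [y.copy()], []

    def _latch_check(tt, yy, latched):
        if schedule_mode:
            return scheduled_regime(design, tt) == LOW
        if not latched and tt >= design.do_check_time - 1e-12 \
                and yy[0] / yy[9] >= design.do_trigger:
            return True
        return latched

    latched = _latch_check(t, y, latched)
    regs.append(LOW if latched else HIGH)
    high, low = kinetics.HIGH_REGIME, kinetics.LOW_REGIME

    for b in edges:
        while t < b - 1e-12:
            step = min(h, b - t)
            latched = _latch_check(t, y, latched)
            regime = low if latched else high
            flows = FlowSnapshot(fin=feed_rate(design, t + 0.5 * step),
                                 cin_glc=design.cin_glc, cin_gln=design.cin_gln)
            f = lambda tt, yy: mass_balance_rhs(yy, regime, flows, params)
            y_new = _rk4_step(f, t, y, step)

            crossed = False
            if not latched:
                if gln_root is not None:
                    g0 = y[4] / y[9] - gln_root
                    g1 = y_new[4] / y_new[9] - gln_root
                    crossed |= (g0 > 0) != (g1 > 0)
                if not schedule_mode and t + step >= design.do_check_time - 1e-12:
                    crossed |= (y_new[0] / y_new[9] >= design.do_trigger)
            if crossed:
                # localise the switch: many small steps, regime/branch
                # re-evaluated at each micro-step start
                hh = step / refine
                for i in range(refine):
                    latched = _latch_check(t, y, latched)
                    regime = low if latched else high
                    f = lambda tt, yy, rg=regime: mass_balance_rhs(
                        yy, rg, flows, params)
                    y = _rk4_step(f, t, y, hh)
                    t += hh
            else:
                y = y_new
                t += step
            ts.append(t)
            ys.append(y.copy())
            regs.append(LOW if _latch_check(t, y, latched) else HIGH)
            latched = _latch_check(t, y, latched)

    # drop any duplicated times from float accumulation
    ts = np.array(ts)
    keep = np.concatenate([[True], np.diff(ts) > 1e-12])
    return Trajectory(ts[keep], np.vstack(ys)[keep],
                      np.array(regs)[keep], params, design, {})
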