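"""Operating designs for fed-batch runs: feeds, volumes, DO-shift rule.

A design describes one cultivation: initial volume and seeding density, basal
media composition, a daily feed schedule expressed as percent of the *initial*
volume per day (delivered continuously), and the DO setpoint shift rule (drop
the setpoint from high to low at a check time once the viable cell density has
reached a trigger; if the trigger is not yet met the shift is deferred until
it is, and once low the regime latches).

Glucose crosses the model boundary in g/L (media specifications) and is
converted to mmol/L with the molar mass of glucose, 180.16 g/mol; all kinetics
run in mmol/L.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

from .kinetics import HIGH, LOW, RegimeContext

__all__ = [
    "GLUCOSE_MOLAR_MASS", "glc_g_per_L_to_mmol", "ExperimentDesign",
    "load_design", "save_design", "load_packaged_design",
    "packaged_design_names", "feed_rate", "feed_breakpoints", "volume_at",
    "do_regime_controller", "scheduled_regime", "regime_breakpoints",
    "initial_state",
]

GLUCOSE_MOLAR_MASS = 180.16  # g/mol


def glc_g_per_L_to_mmol(x: float) -> float:
    """Convert a glucose concentration from g/L to mmol/L."""
    return 1000.0 * x / GLUCOSE_MOLAR_MASS


@dataclass(frozen=True)
class ExperimentDesign:
    """One fed-batch operating design (all internal units: h, L, mmol/L)."""

    name: str
    reactor_type: str          # "shaken" | "stirred"
    V0: float                  # L
    Xv0: float                 # cells/L
    GLC0: float                # mmol/L (basal media)
    GLN0: float                # mmol/L (basal media)
    duration: float            # h
    feed_schedule: Tuple[Tuple[int, float], ...]  # (day index, % of V0 per day)
    cin_glc: float             # mmol/L in feed media
    cin_gln: float = 0.0       # mmol/L in feed media
    feed_start: float = 48.0   # h
    do_mode: str = "trigger"   # "trigger" (shift rule) | "schedule" (setpoints)
    do_check_time: float = 92.0          # h
    do_trigger: float = 5.0e10           # cells/L
    do_setpoints: Tuple[Tuple[float, float], ...] = ((0.0, 50.0), (92.0, 10.0))
    regime_thresholds: RegimeContext = field(default_factory=RegimeContext)
    # Unstated initial states default to 0 (fresh media, seed train).
    Xd0: float = 0.0
    P0: float = 0.0
    LAC0: float = 0.0
    AMM0: float = 0.0
    HCP0: float = 0.0
    DNA0: float = 0.0

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")
        if self.Xv0 <= 0:
            raise ValueError("Xv0 must be positive")
        if self.duration <= self.feed_start:
            raise ValueError("duration must exceed feed_start")
        days = [d for d, _ in self.feed_schedule]
        if sorted(set(days)) != days:
            raise ValueError("feed_schedule days must be strictly increasing")
        if any(p < 0 for _, p in self.feed_schedule):
            raise ValueError("feed percentages must be non-negative")
        if self.do_mode not in ("trigger", "schedule"):
            raise ValueError("do_mode must be 'trigger' or 'schedule'")
        if any(t1 >= t2 for (t1, _), (t2, _) in
               zip(self.do_setpoints, self.do_setpoints[1:])):
            raise ValueError("DO setpoint times must be strictly increasing")

    # -- serialisation ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reactor_type": self.reactor_type,
            "V0_L": self.V0,
            "Xv0_cells_per_mL": self.Xv0 / 1e3,
            "GLC0_g_per_L": self.GLC0 * GLUCOSE_MOLAR_MASS / 1000.0,
            "GLN0_mmol_per_L": self.GLN0,
            "duration_h": self.duration,
            "feed_start_h": self.feed_start,
            "feed_schedule_pct_per_day": [list(e) for e in self.feed_schedule],
            "feed_GLC_g_per_L": self.cin_glc * GLUCOSE_MOLAR_MASS / 1000.0,
            "feed_GLN_mmol_per_L": self.cin_gln,
            "do_mode": self.do_mode,
            "do_setpoints_pct": [list(e) for e in self.do_setpoints],
            "do_shift_check_h": self.do_check_time,
            "do_shift_trigger_cells_per_mL": self.do_trigger / 1e3,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            name=d["name"],
            reactor_type=d["reactor_type"],
            V0=float(d["V0_L"]),
            Xv0=float(d["Xv0_cells_per_mL"]) * 1e3,
            GLC0=glc_g_per_L_to_mmol(float(d["GLC0_g_per_L"])),
            GLN0=float(d["GLN0_mmol_per_L"]),
            duration=float(d["duration_h"]),
            feed_start=float(d.get("feed_start_h", 48.0)),
            feed_schedule=tuple((int(day), float(pct))
                                for day, pct in d["feed_schedule_pct_per_day"]),
            cin_glc=glc_g_per_L_to_mmol(float(d["feed_GLC_g_per_L"])),
            cin_gln=float(d.get("feed_GLN_mmol_per_L", 0.0)),
            do_mode=str(d.get("do_mode", "trigger")),
            do_setpoints=tuple((float(t), float(s))
                               for t, s in d.get("do_setpoints_pct",
                                                 [[0.0, 50.0], [92.0, 10.0]])),
            do_check_time=float(d.get("do_shift_check_h", 92.0)),
            do_trigger=float(d.get("do_shift_trigger_cells_per_mL", 5.0e7)) * 1e3,
        )

    def do_setpoint_at(self, t: float) -> float:
        """Scheduled DO setpoint [%] at time t."""
        times = [s for s, _ in self.do_setpoints]
        i = max(bisect_right(times, t) - 1, 0)
        return self.do_setpoints[i][1]


def load_design(path) -> ExperimentDesign:
    """Load a design from a JSON or YAML file (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return ExperimentDesign.from_dict(data)


def save_design(design: ExperimentDesign, path) -> None:
    path = Path(path)
    data = design.to_dict()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


_PACKAGED = {"A": "design_A.json", "B": "design_B.json", "C": "design_C.json"}


def packaged_design_names() -> tuple:
    return tuple(_PACKAGED)


def load_packaged_design(name: str) -> ExperimentDesign:
    """Packaged fed-batch designs ``"A"``, ``"B"`` or ``"C"``."""
    try:
        fname = _PACKAGED[name]
    except KeyError:
        raise KeyError(f"unknown packaged design {name!r}") from None
    data = json.loads(resources.files("lacshift.data").joinpath(fname).read_text())
    return ExperimentDesign.from_dict(data)


# -- feed profile --------------------------------------------------------------

def _percent_on_day(design: ExperimentDesign, day: int) -> float:
    pct = 0.0
    for d, p in design.feed_schedule:
        if day >= d:
            pct = p
        else:
            break
    return pct


def feed_rate(design: ExperimentDesign, t: float) -> float:
    """Continuous feed rate Fin(t) [L/h].

    A schedule entry ``(day, pct)`` delivers ``pct/100 * V0`` per 24 h from the
    start of that culture day until superseded by the next entry; nothing is
    fed before ``feed_start``.
    """
    if t < design.feed_start:
        return 0.0
    return _percent_on_day(design, int(t // 24.0)) / 100.0 * design.V0 / 24.0


def feed_breakpoints(design: ExperimentDesign) -> np.ndarray:
    """Times in (0, duration) where Fin(t) is discontinuous."""
    pts = {design.feed_start}
    pts.update(24.0 * d for d, _ in design.feed_schedule)
    return np.array(sorted(p for p in pts if 0.0 < p < design.duration))


def volume_at(design: ExperimentDesign, t):
    """Analytic solution volume V(t) = V0 + integral of Fin (fed-batch)."""
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    edges = np.concatenate([[0.0], feed_breakpoints(design), [design.duration]])
    vol = np.full(t.shape, design.V0)
    for a, b in zip(edges[:-1], edges[1:]):
        vol += feed_rate(design, a) * np.clip(t - a, 0.0, b - a)
    # Beyond the run end the last scheduled rate keeps applying (guard only).
    vol += feed_rate(design, edges[-2]) * np.clip(t - design.duration, 0.0, None)
    return float(vol[0]) if scalar else vol


# -- DO regime controller ------------------------------------------------------

def scheduled_regime(design: ExperimentDesign, t: float) -> str:
    """Regime label from the design's DO setpoint schedule (nearest threshold)."""
    return design.regime_thresholds.classify(design.do_setpoint_at(t))


def regime_breakpoints(design: ExperimentDesign) -> np.ndarray:
    """Times in (0, duration) where the scheduled regime label changes."""
    pts = []
    prev = scheduled_regime(design, 0.0)
    for tt, _ in design.do_setpoints:
        lab = scheduled_regime(design, tt)
        if lab != prev and 0.0 < tt < design.duration:
            pts.append(tt)
        prev = lab
    return np.array(pts)


def do_regime_controller(t: float, xv: float, design: ExperimentDesign,
                         latched_low: bool = False) -> RegimeContext:
    """DO regime at time t given the current viable cell density.

    High before the check time; from the check time onward the regime drops to
    low once the viable cell density has reached the trigger, and stays low
    thereafter (latching).  ``latched_low`` carries the latch between calls.
    """
    ctx = design.regime_thresholds
    if latched_low:
        return RegimeContext(LOW, ctx.DO_high_threshold, ctx.DO_low_threshold)
    if t >= design.do_check_time and xv >= design.do_trigger:
        return RegimeContext(LOW, ctx.DO_high_threshold, ctx.DO_low_threshold)
    return RegimeContext(HIGH, ctx.DO_high_threshold, ctx.DO_low_threshold)


def initial_state(design: ExperimentDesign) -> np.ndarray:
    """Initial extensive state vector (order ``kinetics.STATE_NAMES``)."""
    v = design.V0
    return np.array([
        v * design.Xv0, v * design.Xd0, v * design.P0, v * design.GLC0,
        v * design.GLN0, v * design.LAC0, v * design.AMM0, v * design.HCP0,
        v * design.DNA0, v,
    ])
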