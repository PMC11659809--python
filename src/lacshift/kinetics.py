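"""Specific-rate laws and mass balances of the fed-batch CHO culture model.

The model is unstructured and piecewise in the dissolved-oxygen (DO) regime:
DO enters only as a two-level label (``"high"`` ~ 50%, ``"low"`` ~ 10%).  At
high DO the specific lactate production rate Q_lac and glutamine consumption
rate Q_gln follow a sigmoid of the glutamine concentration,

    Q = k11 / (k12 + exp(-k13 * GLN)) + k14,

with k14 < 0 so that the net rate changes sign when glutamine is depleted:
below the sigmoid root the culture *consumes* lactate (the lactate metabolic
shift).  At low DO both rates are constants (k21).  Growth switches between a
lactate-inhibited branch (while lactate is being produced) and a
lactate-as-substrate Monod branch (once Q_lac <= 0); death is driven by
lactate and ammonia and suppressed by glucose.

State is carried extensively, as the ten quantities V*Xv, V*Xd, V*P, V*GLC,
V*GLN, V*LAC, V*AMM, V*HCP, V*DNA and V, matching the balance equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .parameters import ModelParameters, ParameterError

__all__ = [
    "HIGH", "LOW", "STATE_NAMES", "COMPONENTS", "COMPONENT_UNITS",
    "RegimeContext", "SpecificRates", "FlowSnapshot", "RateLawError",
    "compute_qlac", "compute_qgln", "compute_mu", "compute_mud", "compute_qp",
    "specific_rates", "qlac_zero_gln", "qgln_zero_gln", "mass_balance_rhs",
]

HIGH = "high"
LOW = "low"

#: Order of the extensive state vector handed to the integrator.
STATE_NAMES = ("VXv", "VXd", "VP", "VGLC", "VGLN", "VLAC",
               "VAMM", "VHCP", "VDNA", "V")

#: Measurable culture components (concentration / density form).
COMPONENTS = ("Xv", "Xd", "P", "GLC", "GLN", "LAC", "AMM", "HCP", "DNA")

COMPONENT_UNITS = {
    "Xv": "cells/L", "Xd": "cells/L", "P": "g/L",
    "GLC": "mmol/L", "GLN": "mmol/L", "LAC": "mmol/L", "AMM": "mmol/L",
    "HCP": "mg/L", "DNA": "mg/L", "V": "L",
}


class RateLawError(ArithmeticError):
    """A rate law evaluated outside its numerical domain (non-finite result)."""


@dataclass(frozen=True)
class RegimeContext:
    """Dissolved-oxygen regime label plus the thresholds that define it."""

    do_regime: str = HIGH
    DO_high_threshold: float = 50.0  # %
    DO_low_threshold: float = 10.0   # %

    def __post_init__(self) -> None:
        if self.do_regime not in (HIGH, LOW):
            raise ValueError(f"do_regime must be 'high' or 'low', got {self.do_regime!r}")
        if not self.DO_high_threshold > self.DO_low_threshold:
            raise ValueError("DO_high_threshold must exceed DO_low_threshold")

    @property
    def is_high(self) -> bool:
        return self.do_regime == HIGH

    def classify(self, do_percent: float) -> str:
        """Map a measured DO value to the nearer regime label."""
        mid = 0.5 * (self.DO_high_threshold + self.DO_low_threshold)
        return HIGH if do_percent >= mid else LOW


HIGH_REGIME = RegimeContext(HIGH)
LOW_REGIME = RegimeContext(LOW)


@dataclass(frozen=True)
class SpecificRates:
    """Per-cell rates at one instant of the culture."""

    mu: float     # h^-1
    mu_d: float   # h^-1
    Q_lac: float  # mmol/cell/h (negative = net consumption)
    Q_gln: float  # mmol/cell/h (negative = net production)
    Q_p: float    # g/cell/h


@dataclass(frozen=True)
class FlowSnapshot:
    """Instantaneous reactor flows and inlet compositions.

    Fed-batch operation keeps ``fbleed = fharvest = 0``; the perfusion terms
    are carried through the balances but default to zero.
    """

    fin: float = 0.0        # L/h, feed
    fsuppl: float = 0.0     # L/h, supplementary glucose
    fbleed: float = 0.0     # L/h
    fharvest: float = 0.0   # L/h
    cin_glc: Optional[float] = None  # mmol/L in feed
    cin_gln: float = 0.0             # mmol/L in feed
    csuppl: Optional[float] = None   # mmol/L in glucose supplement

    def __post_init__(self) -> None:
        for name in ("fin", "fsuppl", "fbleed", "fharvest"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fin > 0 and self.cin_glc is None:
            raise ValueError("cin_glc is required when fin > 0")
        if self.fsuppl > 0 and self.csuppl is None:
            raise ValueError("csuppl is required when fsuppl > 0")


def _sigmoid_rate(gln: float, k1: float, k2: float, k3: float, k4: float,
                  label: str) -> float:
    den = k2 + math.exp(-k3 * gln)
    if den == 0.0:
        raise RateLawError(
            f"{label}: sigmoid denominator underflowed to zero "
            f"(k12=0 with k13*GLN={k3 * gln:.3g})"
        )
    value = k1 / den + k4
    if not math.isfinite(value):
        raise RateLawError(f"{label}: non-finite rate for GLN={gln:.3g}")
    return value


def compute_qlac(gln: float, regime: RegimeContext,
                 params: ModelParameters) -> float:
    """Specific lactate production rate [mmol/cell/h]."""
    if not regime.is_high:
        return params.k_lac21
    return _sigmoid_rate(max(gln, 0.0), params.k_lac11, params.k_lac12,
                         params.k_lac13, params.k_lac14, "Q_lac")


def compute_qgln(gln: float, regime: RegimeContext,
                 params: ModelParameters) -> float:
    """Specific glutamine consumption rate [mmol/cell/h]."""
    if not regime.is_high:
        return params.k_gln21
    return _sigmoid_rate(max(gln, 0.0), params.k_gln11, params.k_gln12,
                         params.k_gln13, params.k_gln14, "Q_gln")


def _root_of_sigmoid(k1: float, k2: float, k3: float, k4: float) -> Optional[float]:
    # k1/(k2+e^{-k3 g}) + k4 = 0  =>  e^{-k3 g} = k1/(-k4) - k2
    if k4 >= 0 or k1 <= 0 or k3 <= 0:
        return None
    arg = k1 / (-k4) - k2
    if arg <= 0:
        return None
    g = -math.log(arg) / k3
    return g if g > 0 else None


def qlac_zero_gln(params: ModelParameters) -> Optional[float]:
    """Glutamine level at which high-DO Q_lac changes sign (None if never)."""
    return _root_of_sigmoid(params.k_lac11, params.k_lac12,
                            params.k_lac13, params.k_lac14)


def qgln_zero_gln(params: ModelParameters) -> Optional[float]:
    """Glutamine level at which high-DO Q_gln changes sign (None if never)."""
    return _root_of_sigmoid(params.k_gln11, params.k_gln12,
                            params.k_gln13, params.k_gln14)


def _monod(c: float, K: float) -> float:
    # Convention: K == 0 means the factor saturates; 0/0 at c == 0 is taken as 0
    # so that a vanishing driver always silences the term.
    if c <= 0.0:
        return 0.0
    return c / (K + c)


def compute_mu(glc: float, gln: float, lac: float, regime: RegimeContext,
               qlac_now: float, params: ModelParameters) -> float:
    """Specific growth rate [1/h].

    Three branches: at high DO growth is lactate-inhibited while lactate is
    produced (``qlac_now > 0``) and lactate-limited Monod once the culture
    consumes lactate; at low DO a separate lactate-inhibition constant (and,
    in shaken tanks, a separate maximum rate) applies.
    """
    glc, gln, lac = max(glc, 0.0), max(gln, 0.0), max(lac, 0.0)
    monod_glc = _monod(glc, params.K_glc)
    if regime.is_high:
        if qlac_now > 0.0:
            sig_gln = 1.0 / (1.0 + math.exp(-gln / params.K_gln))
            inhib = params.KI_lac1 / (params.KI_lac1 + lac)
            return params.mu_max1 * monod_glc * sig_gln * inhib
        return params.mu_max1 * monod_glc * _monod(lac, params.K_lac)
    mu_max = params.mu_max2 if params.reactor_type == "shaken" else params.mu_max1
    inhib = params.KI_lac2 / (params.KI_lac2 + lac)
    return mu_max * monod_glc * inhib


def compute_mud(lac: float, amm: float, glc: float, regime: RegimeContext,
                params: ModelParameters) -> float:
    """Specific death rate [1/h]: lactate- and ammonia-driven, glucose-inhibited."""
    lac, amm, glc = max(lac, 0.0), max(amm, 0.0), max(glc, 0.0)
    if params.reactor_type == "shaken" and not regime.is_high:
        kd, kd_lac = params.kd2, params.KD_lac2
    else:
        kd, kd_lac = params.kd1, params.KD_lac1
    return (kd * _monod(lac, kd_lac) * _monod(amm, params.KD_amm)
            * params.KDI_glc / (params.KDI_glc + glc))


def compute_qp(mu: float, mu_d: float, params: ModelParameters) -> float:
    """Specific mAb production rate [g/cell/h]; zero when net growth is negative."""
    net = mu - mu_d
    return params.q_p * net if net > 0.0 else 0.0


def specific_rates(glc: float, gln: float, lac: float, amm: float,
                   regime: RegimeContext, params: ModelParameters) -> SpecificRates:
    """All per-cell rates at the given concentrations and DO regime."""
    q_lac = compute_qlac(gln, regime, params)
    q_gln = compute_qgln(gln, regime, params)
    mu = compute_mu(glc, gln, lac, regime, q_lac, params)
    mu_d = compute_mud(lac, amm, glc, regime, params)
    return SpecificRates(mu=mu, mu_d=mu_d, Q_lac=q_lac, Q_gln=q_gln,
                         Q_p=compute_qp(mu, mu_d, params))


def _dissolution(rate: float, K: float, conc: float, volume: float) -> float:
    if rate == 0.0 or conc <= 0.0:
        return 0.0
    return rate * volume * conc / (K + conc)


def mass_balance_rhs(y: Sequence[float], regime: RegimeContext,
                     flows: FlowSnapshot, params: ModelParameters) -> np.ndarray:
    """Time derivative of the extensive state vector (order ``STATE_NAMES``).

    Concentrations handed to the rate laws are clipped at zero so that small
    integrator overshoots below zero cannot produce non-finite rates.
    """
    V = y[9]
    if V <= 0:
        raise ValueError(f"non-positive volume V={V}")
    vxv, vxd, vp = max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0)
    vglc, vgln, vlac = max(y[3], 0.0), max(y[4], 0.0), max(y[5], 0.0)
    vamm, vhcp, vdna = max(y[6], 0.0), max(y[7], 0.0), max(y[8], 0.0)
    xv, xd = vxv / V, vxd / V
    glc, gln, lac, amm = vglc / V, vgln / V, vlac / V, vamm / V
    hcp, dna = vhcp / V, vdna / V

    r = specific_rates(glc, gln, lac, amm, regime, params)
    out_flow = flows.fharvest + flows.fbleed
    lysis = params.r_dcell * V * xd / (params.K_ldcell + xd)

    d = np.empty(10)
    d[0] = (r.mu - r.mu_d) * vxv - flows.fbleed * xv
    d[1] = r.mu_d * vxv - lysis - flows.fbleed * xd
    d[2] = r.Q_p * vxv - out_flow * vp / V
    d[3] = (-(r.mu / params.Y_Xv_glc + params.m_glc) * vxv
            + flows.fin * (flows.cin_glc or 0.0)
            + flows.fsuppl * (flows.csuppl or 0.0)
            - out_flow * glc)
    d[4] = -r.Q_gln * vxv + flows.fin * flows.cin_gln - out_flow * gln
    d[5] = r.Q_lac * vxv - out_flow * lac
    # Ammonia from glutamine catabolism only while glutamine is net-consumed.
    d[6] = (params.k_amm1 * max(r.Q_gln, 0.0) + params.k_amm2) * vxv - out_flow * amm
    d[7] = (params.Y_hcp_Xd * lysis
            - _dissolution(params.r_hcp, params.K_dhcp, hcp, V)
            - out_flow * hcp)
    d[8] = (params.Y_dna_Xd * lysis
            - _dissolution(params.r_dna, params.K_ddna, dna, V)
            - out_flow * dna)
    d[9] = flows.fin + flows.fsuppl - out_flow
    return d
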