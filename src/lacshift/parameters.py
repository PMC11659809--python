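"""Kinetic parameter set for the fed-batch CHO culture model.

All rate constants live in a single flat :class:`ModelParameters` record.  Two
reactor variants exist: ``"shaken"`` (orbitally-shaken tank) carries separate
low-DO growth/death constants (``mu_max2``, ``kd2``, ``KD_lac2``); ``"stirred"``
reuses its high-DO constants at low DO (apart from the lactate-inhibition
constant ``KI_lac2``, which both variants carry).

Units follow the model's internal convention: time h, volume L, cells cells/L,
glucose/glutamine/lactate/ammonia mmol/L, mAb g/L, HCP/DNA mg/L.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

__all__ = [
    "ModelParameters",
    "ParameterError",
    "load_parameters",
    "save_parameters",
    "load_packaged_parameters",
    "packaged_parameter_names",
    "percentage_changes",
    "round_sig",
]


class ParameterError(ValueError):
    """Invalid or inconsistent kinetic parameter set."""


# Constants with a strictly-positive invariant unless the corresponding term is
# disabled (rate = 0) or footnoted negligible in the source parameter set.
_MAY_BE_ZERO_K = {"KD_lac2", "K_dhcp", "K_ddna"}
_SATURATION_K = {
    "K_glc", "K_gln", "K_lac", "KI_lac1", "KI_lac2",
    "KD_lac1", "KD_lac2", "KD_amm", "KDI_glc", "K_dhcp", "K_ddna",
}
_NONNEGATIVE = {
    "mu_max1", "mu_max2", "kd1", "kd2", "Y_Xv_glc", "m_glc", "q_p",
    "K_ldcell", "r_dcell", "r_hcp", "r_dna", "Y_hcp_Xd", "Y_dna_Xd",
    "k_gln12", "k_lac12",
}
_SHAKEN_ONLY = ("mu_max2", "kd2", "KD_lac2")

# Parameters that may legitimately be negative (net production/consumption
# offsets and low-DO net rates).  Everything else is optimised on a log scale.
SIGN_FREE = frozenset({"k_gln14", "k_lac14", "k_gln21", "k_lac21"})


@dataclass(frozen=True)
class ModelParameters:
    """Point estimates of every kinetic constant of the culture model."""

    reactor_type: str  # "shaken" | "stirred"

    mu_max1: float  # h^-1, max specific growth (high DO; stirred: both regimes)
    kd1: float      # h^-1, max specific death (high DO; stirred: both regimes)

    K_glc: float    # mmol/L, Monod constant of growth on glucose
    K_gln: float    # mmol/L, glutamine sigmoid scale in growth
    K_lac: float    # mmol/L, Monod constant of growth on lactate (consumption phase)
    KI_lac1: float  # mmol/L, lactate inhibition of growth, high DO
    KI_lac2: float  # mmol/L, lactate inhibition of growth, low DO
    KD_lac1: float  # mmol/L, lactate activation of death (high DO / stirred)
    KD_amm: float   # mmol/L, ammonia activation of death
    KDI_glc: float  # mmol/L, glucose inhibition of death

    Y_Xv_glc: float  # cells/mmol, growth yield on glucose
    m_glc: float     # mmol/cell/h, maintenance glucose consumption

    k_gln11: float  # mmol/cell/h, glutamine sigmoid amplitude (high DO)
    k_gln12: float  # -, glutamine sigmoid offset
    k_gln13: float  # L/mmol, glutamine sigmoid steepness
    k_gln14: float  # mmol/cell/h, glutamine production offset (negative)
    k_gln21: float  # mmol/cell/h, net glutamine consumption at low DO

    k_lac11: float  # mmol/cell/h, lactate sigmoid amplitude (high DO)
    k_lac12: float  # -, lactate sigmoid offset
    k_lac13: float  # L/mmol, lactate sigmoid steepness
    k_lac14: float  # mmol/cell/h, lactate consumption offset (negative)
    k_lac21: float  # mmol/cell/h, net lactate production at low DO

    k_amm1: float  # -, ammonia yield on glutamine consumption
    k_amm2: float  # mmol/cell/h, glutamine-independent ammonia production

    q_p: float  # g/cell, mAb production per unit net growth

    K_ldcell: float  # cells/L, dead-cell lysis saturation constant
    r_dcell: float   # cells/L/h, max dead-cell lysis rate
    r_hcp: float     # mg/L/h, HCP dissolution rate
    r_dna: float     # mg/L/h, DNA dissolution rate
    K_dhcp: float    # mg/L, HCP dissolution constant
    K_ddna: float    # mg/L, DNA dissolution constant
    Y_hcp_Xd: float  # mg/cell, HCP released per lysed dead cell
    Y_dna_Xd: float  # mg/cell, DNA released per lysed dead cell

    # Shaken-tank low-DO variants; must stay unset for stirred tanks.
    _mu_max2: Optional[float] = field(default=None, repr=False)
    _kd2: Optional[float] = field(default=None, repr=False)
    _KD_lac2: Optional[float] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.reactor_type not in ("shaken", "stirred"):
            raise ParameterError(f"unknown reactor_type {self.reactor_type!r}")
        if self.reactor_type == "stirred":
            for name in _SHAKEN_ONLY:
                if getattr(self, "_" + name) is not None:
                    raise ParameterError(
                        f"{name} must be unset for a stirred-tank parameter set"
                    )
        else:
            for name in ("mu_max2", "kd2"):
                if getattr(self, "_" + name) is None:
                    raise ParameterError(f"{name} is required for a shaken tank")
            if self._KD_lac2 is None:
                object.__setattr__(self, "_KD_lac2", 0.0)
        for name, value in self.to_dict().items():
            if name == "reactor_type" or value is None:
                continue
            if not math.isfinite(value):
                raise ParameterError(f"{name} is not finite: {value}")
            if name in _SATURATION_K:
                if value < 0 or (value == 0 and name not in _MAY_BE_ZERO_K):
                    raise ParameterError(f"{name} must be strictly positive")
            elif name in _NONNEGATIVE and value < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.Y_Xv_glc <= 0:
            raise ParameterError("Y_Xv_glc must be strictly positive")

    # -- shaken-only accessors -------------------------------------------------
    def _shaken_only(self, name: str) -> float:
        value = getattr(self, "_" + name)
        if value is None:
            raise ParameterError(
                f"{name} is a shaken-tank parameter; not defined for "
                f"reactor_type={self.reactor_type!r}"
            )
        return value

    @property
    def mu_max2(self) -> float:
        return self._shaken_only("mu_max2")

    @property
    def kd2(self) -> float:
        return self._shaken_only("kd2")

    @property
    def KD_lac2(self) -> float:
        return self._shaken_only("KD_lac2")

    # -- generic access --------------------------------------------------------
    def get(self, name: str) -> float:
        """Value of a parameter by its canonical name (raises if unset)."""
        if name in _SHAKEN_ONLY:
            return self._shaken_only(name)
        if name == "reactor_type" or not hasattr(self, name):
            raise KeyError(name)
        return getattr(self, name)

    def with_values(self, **updates: float) -> "ModelParameters":
        """A copy with the given parameters replaced (validated)."""
        mapped = {
            ("_" + k if k in _SHAKEN_ONLY else k): v for k, v in updates.items()
        }
        return replace(self, **mapped)

    def to_dict(self) -> dict:
        out: dict = {"reactor_type": self.reactor_type}
        for f in fields(self):
            if f.name == "reactor_type":
                continue
            name = f.name.lstrip("_")
            value = getattr(self, f.name)
            if name in _SHAKEN_ONLY and value is None:
                continue
            out[name] = value
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParameters":
        payload = {
            k: v for k, v in data.items() if k != "standard_errors"
        }
        mapped = {
            ("_" + k if k in _SHAKEN_ONLY else k): v for k, v in payload.items()
        }
        return cls(**mapped)

    def names(self) -> tuple:
        """Names of all parameters defined for this reactor variant."""
        return tuple(k for k in self.to_dict() if k != "reactor_type")


# -- file I/O ------------------------------------------------------------------

def load_parameters(path) -> ModelParameters:
    """Load a flat JSON parameter file (``standard_errors`` block is ignored)."""
    with open(path) as fh:
        return ModelParameters.from_dict(json.load(fh))


def load_standard_errors(path) -> dict:
    """Standard-error block of a parameter file (empty dict if absent)."""
    with open(path) as fh:
        return dict(json.load(fh).get("standard_errors", {}))


def save_parameters(params: ModelParameters, path,
                    standard_errors: Optional[Mapping[str, float]] = None) -> None:
    payload = params.to_dict()
    if standard_errors:
        payload["standard_errors"] = dict(standard_errors)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


_PACKAGED = {
    "shaken_A": "params_shaken_A.json",
    "stirred_C": "params_stirred_C.json",
}


def packaged_parameter_names() -> tuple:
    return tuple(_PACKAGED)


def load_packaged_parameters(name: str, with_errors: bool = False):
    """Packaged parameter sets: ``"shaken_A"`` or ``"stirred_C"``."""
    try:
        fname = _PACKAGED[name]
    except KeyError:
        raise KeyError(f"unknown packaged parameter set {name!r}; "
                       f"choose from {sorted(_PACKAGED)}") from None
    data = json.loads(
        resources.files("lacshift.data").joinpath(fname).read_text()
    )
    params = ModelParameters.from_dict(data)
    if with_errors:
        return params, dict(data.get("standard_errors", {}))
    return params


# -- parameter comparison ------------------------------------------------------

def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def percentage_changes(base: ModelParameters, other: ModelParameters,
                       sig: int = 3) -> dict:
    """Relative parameter changes ``100*(other - base)/base``, per parameter.

    Returns a mapping name -> rounded percentage (3 significant figures by
    default).  Rows that cannot be compared carry a string flag instead:
    ``"not_applicable"`` when the parameter is unused by one reactor variant,
    ``"not_calculated"`` when either value is zero (negligible-impact entries),
    and ``">100%"`` when the relative change exceeds 100% in magnitude.
    """
    names = sorted(set(base.names()) | set(other.names()))
    out: dict = {}
    for name in names:
        try:
            a = base.get(name)
            b = other.get(name)
        except ParameterError:
            out[name] = "not_applicable"
            continue
        if a == 0.0 or b == 0.0:
            out[name] = "not_calculated"
            continue
        pct = 100.0 * (b - a) / a
        out[name] = ">100%" if abs(pct) > 100.0 else round_sig(pct, sig)
    return out
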