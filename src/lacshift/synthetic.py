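"""In-silico fed-batch experiments: simulate, sample daily, add assay noise.

The generator stands in for bench data: it integrates the model under an
operating design, samples the nine offline-measured components at the given
times (daily by default, final sample at run end), and perturbs each value
with multiplicative lognormal noise of a per-component coefficient of
variation.  The noise-free truth is returned alongside so estimators can be
scored against it.  Mean-preserving lognormal factors are used
(E[factor] = 1), with sigma^2 = ln(1 + CV^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .design import ExperimentDesign, load_packaged_design, save_design
from .kinetics import COMPONENT_UNITS, COMPONENTS
from .parameters import (ModelParameters, load_packaged_parameters,
                         save_parameters)
from .rates import MeasurementSeries
from .simulate import SolverOptions, Trajectory, simulate

__all__ = ["NoiseModel", "default_sampling_times", "generate_experiment",
           "make_fixture_suite"]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise with detection floors."""

    cv: Union[float, Mapping[str, float]] = 0.05
    floor: Union[float, Mapping[str, float]] = 0.0
    seed: int = 0

    def cv_for(self, component: str) -> float:
        cv = self.cv.get(component, 0.0) if isinstance(self.cv, Mapping) else self.cv
        if cv < 0:
            raise ValueError("CV must be non-negative")
        return float(cv)

    def floor_for(self, component: str) -> float:
        fl = (self.floor.get(component, 0.0)
              if isinstance(self.floor, Mapping) else self.floor)
        if fl < 0:
            raise ValueError("floor must be non-negative")
        return float(fl)

    def apply(self, component: str, values: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
        cv = self.cv_for(component)
        if cv == 0.0:
            noisy = np.asarray(values, dtype=float).copy()
        else:
            sigma = float(np.sqrt(np.log1p(cv * cv)))
            factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                                    size=np.shape(values))
            noisy = np.asarray(values, dtype=float) * factors
        return np.maximum(noisy, self.floor_for(component))


def default_sampling_times(design: ExperimentDesign) -> np.ndarray:
    """Daily offline sampling from t=0, plus a final sample at run end."""
    times = np.arange(0.0, design.duration, 24.0)
    if design.duration - times[-1] > 1e-9:
        times = np.append(times, design.duration)
    return times


def generate_experiment(
    params: ModelParameters,
    design: ExperimentDesign,
    sampling_times: Optional[np.ndarray] = None,
    noise: Optional[NoiseModel] = None,
    components: Sequence[str] = COMPONENTS,
    solver: Optional[SolverOptions] = None,
) -> Tuple[Dict[str, MeasurementSeries], Trajectory]:
    """One synthetic experiment: noisy offline series plus the ground truth.

    Fully reproducible: the same ``noise.seed`` yields identical output.
    """
    noise = noise or NoiseModel()
    times = (default_sampling_times(design) if sampling_times is None
             else np.asarray(sampling_times, dtype=float))
    if times.min() < 0 or times.max() > design.duration:
        raise ValueError("sampling times must lie within the run")
    unknown = set(components) - set(COMPONENTS)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")

    truth = simulate(params, design, options=solver, extra_times=times)
    rng = np.random.default_rng(noise.seed)
    measurements = {}
    for comp in COMPONENTS:  # fixed order so the rng stream is stable
        if comp not in components:
            continue
        clean = truth.at(comp, times)
        measurements[comp] = MeasurementSeries(
            comp, times, noise.apply(comp, clean, rng),
            unit=COMPONENT_UNITS[comp])
    return measurements, truth


def make_fixture_suite(outdir, seed: int = 1234, cv: float = 0.05) -> Dict[str, Path]:
    """Write the packaged designs, parameter sets and synthetic datasets.

    For each design A/B/C: one noise-free and one noisy (seeded) daily
    measurement CSV.  Design B omits glutamine, exercising the
    missing-component path of the fitting objective.  Shaken-tank parameters
    drive A and B; stirred-tank parameters drive C.
    """
    from .io import write_measurements_csv  # local import avoids a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    param_sets = {"A": "shaken_A", "B": "shaken_A", "C": "stirred_C"}
    for label, pname in (("shaken_A", "shaken_A"), ("stirred_C", "stirred_C")):
        params, ses = load_packaged_parameters(pname, with_errors=True)
        path = outdir / f"params_{label}.json"
        save_parameters(params, path, standard_errors=ses)
        written[f"params_{label}"] = path

    for name in ("A", "B", "C"):
        design = load_packaged_design(name)
        dpath = outdir / f"design_{name}.json"
        save_design(design, dpath)
        written[f"design_{name}"] = dpath

        params = load_packaged_parameters(param_sets[name])
        components = tuple(c for c in COMPONENTS
                           if not (name == "B" and c == "GLN"))
        clean, _ = generate_experiment(
            params, design, noise=NoiseModel(cv=0.0, seed=seed),
            components=components)
        cpath = outdir / f"measurements_{name}_noisefree.csv"
        write_measurements_csv(clean, cpath)
        written[f"measurements_{name}_noisefree"] = cpath

        noisy, _ = generate_experiment(
            params, design, noise=NoiseModel(cv=cv, seed=seed),
            components=components)
        npath = outdir / f"measurements_{name}_noisy_seed{seed}.csv"
        write_measurements_csv(noisy, npath)
        written[f"measurements_{name}_noisy"] = npath

    return written
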