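"""Prediction band from parameter uncertainty.

Takes the packaged shaken-tank estimates with their standard errors, samples
parameter vectors from independent normals (truncated at the feasibility
boundary), simulates each draw, and reports the pointwise min/max band.  The
printed numbers are the band widths at the end of the run: they quantify how
much the reported parameter uncertainty moves the predictions.
"""

import lacshift as ls
from lacshift.fitting import FitResult, prediction_envelope

params, ses = ls.load_packaged_parameters("shaken_A", with_errors=True)
design = ls.load_packaged_design("A")
free = ("mu_max1", "K_glc", "q_p", "K_ldcell")

result = FitResult(params=params, free=free, start={},
                   objective=float("nan"), r2={}, n_iterations=0,
                   n_evaluations=0, converged=True,
                   message="packaged estimates",
                   standard_errors={n: ses[n] for n in free})
env = prediction_envelope(result, design, n_samples=100, seed=1)

t_end = env.t[-1]
print(f"samples               : {env.n_samples} (seed 1)")
print(f"mAb titre at {t_end:.0f} h   : {env.point['P'][-1]:.2f} g/L "
      f"[{env.lower['P'][-1]:.2f}, {env.upper['P'][-1]:.2f}]")
print(f"viable cells at end   : {env.point['Xv'][-1] / 1e3 / 1e6:.1f}e6/mL "
      f"[{env.lower['Xv'][-1] / 1e3 / 1e6:.1f}, "
      f"{env.upper['Xv'][-1] / 1e3 / 1e6:.1f}]")
print(f"HCP at end            : {env.point['HCP'][-1]:.0f} mg/L "
      f"[{env.lower['HCP'][-1]:.0f}, {env.upper['HCP'][-1]:.0f}]")
print()
print("The band is the min/max over all sampled trajectories including the")
print("point estimate, so it always brackets the point-estimate run.")
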