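"""Recover specific rates from daily offline measurements.

Generates a noise-free synthetic experiment (daily samples of the nine
offline-measured components), then inverts the fed-batch balances using
shape-preserving (PCHIP) interpolation.  The printed numbers compare the
re-estimated lactate-shift time against the simulator's own record: with
one sample per day the crossing is located to within half a sampling
interval.
"""

import lacshift as ls

params = ls.load_packaged_parameters("shaken_A")
design = ls.load_packaged_design("A")

measurements, truth = ls.generate_experiment(
    params, design, noise=ls.NoiseModel(cv=0.0, seed=0))
rates = ls.estimate_specific_rates(measurements, design)

est_cross = rates["Q_lac"].zero_crossings()[0]
true_cross = truth.qlac_sign_change_times()[0]

print(f"estimated rates       : {', '.join(rates)}")
print(f"Q_lac sign change     : {est_cross:.1f} h (estimated from daily data)")
print(f"                        {true_cross:.1f} h (simulator log)")
print(f"apparent growth rate  : {rates['mu_app'].values.max():.3f} 1/h (peak)")
print(f"Q_p peak              : {rates['Q_p'].values.max():.2e} g/cell/h")
print()
print("Q_lac > 0 means net lactate production; the crossing marks the")
print("metabolic shift to lactate consumption after glutamine depletion.")
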