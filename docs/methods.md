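# Methods

## Model structure and assumptions

The model is an unstructured kinetic description of a fed-batch CHO culture:
all biology is carried by per-cell specific rates that depend only on bulk
extracellular concentrations and on a two-level dissolved-oxygen (DO) regime
label.  There is no intracellular flux model, no pH, temperature, osmolality
or CO2 dependence, and no continuous DO kinetics: DO acts purely as a switch
between a "high" (~50%) and a "low" (~10%) regime, because that is the
resolution at which the operating strategies it represents control DO.
Perfusion terms (bleed, harvest) are carried through every balance but are
zero in fed-batch operation.

State is integrated extensively (`V·c` and `V`), which makes feeding exact:
`dV/dt = F_in` and the feed contributes `F_in·c_in` to the corresponding
extensive balance.  Glucose crosses the package boundary in g/L (media
specifications) and is converted once, at the boundary, with a molar mass of
180.16 g/mol; internally everything runs in mmol/L, cells/L, g/L (mAb),
mg/L (HCP, DNA), hours and litres.

Key behavioural assumptions, kept deliberately literal:

- The high-DO lactate and glutamine rates are sigmoids in glutamine with a
  negative offset, so each has a single sign-change root.  Below the
  glutamine root the culture consumes lactate and (slightly) produces
  glutamine; the glutamine level therefore self-stabilises near the
  glutamine-rate root (≈ 0.835 mmol/L for the shaken-tank estimates), just
  below the lactate-rate root (≈ 0.894 mmol/L).
- The growth sigmoid `1/(1+exp(-GLN/K_gln))` equals 0.5 at zero glutamine:
  growth is *not* fully suppressed by glutamine exhaustion.  This is
  implemented literally and users should be aware of it.
- Ammonia is produced from glutamine catabolism only while glutamine is
  net-consumed (`k_amm1·max(Q_gln, 0)`), plus a constant per-cell term.
- HCP and DNA are released instantaneously on dead-cell lysis (a saturable
  Michaelis–Menten flux in the dead-cell density).  Delayed DNA release is a
  known limitation of this assumption.
- Production is growth-associated and clipped: `Q_p = q_p·max(μ−μd, 0)`.

Parameters marked negligible in the packaged estimates (`m_glc`, `k_gln12`,
`K_dhcp`, `K_ddna`, `r_hcp`, `r_dna`, and `KD_lac2` for the shaken set)
default to zero.  Two numerical consequences are handled explicitly: with
`k_lac12 = 0` the sigmoid denominator can underflow to zero at very large
glutamine, which raises a domain error instead of returning infinity; and a
zero saturation constant makes `c/(K+c)` equal 1 for `c > 0` and 0 at
`c = 0` (a vanishing driver always silences its term).

## DO regimes: rule vs schedule

Designs carry both the shift *rule* (drop the setpoint at a check time once
viable cell density has reached a trigger; deferred until met; latching) and
the *recorded setpoint schedule*.  `do_mode="trigger"` (default) applies the
rule through solver events; `do_mode="schedule"` follows the setpoint
schedule, classifying each setpoint to the nearer regime threshold.  The
packaged designs use the schedule (shift at 92 h): with the packaged
parameter estimates the simulated peak density (≈ 49×10⁶ cells/mL for
design A) sits just under the 50×10⁶ cells/mL trigger, so the rule alone
would never shift even though the operating history it emulates did.  Both
modes are first-class and tested.

## Numerics

The right-hand side is discontinuous at feed-schedule boundaries, at the DO
shift, and at the growth-branch switch where `Q_lac` changes sign (an
analytically known glutamine level).  The integrator (`solve_ivp`, LSODA,
rtol 1e-8 / atol 1e-10 on the extensive state, max step 0.5 h) splits the
run at the known boundaries and uses terminal events for the state-dependent
switches, restarting at each so the adaptive solver never steps across a
discontinuity.  Event localisation can fail when a trajectory grazes a
switching surface (this happens for some perturbed parameter draws whose
glutamine equilibrium sits exactly at the branch root); the segment is then
re-integrated without events and the max-step cap bounds the smear.  Rate
laws receive concentrations clipped at zero so integrator overshoot cannot
produce non-finite rates.

An independent fixed-step classical RK4 integrator (`simulate_rk4`,
h = 0.01 h, steps aligned to boundaries, 100× local refinement around
switching points) serves as a cross-check; on a 48 h run of the packaged
shaken-tank configuration the two agree to a maximum relative state error of
about 2e-6, and volume matches the analytic feed integral to machine
precision.  The comparison normalises each state's error by
`max(|state|, 1e-6·max_t|state|)` so states that pass through zero do not
produce spurious relative errors.

A loose profile (rtol 1e-6, max step 2 h, 1 h output grid) is used inside
fitting and envelope loops, where per-evaluation cost matters more than the
last four digits.

## Rate estimation from sparse data

Measured series are interpolated with PCHIP (shape-preserving; monotone data
give monotone interpolants, so derivatives never overshoot between samples)
and the fed-batch balances are inverted on an hourly grid:
`Q_lac = d(V·LAC)/dt / (V·Xv)` and analogously for `Q_gln` (minus the feed
glutamine term), `Q_p`, and the apparent growth rate `μ−μd`.  The volume is
reconstructed analytically from the design's feed profile.  The grid is
trimmed by half a sampling interval at each end because one-sided PCHIP end
derivatives are noticeably less accurate.  Glucose is not inverted for a
specific rate (its balance couples consumption to growth through a yield).

Accuracy is limited by sampling density, not by the inversion: with daily
samples the lactate-shift time is located to within half a sampling interval
(the package's round-trip tests bound it by 12 h), while tracking the full
time course of fast-moving rates (growth swings around glucose depletion and
the DO shift) to ~10% requires roughly 12 h sampling.  Exclusion-aware
re-estimation supports the standard diagnostic of dropping a suspect early
sample and comparing the resulting rate curves; by PCHIP locality the effect
of an exclusion is confined to the neighbouring intervals.

## Fitting and uncertainty

The objective is the sum over measured components of R² between the measured
series and the simulated trajectory at the measurement times, computed on
concentrations, unweighted.  Components that were not measured simply drop
out (e.g. a glutamine-free dataset sums over eight components).  Failed
simulations map to a large negative penalty.  Nelder–Mead maximises the
objective; positivity-constrained parameters are optimised on a log scale
(positivity by construction), while sign-free offsets (`k_gln14`,
`k_lac14`, `k_gln21`, `k_lac21`) stay linear.  The run is deterministic
given the start point and options.

The summed-R² objective is not a likelihood.  The reported "standard errors"
are the square roots of the diagonal of the inverse finite-difference
Hessian of the negated objective at the optimum (central differences,
relative step 1e-3, native parameter scale) — a curvature-based uncertainty
measure, reproduced because it is the convention this workflow follows, not
a formally calibrated standard error.  Non-positive-definite or singular
curvature is reported as NaN per parameter and flagged, never silently
repaired.

Prediction envelopes draw parameter vectors from independent normals
(mean = estimate, sd = SE; no covariance), redraw any draw that violates a
parameter invariant (truncation at the feasible boundary), simulate each,
and report the pointwise min/max per state over all samples including the
point-estimate run.  Envelopes are reproducible by seed.

## Synthetic experiments

The generator emulates the study conditions the packaged designs encode:
30 L initial volume, seeding densities of 2.33/2.32/2.45×10⁶ cells/mL,
9.6 g/L basal glucose, 4 mmol/L basal glutamine, 120 g/L glucose in the feed
(no glutamine), continuous feeding from day 2 at 5/10(/12)% of the initial
volume per day, runs of 139 or 164 h, and the DO setpoint drop at 92 h.
Offline sampling is daily from t = 0 with a final sample at run end; initial
values of unmeasured-at-start states (lactate, ammonia, product, dead cells,
HCP, DNA) are zero (fresh media, seed train).  Measurement noise is
multiplicative lognormal with mean-preserving factors
(σ² = ln(1+CV²)), default CV 5% for every component — assay CVs for the
emulated measurements are not published, so 5% is a package choice, and all
recovery statements are relative to it.  A detection floor per component is
supported and defaults to zero.  Design B withholds glutamine, exercising
the missing-component path of the objective.

What the generator does *not* emulate: sampling-volume withdrawal (the
balances omit it, which is one reason simulated final volumes need not match
recorded ones), online sensor streams other than the DO setpoint trace,
sensor drift, and any misfit between the model family and real cultures.
Passing recovery tests therefore demonstrate that the estimation machinery
inverts the model correctly under realistic noise — not that the model
family captures any particular real bioreactor.

## Problem sizes used by the checks

The packaged checks run at desk scale on one CPU: a 48 h window for the
integrator cross-check (fixed step 0.01 h); daily sampling of the 139 h
design for self-fit and round-trip checks; five replicate noisy experiments
(CV 5%, seeds derived from the CLI seed) with a five-parameter fit capped at
600 Nelder–Mead iterations for the recovery surface; and 200-sample
envelopes on an hourly grid.  These sizes were chosen so the full
reproduction script completes in minutes while leaving each statistic's
conclusion unchanged under seed changes.

## Known limitations

- Two parameter sets (shaken vs stirred) are needed; nothing in the model
  interpolates between agitation regimes or DO levels.
- The growth-branch switch is genuinely discontinuous; no smoothing is
  applied, so trajectories have corners at the shift times.
- Identifiability: fitting all ~30 parameters from one run is not
  well-posed; the packaged workflows fit small user-chosen subsets.  No
  profile likelihoods or formal identifiability analysis are provided.
- The curvature "standard errors" inherit the arbitrary scaling of the
  summed-R² objective; envelopes built from them are descriptive, not
  calibrated prediction intervals.
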