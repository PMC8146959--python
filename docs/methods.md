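# Methods

## The two-pool steady-state model

Circulating acetoacetate (AcAc) and β-hydroxybutyrate (BHB) are modelled
as two well-mixed blood pools connected by bidirectional interconversion
and fed by endogenous production and two tracer infusions. At metabolic
and isotopic steady state the system is fully described by six fluxes
(µmol/h per animal):

| flux | meaning |
| --- | --- |
| `ra_acac`, `ra_bhb` | endogenous appearance (hepatic release) |
| `ri_acac` | AcAc → BHB interconversion |
| `ri_bhb` | BHB → AcAc interconversion |
| `rd_acac`, `rd_bhb` | irreversible disposal |

with two node balances,
`rinf_acac + ra_acac + ri_bhb = rd_acac + ri_acac` and symmetrically for
BHB, leaving four free net fluxes. The tracers are [3,4-¹³C₂]AcAc
(M+2) and [U-¹³C₄]BHB (M+4); because no reaction cleaves or condenses
the tracked carbon skeleton, only even carbon masses {0, 2, 4} are
reachable in vivo, and the isotopologue balances close at the level of
whole-molecule MIDs. The forward simulator therefore solves one 2×2
linear system per carbon mass instead of running a generic isotopomer
decomposition; the full atom-mapped network (eleven reactions, carbons
`A–D`, the C3 hydrogen `a`, zero-stoichiometry sampling reactions) is
retained as the validated source of truth, and the hydrogen bookkeeping
is asserted to reduce to a carbon-only model plus a deterministic +1
mass on the AcAc-derived fraction (the sample-prep deuterium).

**Measurement encoding.** Treatment of blood with NaB²H₄ converts AcAc
to deuterated BHB, so a single measured six-channel MID encodes both
ketones: channel `2j` is BHB labeling weighted by `(1 − p)`, channel
`2j+1` is AcAc labeling weighted by `p`, where `p` is the AcAc fraction
of the total ketone signal. `p` carries pool-size information but is
independent of the steady-state fluxes.

## Estimation

Two routes operate on identical inputs:

* **Matrix method** — the six balances in matrix form `E·R = P`, one
  exact linear solve. The condition number is reported and a warning is
  emitted above 1e8; negative solutions are returned but tagged
  implausible, since the algebra is exact and infeasibility indicts the
  data.
* **Bounded regression** — weighted least squares over the free vector
  (`ra_acac`, `ra_bhb`, `ri_acac`, `ri_bhb`, `rinf_acac`, `rinf_bhb`,
  `p`), with both disposals reconstructed from the node balances so
  mass balance holds exactly rather than being penalized. Residuals are
  the six MID fractions weighted by `mid_sigma` (default 0.003 mol
  fraction, typical LC-MS/MS MID precision) and the two infusion rates
  weighted by `rinf_sigma_rel` (default 0.02, pump calibration scale);
  these weights are design choices exposed in `FitConfig`, since the
  measurement error model is rarely published. Fluxes are bounded below
  at 0. The solver is scipy's trust-region-reflective least squares
  with 20 multistarts (one start from the exact matrix solution, the
  rest log-uniform over 0.1–50× the total infusion rate, seeded). A
  disposal flux pushed below the bound is handled by clipping plus a
  linear penalty residual (weight 1e3 per µmol/h), which keeps the
  objective continuous; solver runs that exhaust the evaluation budget
  at that kink are kept as candidates because the objective is already
  at its floor there.

**Degrees of freedom.** The design supplies 6 MID fractions under one
normalization constraint plus 2 rate measurements = 7 independent
measurements, against 4 free net fluxes + 2 infusion fluxes + 1 pool
ratio = 7 parameters: DOF = 0. The dual-tracer design is exactly
determined — on consistent data the regression reproduces the matrix
solution to the optimizer tolerance and the SSR is numerical noise.

**Confidence intervals** are profile-likelihood intervals: the target
flux is stepped away from its optimum geometrically (initial step 2% of
its scale, growth ×1.8), re-optimizing all other parameters with warm
starts, until the SSR exceeds the optimum by χ²(0.95, 1) = 3.841; the
crossing is refined by bisection to a relative tolerance of 1e-3.
Profiling a disposal flux re-parameterizes the matching appearance flux
through the node balance. Intervals are truncated at the flux lower
bound; a side that never crosses within 60 steps is reported at the
search limit and flagged open.

**Precision score.** Each flux's CI is summarized as
`r = min(u/|v|, v/|v|+1) − max(l/|v|, v/|v|−1)`, `S = exp(−r/3)`;
`S ∈ (0, 1]`, with 1 for a zero-width interval and exp(−2/3) ≈ 0.513 as
the floor for a non-negative flux whose interval spans [0, ≥2v].

**Inconsistency detection.** With DOF = 0 a χ² goodness-of-fit test is
unavailable, so the verdict uses an SSR floor (default 1e-3, i.e. any
misfit beyond numerical noise) plus a ranking of measurements by
absolute weighted residual. Detection has a structural limit: a
corrupted data set is flagged only if its exact solution is infeasible
(some flux negative), because any feasible exact solution can be
interpolated by the bounded fit. An undetected 25% AcAc tracer loss is
detectable in interconversion-dominated regimes, where disposal
estimates are hypersensitive to rate errors; a zeroed-and-renormalized
M+5 channel is *never* detectable at zero noise — it is observationally
equivalent to a consistent experiment with `ri_bhb = 0` (one can show
the implied exact solution is always feasible: a receiving pool can
never be relatively more M+2-enriched than its source). Such boundary
solutions are surfaced separately in the residual report
(`boundary_fluxes`), since an interconversion flux of exactly zero is
physiologically suspect.

## Infusion-rate sensitivity

The exact solution is linear in the rate vector, so a relative error ε
in one pump rate moves every flux along an exact straight line
(`sensitivity_scan` verifies the linear-fit residual at machine level
and reports slope/intercept per flux, with sign-change flags). The
default grid is ε ∈ ±0.25 in steps of 0.05, a realistic pump/infusate
error range. Correcting nominal rates by measured/theoretical infusate
concentration (`adjust_infusion_rate`) addresses the dominant real
source of such errors, loss of AcAc during infusate neutralization.

## Synthetic data generator

`generate_experiment` simulates the steady-state combined MID from a
ground-truth flux state and protocol, then applies, in instrument
order: incomplete derivatization (odd-mass signal scaled by the
completeness, then renormalized — this rescales only the apparent pool
ratio, not the enrichments, so fluxes are unaffected), channel dropout,
optional forward natural-abundance convolution, additive truncated
Gaussian noise per fraction (clip at 0, renormalize), and reported
rates equal to nominal rates with relative pump noise. Undetected
tracer loss scales the *delivered* rate while the *reported* protocol
keeps the nominal rate. Everything is driven by one seeded generator.

The presets span physiological regimes with total endogenous Ra rising
~2.5-fold from fed to fasted, `ri_acac > ri_bhb` throughout, and
`ra_bhb/ra_acac < 1`; infusion rates are fixed at the dual-tracer
protocol values (1.91 and 2.08 µmol/h), giving plasma enrichments of
roughly 3–12%:

| preset | ra (A, B) | ri (A, B) | p (AcAc) | regime |
| --- | --- | --- | --- | --- |
| fed | 12, 6 | 16, 12 | 0.45 | low turnover |
| fasted_14wk | 30, 15 | 100, 90 | 0.30 | exchange-dominated (reference) |
| fasted_20wk | 32, 14 | 55, 45 | 0.25 | high turnover |
| obese_fasted | 28, 13 | 40, 32 | 0.35 | moderate exchange |

All values are synthetic order-of-magnitude choices, not measured data.
The reference preset is deliberately exchange-dominated: that is the
regime in which disposal fluxes respond to infusion-rate error by an
order of magnitude and can cross zero within ±25%, which is what makes
corrupted data detectable at all (see above). Conversely it amplifies
MID noise, so the parameter-recovery and CI-coverage studies use the
moderate-exchange `obese_fasted` preset, where the matrix estimator's
median bias at `mid_sigma = 0.003` is within a few percent. Recovery is
assessed over 200 replicates — enough that the Monte-Carlo error of a
median is a few percent while the full study (fit + profile interval
per replicate) completes in minutes on one CPU.

**What the generator does not emulate:** pseudoketogenesis (exchange of
circulating AcAc with tissue acetoacetyl-CoA), acetone formation,
tissue compartments, non-steady-state kinetics, and correlated or
intensity-dependent MS noise. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to these real-world departures.

## Numerical choices and edge cases

* Natural-abundance correction inverts the lower-triangular
  convolution matrix of the configured ion formula (default: the C₄
  skeleton at 1.07% ¹³C; the full m/z 87 product-ion or m/z 105
  precursor formulas are available — H/O contribute at the 1e-4 level).
  Tracer carbons and the derivatization deuterium are excluded from the
  correction. Negative corrected fractions are clipped to 0 and the
  vector renormalized; clips above 0.005 warn, as they indicate a
  distorted envelope rather than noise.
* Decoding requires signal on both parities; an all-even or all-odd
  MID raises a descriptive error (the corresponding ketone pool is
  undetectable).
* An all-zero enrichment set makes the matrix singular and raises,
  naming the enrichments.
* MIDs must be non-negative and normalized to 1e-9; `normalize` is the
  single entry point for renormalization and rejects all-zero vectors.
* Determinism: identical data, protocol, `FitConfig` (including seed)
  reproduce bit-identical results.

## Known limitations

* Individual `ra_acac`/`ra_bhb` are identifiable only under the model's
  assumption of no intrahepatic tracer mixing; their sum is the robust
  total-ketogenesis quantity.
* Profile intervals for interconversion fluxes are wide by design
  (DOF = 0); their precision scores sit near the floor in most regimes.
* The inconsistency verdict cannot flag corruptions whose exact
  solution remains feasible (see above) — with a zero-DOF design this
  is a property of the experiment, not of the implementation.
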