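# ketoflux

Estimation of in vivo ketone-body turnover from dual-tracer stable-isotope
infusions.

## The problem

The two circulating ketone bodies, acetoacetate (AcAc) and
β-hydroxybutyrate (BHB), are produced by the liver and consumed by
peripheral tissues while interconverting rapidly — too rapidly to treat
the pools as independent, too slowly to treat them as one. Quantifying
ketogenesis therefore requires two distinguishable tracers (here
[U-¹³C₄]BHB and [3,4-¹³C₂]AcAc infused together) and a **two-pool model**
with six steady-state fluxes: rates of appearance (*Ra*), disposal
(*Rd*) and interconversion (*Ri*) for each ketone.

Because AcAc is chemically labile, blood samples are treated with
NaB²H₄, which reduces AcAc to a deuterium-tagged BHB (+1 mass). A single
measured BHB isotopologue envelope M+0 … M+5 then encodes both analytes:
**even** mass shifts are plasma BHB, **odd** mass shifts are plasma
AcAc, and the odd/even split encodes the AcAc share of the total ketone
pool.

## What the package computes

Given the combined six-channel mass-isotopomer distribution (MID) and
the two infusion rates (µmol/h), `ketoflux` provides two estimation
routes plus diagnostics:

1. **Exact matrix method.** At steady state the system obeys six linear
   mass balances, e.g. total AcAc
   `Rinf_AcAc + Ra_AcAc + Ri_BHB = Rd_AcAc + Ri_AcAc` and per-tracer
   balances such as `Rinf_AcAc + B·Ri_BHB = A·(Rd_AcAc + Ri_AcAc)`,
   where *A*, *B*, *C*, *D* are the M+2/M+4 enrichments of AcAc and
   BHB. In matrix form `E·R = P`, solved exactly as `R = E⁻¹P`
   (`solve_two_pool`). Exact, but it propagates any data error silently
   — including into physiologically impossible negative fluxes.
2. **Bounded regression (`KetoneFluxModel`).** The same network,
   written with explicit atom transitions (including the sample-prep
   deuterium), is regressed against all six MID fractions and both
   infusion rates in a weighted least-squares sense with fluxes bounded
   at zero. `fit()` returns a results object with profile-likelihood
   confidence intervals, a precision score per flux
   (`S = exp(−r/3)` of the normalized CI range `r`), and a residual
   report that flags data inconsistencies and ranks the offending
   measurements.

Supporting modules cover natural-abundance correction and odd/even MID
decoding, propagation of infusion-rate errors (every flux responds
exactly linearly — some cross zero within a realistic ±25% pump error),
single- vs dual-tracer comparison, and a synthetic-data generator with
known ground truth, including the practically relevant failure modes
(undetected AcAc tracer loss, incomplete derivatization, lost
isotopologue channels).

## Worked example

```python
import ketoflux as kf

# one synthetic fasted-obese mouse: truth Ra = (28, 13) µmol/h,
# Ri = (40, 32), AcAc pool fraction 0.35, MID noise σ = 0.003
exp = kf.generate_experiment(
    kf.get_preset("obese_fasted"),
    kf.NoiseConfig(mid_sigma=0.003, rinf_sigma_rel=0.02, seed=11),
)
model = kf.KetoneFluxModel(exp.measured_mid, exp.reported_protocol,
                           kf.FitConfig(multistart=5, seed=1))
print(model.fit().summary(with_ci=True))
```

```
Two-pool ketone flux regression
==============================================
SSR   1.3408e-28    dof 0    pool ratio (AcAc) 0.350
----------------------------------------------
flux          estimate        lb        ub   score
ra_acac         38.449    21.813    49.435   0.787
ra_bhb           2.723     0.000    18.089   0.513
ri_acac         55.814    27.743   139.266   0.606
ri_bhb          33.462     8.712   128.127   0.560
rd_acac         18.028     1.733    48.329   0.530
rd_bhb          27.153     4.801    39.354   0.654
rinf_acac        1.932
rinf_bhb         2.078
----------------------------------------------
data verdict: consistent
```

The design has zero degrees of freedom, so a consistent data set is
fitted to numerical precision (SSR ≈ 0) and all information about
uncertainty lives in the profile-likelihood intervals: this noisy draw
lands at Ra AcAc = 38.4 µmol/h, but its 95% interval [21.8, 49.4]
contains the true 28, and every other interval contains its truth as
well. Precision scores near 1 mean tight intervals; a score of
exp(−2/3) ≈ 0.513 is the floor for a non-negative flux whose interval
reaches 0 — interconversion fluxes are intrinsically the least precise
quantities in this design. A corrupted data set (for example an
undetected 25% loss of AcAc tracer in the infusate) drives the verdict
to `inconsistent`, with the AcAc-derived odd-mass channels carrying the
largest residuals.

The same pipeline is available from the shell:

```sh
ketoflux simulate --preset fasted_14wk --n 20 --seed 7 --out samples.csv
ketoflux fit samples.csv --out reports
ketoflux sensitivity --which acac --range 0.25
ketoflux decode samples.csv
```

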