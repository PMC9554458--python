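# Methods

This note records the scientific and numerical decisions behind
`gentapbpk`: the model and its assumptions, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
known limits of what these simulations reproduce.

## Model structure and assumptions

Gentamicin is hydrophilic (logP ≈ −3.1), distributes essentially in
extracellular water, binds plasma proteins weakly (<10%) and penetrates
cells poorly; ~90% is cleared renally by glomerular filtration, with
~21% of the filtered drug reabsorbed in the tubule and negligible
secretion. A minimal PBPK structure is therefore adequate: a blood pool
of volume Vd, a kidney and a lumped rest-of-tissues compartment, both
flow-limited (tissue and emergent venous concentration at partition
equilibrium, `C_tissue/P`), and a heart chamber that only mixes cardiac
output (no exchange or elimination). Elimination is a flow
`Qe = TBW × GFR × (1 − f_reab)` applied to the kidney emergent
concentration, so whole-body clearance at quasi-steady state is the
flow-limited extraction `Qe·Qk/(Qk + Qe)` — 1.612 mL/min for the
reference preterm subject versus the nominal `Qe` of 1.790 mL/min
(0.107 L/h, the value quoted as "predicted clearance").

Kinetics are linear: profiles scale with dose and superpose across
doses. Both properties are enforced by tests and exploited for dose
normalization of observations.

### The blood equation and the `as_printed` mode

A published formulation of this model writes the blood balance without
the blood-to-tissue outflow term `−(Qk + Qr)·Cb`. Because the tissue
flows (9.35 + 217 mL/min/kg) exceed cardiac output (172 mL/min/kg), that
equation has net positive feedback: the system matrix acquires a
positive eigenvalue and concentrations grow without bound (doubling time
of a couple of minutes once the tissues charge). The package's default
`mass_conserving` mode restores the outflow term, which is what any
automatic blood-connection generator must do for the model to conserve
drug amount; total amount (blood + heart + tissues + eliminated) then
matches the administered amount to better than 1e-6 relative at all
output times (in practice ~1e-12 with the exact propagator). The
`as_printed` mode is retained for fidelity audits: the simulator detects
the unstable eigenvalue and raises `ModelDivergenceError` rather than
return unbounded values; `on_divergence="warn"` forces integration for
demonstration purposes.

### Tissue-volume constants: literal millilitres, not fractions

The reference tissue constants are printed as "organ volumes (ml) 0.03 /
0.87". Two readings are possible and the package exposes both
(`volume_units`):

* `"mL"` (default) — literal absolute volumes. Tissue capacity is then
  negligible (≤1 mL) and the tissues act as flow-through exchange sites;
  whole-body kinetics collapse onto the blood pool Vd with flow-limited
  renal extraction (effective volume ≈ 0.52 L/kg preterm, terminal
  half-life ≈ 6.5 h).
* `"L/kg"` — fractional volumes scaled by body weight. This adds
  `Vk·Pk + Vr·Pr ≈ 1.17 L/kg` of equilibrium capacity on top of Vd,
  tripling the apparent distribution volume to ≈1.69 L/kg.

The literal reading is the default because it is the one consistent with
neonatal gentamicin pharmacology and with the reported simulation
outputs. Vd ≈ 0.5 L/kg *is* the total (extracellular) distribution
volume of gentamicin in neonates; stacking a further 0.87 L/kg of
equilibrating "rest of tissues" on top double-counts distribution. Under
the fractional reading a 6 mg/kg dose peaks at ≈3.6 mg/L, which would
make the Cmax/MIC ≥ 8 target unattainable at MIC 1 mg/L for every
regimen (PTA = 0%) and is grossly inconsistent with measured 2-h levels
of 14–18 mg/L at these doses; under the literal reading the extended
regimens attain the peak target in essentially all virtual subjects, as
reported. The fractional reading remains available for sensitivity
analyses, and the mass-balance and property tests cover both.

The heart-chamber volume Vh is not specified anywhere; the default is
0.01 L/kg. The heart loop neither stores nor eliminates drug
selectively, but Vh adds ~2% to the effective volume: halving or
doubling it moves blood concentrations by <5% across the sampled 0.5–24 h
window (the terminal-slope drift compounds to ~8% by 48 h). Flows need
not sum to cardiac output in this blood-pool formulation; an optional
renormalization `Qr' = CO − Qk` is provided but off by default.

## Numerical solution

The model is linear and time-invariant with piecewise-constant infusion
forcing, so the default engine propagates the exact solution segment by
segment with matrix exponentials of the augmented 6×6 system (state plus
constant input). This is exact to machine precision, conserves mass to
~1e-12, and is immune to the extreme stiffness introduced by the
literal-mL tissue volumes (compartment time constants of ~1 s next to a
6.5 h half-life). `scipy.integrate.solve_ivp` with Radau/LSODA/BDF at
rtol 1e-8 / atol 1e-10 is kept as an independent cross-check engine,
integrated per dosing segment so the infusion edges are never smeared;
the two engines agree to ~1e-9 mg/L on the reference problem. The output
grid always contains the exact start and end of every infusion.

Initial conditions are drug-naïve (all compartments zero), first dose at
t = 0. PK indices are evaluated over the first dosing interval by
default; accumulation is negligible at q24–48 h intervals given the
~6.5 h half-life (the evaluation window start is configurable). Cmax is
the profile maximum over the window, which for this model occurs at the
end of the infusion; T>MIC uses linear interpolation at threshold
crossings. Degenerate inputs are handled explicitly: MIC ≤ 0 defines
T>MIC as 100% (logged), zero dose yields the zero profile.

## Virtual populations

Between-subject variability is log-normal and moment-matched:
`sigma² = ln(1 + CV²)`, `mu = ln(mean) − sigma²/2`, so the arithmetic
mean and CV of each sampled parameter equal their targets (CV 20% for
TBW and Qk, 24% for CO, 40% for GFR). Parameters are sampled
independently — reported correlations between these physiological
quantities are not modelled, consistent with the per-kg parameterization
that already absorbs most size-related correlation. Dose in mg is
computed from each subject's sampled weight, so per-kg dosing cancels
TBW almost exactly in the concentration scale.

Vd is fixed at its subpopulation mean by default. Only TBW, Qk, CO and
GFR carry stated CVs; sampling Vd with the CV implied by its reported SD
(≈0.31) is available (`vd_policy="sampled"`) but flattens the extreme
PTA values (near-100% / near-0%) that the fixed policy reproduces, which
is why fixed is the default. Sampling is subject-major from a single
seeded generator with a documented column order (TBW, CO, GFR, Qk, Vd),
making cohorts bit-reproducible across platforms.

## Dosing evaluation

PTA at a given MIC is the percentage of virtual subjects attaining a
criterion: efficacy Cmax/MIC ≥ 8 and T>MIC ≥ 60% of the interval;
toxicity Cmin ≥ 2 mg/L and Cmax ≥ 25 mg/L. A regimen is classified
effective when PTA ≥ 90% for the efficacy criteria and safe when
PTA ≤ 10% for the toxicity criteria (all comparisons inclusive). The MIC
grid for breakpoint curves is 0.05–2.0 mg/L in 0.05 steps (no MIC above
the 2 mg/L clinical breakpoint is evaluated), with 1 mg/L as the
reference MIC. The MIC breakpoint is the largest grid MIC with
PTA ≥ 90%; PTA is mathematically non-increasing in MIC on a fixed
cohort, and a non-monotone curve (possible only across different
cohorts) triggers a warning and uses the last down-crossing.

## Validation metrics and predictive check

Prediction error is `(PRED − OBS)/OBS × 100`; MPE is its mean. AFE
(geometric bias) and AAFE (geometric precision) are `10^mean(log10 r)`
and `10^mean(|log10 r|)` of the fold ratio `r = PRED/OBS`, with the
conventional 0.5–2-fold adequacy band. Identities (swap antisymmetry of
AFE, invariance of AAFE, `AAFE ≥ max(AFE, 1/AFE)`) are property-tested.
MPE can be computed on raw or dose-normalized pairs; raw is the default.

The predictive check simulates ≥100 (by default 1000) virtual subjects,
takes empirical percentiles (10/25/50/75/90, linear interpolation
between order statistics) of the simulated concentrations at the nominal
sampling times (2 h and 24 h — no continuous-time binning is needed for
this design), and shades 50% (25th–75th) and 90% (5th–95th) prediction
intervals. Observations are dose-normalized to the standard 6 mg/kg dose
(valid under linearity), and coverage is the fraction falling inside the
90% interval; drawing observations from the model itself yields coverage
statistically indistinguishable from 0.90, which is the self-consistency
test.

## Population estimation (ITS)

Only GFR is estimated; every other physiological parameter is fixed at
its subpopulation value and each subject's weight is taken from the
data. Between-subject variability is log-normal
(`GFR_i = typical·e^{η_i}`, `η ~ N(0, ω²)`); the residual model is
proportional with SD σ — the natural choice for an immunoassay whose
precision scales with the measured level — and the full likelihood
(including the `ln(σ·f)` normalization term) is used. Each iteration
runs a bounded scalar MAP optimization per subject (posterior mode plus
curvature-based variance from a central second difference), then updates
the population: the typical value moves by the mean η, ω² is
re-estimated as `mean(η_i² + var_i)` — the curvature term corrects
shrinkage bias — and σ² from pooled proportional residuals (floored at
1e-4 so noise-free data converge cleanly). Convergence requires the
relative change of all three population parameters below 1e-3
(dimensionless spread parameters are judged against a 0.01 floor so a
collapsing variance can converge). Below-LLOQ observations are excluded
and counted; a subject with no usable observations falls back to the
prior mode, flagged, and is excluded from the population update. With
one subject ω is not estimable and stays fixed, flagged. The procedure
is deterministic given the dataset, invariant to subject order (to
optimizer tolerance) and to concentration unit rescaling.

## Synthetic TDM generator

The generator defines the study conditions used throughout testing: two
subgroups (31 preterm, 16 term); demographics from truncated normals
matching the published mean ± SD within the printed min–max (GA
33.7 ± 1.56 in 32–37 weeks and 38.9 ± 0.25 in 38–39; PNA 3.03 ± 1.02 and
2.94 ± 0.85 days; TBW 1.96 ± 0.41 in 1.16–3.00 kg and 3.09 ± 0.23 in
2.29–3.62 kg — no distributional form is published, and truncation
shifts the preterm TBW mean by ~+0.02 kg relative to the printed value);
6 mg/kg doses over 0.5 h (a "realistic" policy samples the published
per-kg dose spread instead; the term dose range is printed with min and
max transposed and is used as 6.21–6.99); samples at 2 h and 24 h;
10% proportional assay error (assay precision is unreported; 10% is a
standard figure for fluorescence polarization immunoassays and is
configurable); censoring below the 0.3 mg/L quantification limit; and 3
samples missing at random, matching the 91-of-94 sample count of the
original design. Physiological parameters are drawn from the same
log-normal population model, with TBW taken from the demographic model
rather than sampled twice. The full generating truth is emitted as a
JSON sidecar for recovery experiments.

What the generator does **not** emulate: real assay error structure
(additive floor near the LLOQ), correlated physiology, GA/PNA maturation
within a subgroup (covariates are drawn but do not drive the
parameters), non-random missingness, or the actual 47 patients' values.
Passing recovery and validation tests therefore demonstrates internal
consistency of the estimator and metrics under the declared design, not
performance on real TDM data.

About 10% of preterm 24-h samples fall below the LLOQ (high-GFR
subjects), which removes the most informative sample of exactly those
subjects and biases the recovered population GFR mean slightly downward
— visible (a few percent) but well inside the 10% recovery tolerance at
n = 31.

## Problem sizes

Default study sizes are the package's own choices: 1000 virtual subjects
per cohort for PTA and predictive checks (the published precedent for
prediction intervals; the Monte Carlo SE of a PTA near 90% is then
~1 point), 31-subject preterm cohorts for recovery experiments, 10⁴
draws where a sampling distribution is compared against a closed form.
The exact propagator makes these sizes cheap (a 1000-subject, 48-h
cohort simulates in ~1 s).

## What is and is not reproduced

With the defaults above, the pipeline reproduces the qualitative and
most of the quantitative published pattern: extended-interval regimens
attain Cmax/MIC ≥ 8 in ≈100% of subjects (reported 99.9% preterm /
99.8% term), the preterm conventional regimen fails that target, every
toxicity PTA stays at or below the 10% safety threshold, conventional
T>MIC values match within a few points (≈86 vs 87.9 preterm, ≈57 vs
61.2 term), and preterm conventional trough toxicity matches (≈6 vs
5.0%).

Several printed values are not reproducible from the specified model
under any parameterization exposed here, and the package reports its own
computed values rather than targeting them:

* **Conventional-regimen Cmax/MIC PTA (10.8% preterm / 32.3% term).**
  With Vd fixed and per-kg dosing, the deterministic peak is 7.4 mg/L
  (preterm) / 8.4 mg/L (term) with a Cmax CV of only ~1–3%, so attainment
  at MIC 1 is ~0% / ~95%, not 10.8% / 32.3%. The printed
  conventional-vs-extended pairs jointly imply a Cmax log-SD of
  0.09–0.12, which no stated variability source produces (TBW cancels;
  GFR and Qk barely touch the peak; sampling Vd overshoots to ~0.31 and
  destroys the extreme extended-interval values).
* **Extended-interval T>MIC PTA (70.7% preterm / 54.9% term).** The
  model's ≈6.5 h half-life puts the median preterm subject above
  1 mg/L for ~48% of a 48 h interval, giving PTA ≈33%; the conventional
  T>MIC entries, by contrast, match well.
* **Mean predicted concentrations (17.4 / 2.62 / 15.4 / 0.89 mg/L) and
  the term predicted clearance 0.23 L/h.** A population simulation of
  this model cannot exceed the hard ceiling `dose/Vd` (11.5 mg/L
  preterm, 13.0 mg/L term at 6 mg/kg), which the printed 2-h means
  violate; they are consistent with individual a-posteriori (MAP
  Bayesian) predictions conditioned on each patient's measurements,
  which require the clinical records. The term clearance likewise does
  not follow from the stated term covariate means (which give
  0.29 L/h). These quantities are demonstrated out of range by a test
  and excluded from reproduction targets.

## Limitations

Single linearly-eliminated drug; no saturable kinetics, no tissue
accumulation model for nephro-/ototoxicity, no bacterial dynamics or MIC
distributions (a single reference MIC or grid); discrete subpopulation
presets rather than continuous maturation functions; ITS (not
FOCE/Laplacian) population estimation with a single estimable parameter;
no covariate model selection; validation data are synthetic stand-ins by
design.
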