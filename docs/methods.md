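# Methods

## Scope and model structure

`renalpbpk` simulates the renal disposition of ganciclovir (dosed IV, or
orally as the prodrug valganciclovir) with a whole-body physiologically
based pharmacokinetic (PBPK) model whose kidney is resolved into a
mechanistic nephron. The question the model answers is local, not systemic:
how concentrated does the drug become in the tubular filtrate — in
particular in the medullary collecting duct (MCD), the last and most
water-extracted segment — and when does that concentration cross the
drug's aqueous solubility window (2600–6000 mg/L), the condition for
crystalluria.

The body is a minimal perfusion-limited set: blood (plasma-equivalent
central pool), liver, muscle, adipose and rest-of-body, each exchanging at
its blood flow with a tissue:plasma partition coefficient Kp. Hepatic
elimination is one whole-liver intrinsic clearance acting on unbound liver
concentration; it is not attributed to any enzyme. The kidney block is
permeability-limited:

* **Filtration.** Unbound drug leaves arterial plasma into the first
  proximal-tubule lumen at fu·GFR.
* **Secretion.** A lumped basolateral uptake transporter (called "OAT1";
  individual OAT isoforms are not separated) moves unbound drug from kidney
  tissue into a proximal-tubule cell pool; apical MATE efflux passes it on
  into the proximal luminal segments, split 0.10/0.50/0.40 over PT1/PT2/PT3
  (organic-anion secretion is weighted to the S2/S3 segments). Whole-kidney
  clearances scale as
  `CLint × abundance × activity × PTCPGK × kidney weight`, with PTCPGK the
  proximal-tubule cellularity per gram kidney. Because efflux capacity far
  exceeds uptake, the cell pool is a pass-through and uptake is the
  rate-determining step; the MATE CLint is deliberately insensitive.
* **Luminal chain.** Seven segments (PT1, PT2, PT3, loop of Henle, distal
  tubule, cortical and medullary collecting duct) each receive the upstream
  exit flow and concentration. Water is reabsorbed (exit flows fall from
  GFR down to the urine flow) while the drug — poorly permeant, with
  negligible tubular reabsorption — is carried along, so its concentration
  rises roughly as GFR/urine-flow by the terminal segment. MCD outflow
  accumulates into urine.

Passive transcellular permeability is a parameter but is zero for
ganciclovir. There is no pH dependence: the solubility window is treated
as flat across urinary pH.

## Numerics

Every process is first order, so between dose events the state obeys a
linear time-invariant system `dx/dt = A x (+ b)` with 17 states. The
integrator propagates the exact solution using a cached matrix exponential
on a uniform 0.05 h grid; oral doses are impulses into the absorption
depot, IV infusions use the standard augmented-matrix discretisation. No
solver tolerance enters the result, mass balance closes to ≤1e-4 of dose
by construction (and is asserted on every run), and a 21-day twice-daily
regimen costs the same per step as a single dose — which is what makes
200-subject virtual trials cheap. An adaptive stiff (BDF) integration of
the same system matrix is kept in the test-suite as an independent check;
the two agree to ~1e-8 relative.

Segment and plasma maxima are tracked per dosing window at full grid
resolution; long simulations decimate only the *stored* series (0.25 h).
Noncompartmental analysis uses trapezoidal AUC on the stored grid and a
terminal log-linear regression (last five points at 0.5 h spacing,
r² ≥ 0.95 required); when no clean terminal phase exists, extrapolated
quantities are reported as NaN rather than guessed.

Exact zeroth-order moments (`disposition_moments`) solve `A X = −x0` on
the non-absorbing states, giving AUC, cumulative urinary and metabolic
amounts, CL, CL_R and fe without time stepping. The elimination
calibration uses these.

A closed-form steady-state oracle for the luminal chain
(`steady_state_luminal_oracle`) is implemented independently of the ODE
path and is used to validate it: at constant input the ODE steady state
matches the chain solution to 0.1%.

## Drug parameters and calibration

Internal units are mg, L, h. The shipped ganciclovir config uses
fu 0.98, B:P 1.03, first-order ka 2.2 h⁻¹ with systemic availability 0.60
for the oral prodrug route (complete presystemic hydrolysis; oral input =
dose × 255.23/354.36 × 0.60), and Kp values (liver 0.80, kidney 1.50,
muscle 0.78, adipose 0.12, rest 0.65) that place the terminal half-life at
2.8 h and Vz at ≈50 L (0.62 L/kg) in the reference subject — inside the
drug's reported clinical range. The absorption rate constant is fast on
purpose: it reproduces the early simulated Tmax (~0.7 h) characteristic of
this model family, and peak MCD concentration is sensitive to it.

The elimination split is not transcribed but *calibrated*
(`calibrate_elimination`): given the target fraction excreted unchanged in
urine (fe = 0.88) and a target total plasma clearance (12.5 L/h) in the
reference subject (healthy male, 30 y, 81 kg, GFR 114 mL/min), nested
bounded root-finding on (CLint,OAT1, CLint,met) drives the moment-based fe
and CL to their targets (|Δfe| ≤ 0.005, |ΔCL/CL| ≤ 2%). Filtration sets a
floor: if fu·GFR already exceeds fe × CL the request is infeasible and the
calibration says so. The YAML ships the calibrated values
(CLint,OAT1 = 3.71 µL/min/10⁶ cells, CLint,met = 1.56 L/h); re-running the
calibration reproduces them (idempotent to <0.1%).

## Virtual populations

Sampling is per-subject from distribution tables: log-normal for positive
physiological quantities (GFR, body weight, PTCPGK, transporter
abundances, kidney-weight and cardiac-output noise), truncated normal for
height, albumin and haematocrit, uniform age within the population's age
range. Covariates: BSA by Du Bois; cardiac output 14.4·BW^0.75 L/h; kidney
weight 4.3 g/kg body weight; serum creatinine is a descriptive inverse of
GFR and drives no kinetics. Renal and cardiac ageing decline linearly
beyond age 40 (−1.125 %/y for GFR, −0.475 %/y for cardiac output),
calibrated so the geriatric (65–95 y) medians fall ≈45% (GFR) and ≈19%
(cardiac output) below the healthy 18–65 y medians, with no age effect on
cellularity, transporter abundance, kidney weight or urine flow.

Log-normals are parameterized with the table value as the **median**
(typical subject). This is a deliberate choice: it keeps the
population-median clearance equal to the calibrated reference clearance,
which a mean parameterization would undercut by ~8% at a 60% CV.

CKD severity is defined on the BSA-normalised GFR scale and de-normalised
per subject: healthy >90, moderate 30–60, severe 15–30 mL/min/1.73 m².
The severe population centres at 19.6 mL/min/1.73 m² (absolute median
≈21 mL/min), with reduced albumin (36.7), haematocrit (0.33) and kidney
mass (×0.75). Five disease hypotheses for tubular secretion are applied as
multiplicative scenario factors after sampling (so matched seeds share all
random draws): no change; PTCPGK ×0.35/×0.17 (moderate/severe); OAT1
abundance ×0.35/×0.17; OAT1+MATE ×0.35/×0.17; PTCPGK ×0.35/×0.17 plus a
uremic-solute OAT1 activity factor 0.73/0.41. The cellularity-loss and
abundance-loss variants have identical PTCPGK×OAT1 products and therefore
identical whole-kidney secretion — a structural identity the tests assert.

Population diagnostics summarise medians and 5th–95th percentiles,
Spearman correlations (zero-variance columns marked undefined), and flag
contiguous empty bands in the pooled BSA-normalised GFR histogram — the
signature of stitching discrete severity classes together rather than
sampling a continuous disease axis.

## Flow modes and the urine-flow scenarios

Two nephron-flow modes exist. In `scaled` mode (default at normal urine
flow) each subject's filtrate flows are proportional to their own GFR,
with the terminal urine flow held at the scenario value — urine production
is preserved in CKD, so at low GFR the distal exit flows are floored at
the urine flow rather than letting water reabsorption go negative. In
`fixed` mode one common profile (GFR 120 mL/min unless overridden) applies
to every subject, including the filtration term — the configuration in
which altered-urine-flow simulations carry no inter-individual
filtrate-flow variability. `fixed` engages automatically
whenever the urine flow deviates from 1 mL/min. The Fig-8C-style preset
(`severe_ckd_gfr50_preset`) is fixed-flows with GFR 48 mL/min (40% of the
common profile) and tubular secretion scaled to 0.4 — the deepest
impairment the altered-urine-flow machinery supports.

Because the drug is impermeant and the MCD residence time is short
(volume 1.2 mL), the median MCD Cmax scales essentially as 1/urine-flow:
0.5 and 0.1 mL/min give 2× and 10× the 1 mL/min value to within 5%.

Luminal volumes (PT1..MCD: 6/6/4/4/2/1.5/1.2 mL) are small enough that
residence is flow-dominated; doubling them moves the single-dose MCD Cmax
by <5% (asserted in tests).

## Synthetic observed data

No clinical data ship with the package. `generate_observed` emulates the
structure of sparse regulatory PK datasets: simulate true profiles for
sampled subjects, sample at protocol times, apply multiplicative
log-normal residual error (default proportional SD 0.2), censor below the
assay LLOQ (default 0.05 mg/L), and emit cumulative urinary excretion
totals; records follow the ID/TIME/DV/AMT/EVID column convention.
`recover_parameters` is the matching reverse-translation: pooled
least-squares on log concentrations (plus urine totals, which anchor the
renal/hepatic split) for the two elimination CLints, reported against the
hidden truth. What passing these tests shows is that the estimation
machinery is consistent with the generator; it does not validate the model
against real patients — real data carry between-study heterogeneity,
covariate error in renal-function markers, and model misspecification that
the generator deliberately omits.

## Performance metrics and risk reporting

AFE = 10^mean(log₁₀ P/O), GMFE = 10^mean(|log₁₀ P/O|), RMSE in input
units; base-10 throughout. The validation gate applies a two-sided
bioequivalence bound (0.8–1.25) and caps the reported fold value at the
conventional twofold limit. Crystalluria is reported against both
solubility bounds: a median segment Cmax above 2600 mg/L flags risk,
above 6000 mg/L flags high risk; per-subject exceedance fractions and the
median margin against the upper bound are also reported.

## Problem sizes and determinism

Virtual trials default to 200 subjects per arm (1000 where distribution
medians are the quantity of interest, 100 for the single-dose regional
comparison); trial resampling uses sub-seeds derived from
(seed, trial index), so every number in a run is a pure function of the
seed. The acceptance script re-derives the elimination calibration and all
summary quantities from scratch at these sizes in about a minute.

## Known limitations

* The demographic covariate model is deliberately simple (allometry +
  linear ageing); it reproduces the reported population medians and
  percentile ranges, not any proprietary covariate machinery.
* The tissue set is minimal; Kp values are calibrated to clearance-volume
  behaviour, not measured compositions.
* Metabolism is a single unassigned hepatic clearance, assumed unchanged
  in CKD.
* Solubility is a fixed aqueous window; no supersaturation kinetics,
  nucleation or urine-matrix effects, so "risk" means concentration above
  solubility, not predicted stone formation.
* Within-subject variability (circadian urine flow, fluid intake cycles)
  is not modelled; urine flow is a per-scenario constant.
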