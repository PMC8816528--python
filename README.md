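# renalpbpk

Whole-body physiologically based pharmacokinetic (PBPK) simulation with a
mechanistic nephron-lumen kidney model, built to study the renal
disposition of ganciclovir (dosed IV or orally as valganciclovir) and its
crystalluria risk in chronic kidney disease (CKD), old age and low fluid
intake.

Antiviral crystal nephropathy happens because the nephron concentrates
filtrate ~100-fold between the glomerulus and the final urine: a drug that
is filtered and actively secreted but poorly reabsorbed rides along and
its luminal concentration rises as water is reclaimed, peaking in the
medullary collecting duct (MCD). When that peak exceeds the drug's aqueous
solubility (2600–6000 mg/L for ganciclovir), precipitation and tubular
injury become possible. Plasma concentrations alone cannot expose this
risk; a kidney model resolved into tubular segments can. The package is
aimed at PK modellers and clinical-pharmacology researchers who want an
open, scriptable implementation of this class of simulation.

## Model in brief

* Perfusion-limited whole-body distribution (blood, liver, muscle,
  adipose, rest) with a permeability-limited kidney: glomerular filtration
  of unbound drug (fu·GFR), lumped OAT1-mediated basolateral uptake into
  proximal-tubule cells scaled by cellularity (PTCPGK) and abundance,
  apical MATE efflux into the proximal lumen, and a seven-segment luminal
  chain (PT1→PT2→PT3→loop of Henle→distal tubule→cortical→medullary
  collecting duct) in which exit flows fall from GFR to the urine flow
  while the drug is carried through to urine. CL_R = Ae/AUC ≥ fu·GFR.
* Elimination split calibrated, not assumed: CLint,OAT1 and CLint,met are
  solved so the reference subject hits fe = 0.88 (fraction excreted
  unchanged in urine) and total CL = 12.5 L/h.
* Virtual populations — healthy (18–65 y), North-European-Caucasian
  (18–95 y), geriatric (65–95 y), moderate (GFR 30–60 mL/min/1.73 m²) and
  severe (15–30) CKD — plus five disease hypotheses for tubular secretion
  (intact-nephron-hypothesis loss of cellularity, of OAT1, of OAT1+MATE,
  cellularity loss plus uremic-solute OAT1 inhibition, or no change).
* Everything is first order, so the system is integrated exactly with
  matrix exponentials between dose events; 21-day twice-daily virtual
  trials with hundreds of subjects run in seconds. Seeded end to end.

See `docs/methods.md` for the full model description, parameter choices
and limitations.

## Worked example

Single 900 mg oral valganciclovir dose in the reference healthy subject
(30 y male, 81 kg, GFR 114 mL/min, urine flow 1 mL/min):

```python
import renalpbpk as rp

drug = rp.load_default_drug()
subject = rp.reference_subject()
flows = rp.build_flow_profile(subject.gfr, subject.urine_flow)
regimen = rp.DoseRegimen(route="oral", dose_amount=900.0)
result = rp.simulate_subject(subject, drug, regimen, flows, duration=48.0)
m = rp.nca(result, regimen)
print(f"Cmax      {m.cmax:7.2f} mg/L at t = {m.tmax:.2f} h")
print(f"AUC0-inf  {m.auc_0_inf:7.2f} mg*h/L")
print(f"CL        {m.cl:7.2f} L/h   CL_R {m.cl_r:6.2f} L/h")
print(f"t1/2      {m.t_half:7.2f} h     Ae(0-48h) {m.ae_cum:6.1f} mg")
print(f"MCD Cmax  {result.segment_cmax('MCD'):7.1f} mg/L")
print(f"MCD/PT1   {result.segment_cmax('MCD')/result.segment_cmax('PT1'):7.1f} fold")
```

prints

```
Cmax         6.17 mg/L at t = 0.70 h
AUC0-inf    31.09 mg*h/L
CL          12.51 L/h   CL_R  11.01 L/h
t1/2         2.84 h     Ae(0-48h)  342.3 mg
MCD Cmax   1130.8 mg/L
MCD/PT1     131.8 fold
```

Reading: plasma kinetics are unremarkable (88% of the absorbed dose ends
up unchanged in urine), but the collecting-duct lumen sees a peak more
than 130-fold above the proximal tubule and ~180-fold above plasma —
still below the 2600–6000 mg/L solubility window at normal urine flow.
Drop the urine flow to 0.1 mL/min under twice-daily dosing and the median
MCD peak rises ~10-fold, well above the window; that is the crystalluria
scenario the trial-level API (`run_trial`, `assess_crystalluria`)
quantifies across virtual populations.

The same pipeline is scriptable from the shell:

```
renalpbpk simulate --population healthy --dose 900 --n-subjects 100 \
    --seed 1 --out-dir out/healthy
renalpbpk risk --run-dir out/healthy
renalpbpk population --population ckd_severe --n-subjects 1000 --seed 1 \
    --out-dir out/pop
```

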