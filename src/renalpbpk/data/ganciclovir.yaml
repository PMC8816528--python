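# Ganciclovir drug parameters (oral route: valganciclovir prodrug, handled
# as complete presystemic hydrolysis).  Internal units: mg, L, h.
# clint_oat1 / clint_met defaults are the output of
# renalpbpk.drug_model.calibrate_elimination against the reference healthy
# subject (fe 0.88, total plasma clearance 12.5 L/h); re-running the
# calibration reproduces them.
molecular_weight: {value: 255.23, unit: g/mol}
prodrug_molecular_weight: {value: 354.36, unit: g/mol}
fu_plasma: 0.98
blood_plasma_ratio: 1.03
ka: {value: 2.2, unit: 1/h}
f_abs: 0.60
clint_met: {value: 1.5551, unit: L/h}
clint_oat1: {value: 3.7127, unit: uL/min/1e6cells}
clint_mate: {value: 40.0, unit: uL/min/1e6cells}
passive_perm_clearance: {value: 0.0, unit: L/h}
fe_target: 0.88
solubility_low: {value: 2600.0, unit: mg/L}
solubility_high: {value: 6000.0, unit: mg/L}
kp:
  liver: 0.80
  kidney: 1.50
  muscle: 0.78
  adipose: 0.12
  rest: 0.65
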