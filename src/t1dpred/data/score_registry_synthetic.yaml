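# Composite risk-score registry.
#
# Each entry is linear in transformed participant inputs:
#   score = intercept + sum(coef * transform(input))
# Transforms: identity, log (natural log), glucose_mgdl (mmol/l -> mg/dl).
# Glucose inputs are mmol/l, C-peptide ng/ml, HbA1c mmol/mol, age years.
#
# index60 carries the published coefficients from its primary source
# (fasting log C-peptide, 60-min glucose in mg/dl, 60-min C-peptide in
# ng/ml).  The remaining classical-score entries are SYNTHETIC placeholders
# with realistic sign structure, shipped so the pipeline runs end-to-end
# without the primary sources; replace them with published coefficient sets
# for real analyses.

index60:
  terms:
    - {input: cpeptide_0, transform: log, coef: 0.3695}
    - {input: glucose_60, transform: glucose_mgdl, coef: 0.0165}
    - {input: cpeptide_60, transform: identity, coef: -0.3644}

cpeptide30:  # synthetic; uses the fasting and 30-min samples only
  terms:
    - {input: glucose_30, transform: glucose_mgdl, coef: 0.016}
    - {input: cpeptide_0, transform: log, coef: 0.35}
    - {input: cpeptide_30, transform: identity, coef: -0.22}

beta2:  # synthetic; fasting draw only (one glucose, one C-peptide, HbA1c)
  terms:
    - {input: cpeptide_0, transform: log, coef: -0.8}
    - {input: glucose_0, transform: glucose_mgdl, coef: 0.02}
    - {input: hba1c, transform: identity, coef: 0.05}

dptrs:  # synthetic; full OGTT glucose/C-peptide sums plus age and BMI
  terms:
    - {input: glucose_30, transform: glucose_mgdl, coef: 0.0025}
    - {input: glucose_60, transform: glucose_mgdl, coef: 0.0025}
    - {input: glucose_90, transform: glucose_mgdl, coef: 0.0025}
    - {input: glucose_120, transform: glucose_mgdl, coef: 0.0025}
    - {input: cpeptide_30, transform: identity, coef: -0.09}
    - {input: cpeptide_60, transform: identity, coef: -0.09}
    - {input: cpeptide_90, transform: identity, coef: -0.09}
    - {input: cpeptide_120, transform: identity, coef: -0.09}
    - {input: age, transform: identity, coef: -0.025}
    - {input: bmi, transform: log, coef: 1.3}

dptrs60:  # synthetic; OGTT truncated at 60 min
  terms:
    - {input: glucose_30, transform: glucose_mgdl, coef: 0.004}
    - {input: glucose_60, transform: glucose_mgdl, coef: 0.004}
    - {input: cpeptide_30, transform: identity, coef: -0.13}
    - {input: cpeptide_60, transform: identity, coef: -0.13}
    - {input: age, transform: identity, coef: -0.025}
    - {input: bmi, transform: log, coef: 1.3}

m120:  # synthetic; anchored on the 120-min measurements
  terms:
    - {input: glucose_120, transform: glucose_mgdl, coef: 0.012}
    - {input: cpeptide_120, transform: identity, coef: -0.25}
    - {input: age, transform: log, coef: -0.35}

cph:  # synthetic stand-in for the published Cox-score formula (90-min OGTT)
  terms:
    - {input: glucose_90, transform: glucose_mgdl, coef: 0.010}
    - {input: cpeptide_90, transform: identity, coef: -0.20}
    - {input: age, transform: log, coef: -0.30}
    - {input: bmi, transform: identity, coef: 0.02}

lr:  # synthetic stand-in for the published likelihood-ratio score (90-min OGTT)
  terms:
    - {input: glucose_90, transform: glucose_mgdl, coef: 0.011}
    - {input: cpeptide_0, transform: log, coef: 0.30}
    - {input: cpeptide_90, transform: identity, coef: -0.22}
    - {input: age, transform: identity, coef: -0.02}
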