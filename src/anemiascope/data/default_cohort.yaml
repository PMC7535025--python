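# Default cohort specification: a rural Ethiopian lactating-women survey.
#
# Marginals are encoded as median/IQR summaries plus prevalence-threshold
# pairs (value v at cumulative probability p means a fraction p of women fall
# below v).  The loader turns these into quantile anchors; where an IQR anchor
# contradicts a prevalence threshold the threshold wins (see
# synthetic_cohort.build_anchors).  Correlation targets are Pearson r on the
# analysis scale: natural log for the right-skewed biomarkers, raw otherwise.

n: 150
altitude_m: 1700.0

marginals:
  hb:
    units: g/L
    log_scale: false
    median: 131.5
    iqr: [123.0, 139.0]
    thresholds:
      - {value: 110.0, p: 0.066}
      - {value: 120.0, p: 0.191}
  ferritin:
    units: ug/L
    log_scale: true
    median: 27.6
    iqr: [12.0, 56.0]
    thresholds:
      - {value: 150.0, p: 0.98}
  tfr:
    units: mg/L
    log_scale: true
    median: 3.5
    iqr: [2.0, 5.0]
    thresholds:
      - {value: 8.3, p: 0.92}
  plasma_iron:
    units: umol/L
    log_scale: true
    median: 14.7
    iqr: [11.0, 20.0]
  hepcidin:
    units: ug/L
    log_scale: true
    median: 7.2
    iqr: [4.0, 11.0]
  crp:
    units: mg/L
    log_scale: true
    median: 0.8
    iqr: [0.4, 1.9]
    thresholds:
      - {value: 5.0, p: 0.94}
  agp:
    units: g/L
    log_scale: true
    median: 0.7
    iqr: [0.5, 0.8]
    thresholds:
      - {value: 1.0, p: 0.87}
  zinc:
    units: umol/L
    log_scale: false
    median: 9.5
    iqr: [8.0, 11.0]
    thresholds:
      - {value: 10.7, p: 0.78}
  selenium:
    units: umol/L
    log_scale: false
    median: 3.0
    iqr: [2.6, 3.4]
    bounds: [2.0, 5.0]

# Pearson correlation targets on the analysis scale.
correlations:
  - [hb, plasma_iron, 0.33]
  - [hb, zinc, 0.23]
  - [hb, tfr, -0.19]
  - [hb, agp, -0.23]
  - [ferritin, plasma_iron, 0.32]
  - [ferritin, hepcidin, 0.48]
  - [ferritin, tfr, -0.24]
  - [crp, agp, 0.34]
  - [crp, plasma_iron, -0.17]
  - [agp, plasma_iron, -0.16]

categorical:
  education:
    illiterate: 0.618
    literate: 0.382
  hfias_category:
    food_secure: 0.526
    mild: 0.125
    moderate: 0.230
    severe: 0.118

# Marginal frequency of each binary household asset indicator.
asset_probs: [0.85, 0.72, 0.55, 0.45, 0.34, 0.25, 0.15, 0.08]

anthropometry:
  muac: {mean: 24.4, sd: 2.4, min: 17.0, max: 35.0}
  bmi: {mean: 20.7, sd: 2.3, min: 14.0, max: 32.0}

demographics:
  age: {mean: 23.3, sd: 4.2, min: 18, max: 36}
  household_size: {mean: 5.7, sd: 2.2, min: 1, max: 14}
  n_children: {mean: 3.1, sd: 1.9, min: 1, max: 10}
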