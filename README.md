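# anemiascope

An inflammation-adjusted iron biomarker pipeline for anemia surveys of women
of reproductive age, with a calibrated synthetic cohort generator.

Anemia surveys in high-infection-burden settings cannot interpret iron
biomarkers at face value: ferritin is an acute-phase reactant and the
soluble transferrin receptor (sTfR) also shifts with inflammation.
`anemiascope` implements, as one tested pipeline, the analysis chain such a
survey needs:

1. **Synthetic cohorts** — a Gaussian copula over quantile-anchored
   marginals, calibrated so that published medians/IQRs, prevalence
   thresholds and pairwise correlations all hold on generated data. Every
   downstream stage is testable without participant-level data.
2. **Biomarker adjustment** — BRINDA-style inflammation correction
   `exp(ln v − β₁·max(0, ln CRP − ref) − β₂·max(0, ln AGP − ref))` with
   in-sample slope estimation and lowest-decile references; the
   UNICEF/UNU/WHO altitude correction for hemoglobin; Cook's body-iron
   index `−(log₁₀(sTfR/F) − 2.8229)/0.1207` mg/kg.
3. **Status classification** — anemia severity (Hb < 120/110/80 g/L), iron
   deficiency (adjusted ferritin < 15 µg/L), IDA, overload (> 150 µg/L),
   functional iron deficit (sTfR ≥ 8.3 mg/L), tissue iron deficiency (body
   iron < 0), acute/chronic inflammation staging (CRP > 5 mg/L, AGP > 1
   g/L), zinc inadequacy (< 10.7 µmol/L), with cohort prevalence summaries.
4. **Socio-economic scores** — HFIAS food-insecurity score (0–27) and the
   FANTA v3 four-level category via a packaged decision table; a DHS-style
   PCA asset wealth index with rank-cut quintiles; covariate recodes at the
   standard epidemiological cuts.
5. **Determinant models** — OLS for hemoglobin on log₁₀ biomarkers with VIF
   screening (< 2.5) and squared semipartial correlations by nested refit;
   a bivariate-screen → multivariate logistic regression for anemia with
   odds ratios and 95% Wald intervals.

## Worked example

```sh
anemiascope run --n 2000 --seed 3 --effects --out-dir demo
```

generates a 2000-woman synthetic cohort (with the optional
socio-demographic effects hook enabled so the logistic stage has signal),
adjusts, classifies, scores and models it, and prints:

```
Prevalence summary (n = 2000)
------------------------------------------
anemia_mild                     348    17.4%
anemia_moderate                 212    10.6%
anemia_severe                     0     0.0%
anemic                          560    28.0%
iron_deficient                  635    31.8%
ida                             187     9.3%
iron_overload                    40     2.0%
functional_iron_deficit         145     7.2%
...

Linear model for hemoglobin (n = 2000, adjusted R^2 = 25.5%)
predictor          coef               95% CI        p    sr^2  p(sr^2)
ferritin         -7.224 (  -8.585,   -5.864)    0.000   0.040    0.000
tfr             -10.126 ( -11.876,   -8.375)    0.000   0.048    0.000
...
plasma_iron      27.549 (  24.362,   30.736)    0.000   0.107    0.000

Logistic model for anemia (n = 2000)
factor                 OR                 95% CI        p
low_tfr             0.497 (    0.347,     0.710)    0.000
low_agp             0.423 (    0.324,     0.551)    0.000
low_muac            2.334 (    1.798,     3.029)    0.000
illiterate          1.845 (    1.482,     2.297)    0.000
low_zinc            1.850 (    1.418,     2.413)    0.000
```

Reading the output: with the effects hook on, anemia prevalence rises above
the marginal 19% (low-MUAC and illiterate women have been assigned lower
hemoglobin, and they are common in this population). Plasma iron carries
the largest unique share of hemoglobin variance (sr² = 0.107); women with
sTfR < 8.3 mg/L have 50% lower odds of anemia (OR 0.497 — sufficient
functional iron is protective), while MUAC < 22 cm raises the odds 2.3-fold.
The same stages run individually (`generate`, `adjust`, `classify`,
`score`, `model`) or from the library:

```python
from anemiascope import default_cohort_spec, generate_cohort

spec = default_cohort_spec(n=50_000, seed=1, calibrate=True)
cohort = generate_cohort(spec)     # tidy DataFrame, one row per woman
```

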