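# twostep — blood-based triage for amyloid-PET positivity

`twostep` implements a two-step diagnostic workflow for detecting amyloid-β
(Aβ) pathology in memory-clinic patients with mild cognitive impairment,
aimed at biostatisticians and clinical-biomarker researchers who want to
evaluate blood-based screening strategies without bespoke analysis code.

**Step 1** is a logistic risk model on blood-accessible predictors,

```
logit P(Aβ-PET+) = β₀ + β₁·log(p-tau217) + β₂·age + β₃·APOEε4 ,
```

whose predicted probabilities sort patients into three zones using paired
sensitivity/specificity-anchored thresholds: *low risk* (p < lower, where
the lower threshold guarantees ≥ Se% sensitivity, i.e. at most (100−Se)% of
true Aβ-positives are ruled out), *high risk* (p ≥ upper, guaranteeing
≥ Sp% specificity), and an *intermediate* zone in between. **Step 2** refers
only the intermediate zone to a confirmatory CSF Aβ42/Aβ40 test; low- and
high-risk patients are classified by blood alone, which is where the
reduction in lumbar punctures / PET scans comes from. Overall workflow
accuracy decomposes exactly as

```
accuracy = (correct_low + correct_high + correct_confirmatory) / N .
```

The package covers the full analysis around that idea:

- `twostep.cohort` — seeded synthetic memory-clinic cohorts (log-normal
  p-tau217 with configurable fold-change, APOE enrichment, bimodal PET/CSF
  markers, a second assay scale) plus reference-sample summaries;
- `twostep.binarization` — deterministic two-component Gaussian-mixture EM
  and equal-posterior cutoffs for continuous PET SUVr / CSF ratios;
- `twostep.risk_model` — logistic fitting, bootstrapped backward
  elimination (Wald p vs α = 0.157), Harrell optimism-corrected AUC with
  DeLong CIs, Nagelkerke R², AIC, decile calibration;
- `twostep.thresholds` / `twostep.workflow` — threshold derivation on the
  empirical probability grid, risk-zone stratification, zone NPV/PPV,
  confirmatory-test metrics, accuracy decomposition, tests-avoided
  fraction, Wilson CIs;
- `twostep.harmonization` — z-scoring against a cognitively-unimpaired
  Aβ-negative reference so the model and thresholds transfer across
  p-tau217 assays;
- `twostep.pipeline` / `twostep.cli` — the end-to-end sequence with a
  seeded manifest, also available as the `twostep` shell command.

## Worked example

`python examples/04_thresholds_and_workflow.py` fits the model on a
synthetic 348-participant cohort and evaluates all three strategies:

```
Se/Sp 90%: thresholds [0.52, 0.72), zones low/inter/high = 138/25/185
  low-zone NPV 85.5%, high-zone PPV 92.4%; overall accuracy 88.8% (CI 85.0-91.7%), confirmatory tests avoided 92.8%
Se/Sp 95%: thresholds [0.33, 0.89), zones low/inter/high = 119/77/152
  low-zone NPV 91.6%, high-zone PPV 95.4%; overall accuracy 92.2% (CI 88.9-94.6%), confirmatory tests avoided 77.9%
Se/Sp 97.5%: thresholds [0.25, 0.94), zones low/inter/high = 109/124/115
  low-zone NPV 95.4%, high-zone PPV 97.4%; overall accuracy 93.7% (CI 90.6-95.8%), confirmatory tests avoided 64.4%
```

Reading: with the moderate (95%) strategy, 119 + 152 of 348 patients are
classified by blood alone (77.9% of confirmatory tests avoided); the
low-risk zone is 91.6% Aβ-negative (its NPV), the high-risk zone 95.4%
Aβ-positive (its PPV), and adding the CSF result for the 77 intermediate
patients brings the whole workflow to 92.2% correct Aβ-PET classifications.
More stringent strategies trade avoided tests for accuracy. The other
example scripts cover cohort simulation, GMM binarization, model
development with optimism correction, and cross-assay transfer.

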