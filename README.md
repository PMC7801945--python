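# plsprog

Prognostic modelling of post-prostatectomy biochemical recurrence from
routine clinico-pathological variables and qPCR-derived molecular features,
built around a from-scratch PLS-DA (partial least-squares discriminant
analysis) classifier with a full cross-validation / permutation / ROC
evaluation stack.

## Who this is for

Biostatisticians and translational researchers who want to ask: *given a
small surgical cohort (tens of patients), does adding molecular markers —
here, expression of MALAT1-responsive transcripts measured in organotypic
slice cultures before and after MALAT1 silencing — improve prediction of
biochemical recurrence over the classical clinical picture?* Everything is
testable end to end without patient data thanks to a calibrated synthetic
cohort generator.

## The model

Patients are described by three nested feature sets ("criteria"):

* **classical** — age, serum PSA (ng/mL), ISUP grade group (from Gleason
  primary + secondary patterns), an ordinal pathological-stage code
  (pT2a→1 … pT3b→5), and a weighted *adverse-clinical-features* score

  `score = 1·LVI + 2·margins + 3·ECE + 0.5·PNI  ∈ [0, 6.5]`

  (lymphovascular invasion, positive surgical margins, extracapsular
  extension, perineural invasion);
* **new** — classical plus basal fold changes (vs the LacZ-gapmer control,
  2^−ΔΔCt convention) of MALAT1, ME3, PDK3, PDK1, CHKA, pS2 and PSA mRNA;
* **new_bis** — new plus the silenced/basal modulation ratios of ME3,
  PDK3, PDK1 and PSA, available only for patients whose MALAT1 silencing
  was efficient (≥ 17 % depletion).

A binary class indicator y (recurrent = 1) is regressed on the autoscaled
feature matrix by NIPALS PLS: per component, w ∝ Xᵀy (unit norm), t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then deflation X ← X − t pᵀ. Model quality is
quantified by

* **Q2 = 1 − PRESS/TSS** under leave-one-out cross-validation (scaling and
  fitting redone in every fold), with the number of components chosen to
  maximise Q2;
* a **permutation p-value** (default 1000 label permutations, add-one
  estimator (b+1)/(B+1)) for the observed Q2, re-running the entire
  cross-validation in every permutation;
* **ROC AUC** (Mann–Whitney pair statistic) with a stratified-bootstrap
  95 % CI;
* the **Youden criterion** threshold (maximising sensitivity + specificity
  − 1) and its misclassification error.

The package also ships the printed 50-patient clinical table as a fixture,
a qPCR toolbox (ΔΔCt fold change, silencing efficiency and the ≥ 17 %
depletion filter, modulation ratios, mtDNA content), and deterministic
calculators for the accompanying biochemical assays (lactate from a
standard curve, NADH/DCIP enzyme kinetics, metabolite ratios).

## Worked example

Forty synthetic patients (28 non-recurrent / 12 recurrent) drawn with the
default, literature-calibrated group parameters, evaluated under the
classical and new criteria:

```python
from plsprog import RunConfig, run_analysis, CohortSimParams

cfg = RunConfig(
    sim_params=CohortSimParams(seed=11),
    criteria=("classical", "new"),
    n_permutations=999,
    seed=5,
    out_dir="example_out",
)
for name, rep in run_analysis(cfg).items():
    print(name, rep.q2, rep.permutation_p, rep.auc, rep.misclassification_error)
```

prints (formatted):

```
classical: n=40 A=1 Q2=0.403 p=0.001 AUC=0.940 CI=(0.82,1.00) err=7.5%
new:       n=40 A=1 Q2=0.581 p=0.001 AUC=0.994 CI=(0.97,1.00) err=5.0%
```

Reading: both criteria carry real signal (Q2 ≫ 0; no permutation beat the
observed Q2, so p hits the 1/(B+1) floor). Adding the molecular features
lifts the AUC from 0.94 to 0.99 and drops the Youden misclassification
error from 7.5 % to 5 %. The component-score correlations identify the
drivers — under the new criterium the component correlates most with the
stage code (0.71), adverse score (0.69) and basal ME3 (0.65). Per-criterium
JSON reports, ROC coordinate TSVs and a univariate comparison table land in
`example_out/`.

The same pipeline is scriptable from the shell:

```bash
plsprog simulate --out cohort.csv --seed 2
plsprog run --input cohort.csv --criterium classical,new --permutations 999 \
            --seed 1 --out results_dir
plsprog compare results_dir/report_classical.json results_dir/report_new.json
```

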