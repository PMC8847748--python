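# cogconv

Longitudinal cognitive-conversion prediction and treatment-reassignment
analysis for Alzheimer's disease (AD) and mild cognitive impairment (MCI)
cohorts.

## The problem

Patients with AD or MCI are monitored with repeated neuropsychological
assessments (ADAS-cog, MMSE, IADL, NPI, QOL-AD, GDS, anxiety, CDR, DSST,
TMT-A/B) at baseline, 3 and 6 months.  A decline of **4 or more ADAS-cog
points** from baseline defines a clinically important improvement: the
patient is labeled *cognition improved* (CI), otherwise *cognition not
improved* (CNI).  If the long-term label could be predicted at baseline,
an insufficient treatment could be redirected months earlier.  `cogconv`
implements that full analysis as a tested pipeline:

1. **Synthetic cohorts** (`cogconv.synthetic`) — the original trial data
   are private, so a seed-deterministic generator emulates the cohort's
   schema and marginals (five intervention arms, arm-dependent ADAS-cog
   drift, AR(1)-correlated visit noise, coupled secondary scales).
2. **Preprocessing** (`cogconv.preprocess`) — exclusion of patients with
   >50% missing cells, mean/mode imputation, z-scoring fit on training
   folds only (a `pooled_scaling` switch restores whole-dataset
   fitting), and baseline-referenced CI/CNI labeling.
3. **The hybrid classifier** (`cogconv.model`) — a five-layer fully
   connected ReLU encoder compresses the static features into a logistic
   score `s ∈ (0,1)`; at each visit step an LSTM consumes
   `[scales_t, s, prev_outcome]` (teacher forcing: the true 3-month label
   during training, the predicted label at inference); scaled dot-product
   attention `softmax(QKᵀ/√d)V` over the hidden states feeds a logistic
   head producing P(CI) at 3 and 6 months.  Training is full-batch Adam
   (lr 0.01, ×0.1 at epochs 400/800, 1000 epochs) with epoch selection by
   highest validation AUC.  The network runs on a compact, finite-
   difference-checked reverse-mode autodiff core (`cogconv.nn`).
4. **Evaluation** (`cogconv.evaluation`) — stratified five-fold CV;
   per-fold accuracy/sensitivity/specificity/PPV/NPV/F-score/AUC/AUPRC at
   the Youden-optimal cutoff (J = sensitivity + specificity − 1), exact
   Clopper–Pearson intervals for proportions, DeLong intervals for AUC;
   and the **withdrawal experiment**: re-scoring trained models with the
   3-month visit removed, measuring how much 6-month prediction depends
   on the mid-point follow-up.
5. **Decision analysis** (`cogconv.decision`) — a CNI label at a
   follow-up flags the patient for treatment reassignment; actual vs
   predicted flag rates are compared per stratum (intervention, age band,
   gender, diagnosis) with the uncorrected Pearson chi-square, routing to
   Fisher's exact test when an expected cell count is below 5 (McNemar's
   paired test is available as the labeled alternative).

## Worked example

```bash
python examples/03_train_and_evaluate.py
```

trains the hybrid model on a 300-patient two-arm cohort whose arms differ
by 4 ADAS-cog points of drift per 3-month step, and prints:

```
3-month held-out AUC per fold: [0.702, 0.832, 0.833, 0.751, 0.783]
  mean accuracy 0.730, sensitivity 0.839, specificity 0.702
6-month held-out AUC per fold: [0.954, 0.939, 0.976, 0.89, 0.907]
  mean accuracy 0.883, sensitivity 0.942, specificity 0.844

withdrawal experiment (6-month AUC, per fold):
 fold  auc_full  auc_withdrawn  auc_drop  n
    0     0.954          0.865     0.089 60
...
mean AUC full 0.933 vs withdrawn 0.887
```

Six-month discrimination beats 3-month (the model integrates two visits),
and withdrawing the 3-month visit costs AUC because visit noise is
AR(1)-correlated — the mid-point genuinely informs the 6-month outcome.
The other examples cover cohort simulation (`01`), preprocessing (`02`),
and the reassignment contingency analysis (`04`), which reproduces the
published overall comparison exactly from its printed counts
(139/224 vs 104/224 → X² = 11.017, p = 0.001).

A config-driven end-to-end run is also available from the shell:

```bash
cogconv run-all --config my_run.yaml --out results/run1
```

emitting the cohort CSV, preprocessing report, per-fold metric tables,
model checkpoints, withdrawal table, stratified reassignment report, and
a line-delimited JSON log stamped with the config hash.

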