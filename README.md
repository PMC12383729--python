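# silentdropout

Toolkit for detecting **pre-symptomatic ("silent") retinal capillary
dropout** in a diabetic cohort, built around the inference chain used in
Nile-rat (*Arvicanthis niloticus*) diabetic-retinopathy studies, where a
destructive trypsin-digest measurement of acellular-capillary density
(counts/mm²) provides ground truth that non-destructive imaging cannot.

The package implements, as a tested library with a thin CLI:

- **Cutoff derivation** — the dropout threshold is the midpoint between a
  normal density band ([10, 16] counts/mm²) and a clearly affected band
  ([20, 22]), giving 18 counts/mm²; blood glucose and diabetes duration are
  compared across the bands with a Wilcoxon rank-sum test (exact by
  enumeration for small tie-free samples, Edgeworth-sharpened normal
  approximation otherwise).
- **Logistic duration prior** — P(CD|D) = σ(β₀ + β₁D) fit by Newton–Raphson
  maximum likelihood with step-halving, standard errors from the observed
  information.
- **Bayesian evidence fusion** — an image classifier's probability
  P(CD|AI) and the prior P(CD|D) are combined as
  P(CD|AI,D) = P(CD|AI)·P(CD|D) / (P(CD|AI)·P(CD|D) + (1−P(CD|AI))(1−P(CD|D))),
  i.e. addition on the log-odds scale, plus the posterior surface over all
  (duration, classifier-probability) combinations.
- **Evaluation** — confusion metrics, Mann–Whitney AUC, tie-grouped ROC
  curves, stratified k-fold assignment, and a from-scratch **paired DeLong
  test** for comparing raw vs fused AUCs on the same images.
- **Permutation importance** — a from-scratch regression random forest with
  out-of-bag bookkeeping and mean-decrease-in-accuracy (MDA) importance,
  MDA(Xₑ) = (1/T) Σₜ (Acc_baselineₜ − Acc_permutedₜ), ranking predictors of
  acellular density (diabetes duration, glucose, diet, age, sex).
- **RNA-seq noise benchmark & marker screen** — TPM, median-of-ratios size
  factors, Spearman rank correlation, per-gene overdispersion ratios
  (variance/mean of normalised counts) with a paired signed-rank comparison
  of two quantification methods, quantile-binned SD profiles, and a
  negative-binomial Wald screen flagging markers at >2 fold-change of
  normalised group medians and FDR < 5% (Benjamini–Hochberg).

A seeded synthetic generator (`silentdropout.simulate`) emulates the cohort
table, the classifier's class-conditional score distribution (Beta
distributions calibrated to a target AUC), and paired negative-binomial count
matrices, so the whole chain runs and is testable without any external data.
Real tables plug in as plain CSV/TSV with the same schemas.

## Worked example

```python
import silentdropout as sd

cfg = sd.SimulationConfig(seed=1, n_animals=250)
cohort = sd.simulate_cohort(cfg)                      # per-animal covariates + density
scores = sd.simulate_classifier_scores(cohort, 18.0, cfg)   # 2 images/animal

cut = sd.derive_cutoff(cohort)                        # bands [10,16] vs [20,22]
print(cut.cutoff)                                     # 18.0
print(round(cut.duration_test.median_low, 1),
      round(cut.duration_test.median_high, 1))        # 0.0 19.4  (weeks)

labels = sd.label_dropout(cohort["acellular_density"].to_numpy(), cut.cutoff)
prior = sd.fit_logistic_mle(cohort["diabetes_duration_weeks"].to_numpy(), labels)
fused = sd.fuse_cohort(scores, prior, cohort)

y = scores["true_label"].to_numpy()
res = sd.delong_test(fused["score"], scores["score"], y)
print(round(res.auc_b, 3), round(res.auc_a, 3))       # 0.853 0.995
print(res.p_value < 0.05)                             # True
```

The cutoff is the band midpoint (18 counts/mm²); animals in the high band
have a far longer median diabetes duration (19.4 vs 0.0 weeks); fusing the
duration prior with the classifier raises the AUC from 0.853 to 0.995, and
the paired DeLong test confirms the gain is not sampling noise.

The same steps are available from the shell:

```bash
silentdropout simulate --seed 1 --out sim/
silentdropout cutoff --cohort sim/cohort.csv --low 10:16 --high 20:22
silentdropout fit-prior --cohort sim/cohort.csv --out prior.json
silentdropout fuse --scores sim/scores.csv --prior prior.json --cohort sim/cohort.csv --out fused.csv
silentdropout evaluate --scores fused.csv --compare sim/scores.csv
```

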