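# ctcsig

Circulating tumor cells (CTCs) seed metastasis, and genomic regions
recurrently gained in CTCs define a signature whose expression, copy
number, and intratumor heterogeneity carry prognostic information in
ER+/HER2− breast cancer. `ctcsig` implements the full analysis pipeline
around such a signature as a tested, reusable Python package:

- **Expression signature training** — counts from a targeted panel
  (89 CTC + 24 breast-cancer + 14 EMT + 5 housekeeping genes) are
  normalized per sample to the geometric mean of the housekeeping genes
  (*PUM1, GUSB, GAPDH, POLR2A, PSMC4*), then an L1-penalized (LASSO)
  linear model of a continuous recurrence score (Oncotype-DX-like,
  0–100) is trained over repeated 60/40 random splits with 10-fold CV;
  the best iteration is selected by mean Pearson R on training and
  held-out data, and its stability is quantified over 1000 random
  sample subsets from 10% to 100% of the cohort.
- **Copy-number modeling** — 1-Mb segment log-ratios are QC-gated
  (tumor fraction < 0.15 or GC-Map MAD > 0.15 excluded), intersected
  with the CTC signature regions (0-based half-open, ≥1 bp), and fit by
  bidirectional stepwise-AIC regression (or the same L1 harness).
- **External survival validation** — a trained signature is transferred
  to an external cohort using coefficient *signs* only (bridging
  platform-scale differences), patients are stratified at the threshold
  maximizing the standardized log-rank statistic, and recurrence-free
  survival is compared by Kaplan-Meier curves and the log-rank test.
- **Intratumor heterogeneity (ΔH)** — per-cell Multiplex-FISH spot
  counts for 5 probes (*KLK10, MUC16, CCNE1, TGFB1, BSG*) plus a
  chromosome-19 centromere control are converted to gain signatures
  (probe count > control count); signatures exceeding a 99% Wilson
  bound around a pooled-normal null are "true clones"; each core's
  Shannon index H = −Σ p ln p over the clone table gives
  ΔH = |H_A − H_B| between two spatially separate cores of one tumor,
  compared across risk groups by Wilcoxon rank-sum tests.

Because the cohorts this kind of study uses are not publicly
distributable, the package ships synthetic-cohort generators
(`ctcsig.simulate`) that reproduce the statistical structure every
stage assumes — negative-binomial panel counts with hidden driver
genes, injected copy-number gains with QC metadata, censored
exponential survival on a shifted platform, and clone-mixture FISH
cores with a tunable between-core divergence — each carrying its latent
truth so recovery is testable.

## Worked example

```python
import ctcsig as cs

cfg = cs.GeneratorConfig(seed=1)
cohort = cs.generate_expression_cohort(cfg)   # 132 genes x 403 samples
norm = cs.hk_normalize(cohort)
harness = cs.run_harness(norm, cohort.scores, n_iter=10)
print(harness.performance.loc[harness.selected_index])
```

```
r_train        0.81379
p_train            0.0
r_test        0.771474
p_test             0.0
degenerate       False
Name: 7, dtype: object
```

The selected iteration (#7 of 10) correlates strongly with the
recurrence score on the 203 training samples (R = 0.81) and remains
strong on the 136 unseen test samples (R = 0.77). Transferring it by
signs alone to a synthetic
external cohort and stratifying at the optimal cutpoint:

```python
surv = cs.generate_survival_cohort(cfg)
risk = cs.sign_only_score(harness.selected, cs.hk_normalize(surv.expression))
cut = cs.optimal_cutpoint(risk.scores, surv.time, surv.event)
```

yields a high-risk group with clearly worse 20-year recurrence-free
survival (log-rank χ² = 17.0 at n = 400 under the default generator
settings).

A `ctcsig` command-line interface wraps the same steps
(`ctcsig simulate`, `expr-train`, `expr-robustness`, `cn-train`,
`validate`, `ith`); run `ctcsig --help`.

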