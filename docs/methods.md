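# Methods

This note documents the statistical procedures `ctcsig` implements, the
assumptions behind the synthetic-cohort generators, and the design
choices made where the analysis left genuine freedom.

## Expression signature

Panel counts are normalized per sample to the geometric mean of the
five housekeeping genes:

    value(g, i) = log2( (count(g, i) + 1) / geomean_{k ∈ HK}(count(k, i) + 1) )

The +1 pseudocount guards the zero counts typical of degraded FFPE
RNA; normalization is exactly scale-invariant in the large-count limit
(tested at counts ≥ 10³ to 10⁻³). Samples with all-zero housekeeping
counts carry no usable scale and are dropped with a logged record.
Tumor-vs-normal differential expression uses a per-gene Welch t-test
with Benjamini-Hochberg adjustment; genes are flagged at raw p < 0.01
(the volcano-plot threshold). Regression against the recurrence score
is done on log2 normalized values.

The training harness minimizes

    (1/2n) ‖y − Xβ − b‖² + λ‖β‖₁

with λ chosen at the minimum mean 10-fold-CV error (prediction, not
parsimony, is the goal, so the 1-SE rule is not used). Housekeeping
genes never enter the predictor set. Each of the (default 10) harness
iterations draws its own 60/40 split — train size ⌊0.6 n⌋, which gives
203/136 at n = 339 and 196/131 at n = 327 — and the selected iteration
maximizes mean(R_train, R_test), a concrete formalization of "best
performance in training and testing data". Degenerate iterations
(empty model, undefined correlation) are recorded but excluded from
selection. Robustness of the *fixed* selected model is the
distribution of Pearson R over 1000 subsets drawn without replacement
at each fraction of the cohort (default grid 10%–100% in 5% steps);
because the model is not refit, the median R is stable across
fractions and the spread at fraction 1.0 is exactly zero.

Pearson p-values use t = R·√((n−2)/(1−R²)) on n−2 df, two-sided.

## Copy-number model

Segment-level samples are QC-gated with strict inequalities — excluded
iff tumor fraction < 0.15 **or** GC-Map MAD > 0.15; boundary values are
retained. The gate is idempotent. Bins (fixed 1 Mb, 0-based half-open)
are kept iff they share ≥ 1 bp with any CTC signature region;
the result is independent of region input order and each kept bin
records every overlapping region id.

The stepwise model is bidirectional stepwise linear regression from the
intercept-only model under AIC (the conventional default of the
stepwise routine in the R stats environment), computed as
n·ln(RSS/n) + 2(k+1) up to a model-independent constant; at each step
the single add/remove move with the lowest AIC is accepted until no
move improves it, and the accepted-move trace is returned. On
independent designs with ≤ 10 candidate segments the search provably
matches the exhaustive all-subsets optimum in the test suite. Exactly
duplicated columns are deduplicated with a warning. The L1 arm reuses
the expression harness with n_iter defaulting to 1000.

## Survival validation

Sign-only transfer scores an external cohort as Σ sign(β_g)·x_g over
model genes present (absent genes logged), on log2
housekeeping-normalized values; this is invariant to any positive
rescaling of the coefficients, which is the point of the construction —
only the direction of each gene's association survives a platform
change. Copy-number models transfer at the gene level: each model
segment maps to its annotated genes and each available gene contributes
sign(β_segment)·cn_gene, **summed** over genes (a segment spanning more
genes weighs more; averaging was the alternative and the choice is
logged here).

The optimal cutpoint scans the midpoints of consecutive distinct
scores, keeps candidates leaving both groups ≥ minprop·n
(minprop = 0.1, the cutpoint routine's conventional default), and
returns the threshold maximizing |Z| of the standardized log-rank
statistic, ties broken toward the lower threshold. The scan equals
brute force by construction and is verified against an independent
lifelines-based scan. No multiplicity correction is applied over the
scan — matching the common practice it mirrors — so the p-value at the
selected threshold is optimistic; treat it as a stratification device,
not an honest test of association.

The log-rank statistic accumulates observed minus
hypergeometric-expected events per distinct event time with the
standard variance (no Efron tie handling is needed for the two-group
statistic); Kaplan-Meier curves come from lifelines with Greenwood 95%
CIs, and S(t) queries use the right-continuous step function with the
last value carried forward.

## FISH heterogeneity (ΔH)

Per cell, probe g is gained iff count_g > count_control; dividing out
the shared centromeric control absorbs sectioning truncation (thin
sections lose signals from all probes alike), which is why no explicit
thickness correction appears. Cells with a zero control count are
dropped. A clone is an exact 5-bit gain signature (32 possible; no
sub-clustering by copy level). Pooled normal cells give per-signature
null frequencies and the global false-positivity rate (fraction of
normal cells with any gain call). A tumor-core signature with observed
frequency f̂ over n cells is a *true clone* iff f̂ exceeds the upper
bound of the two-sided Wilson score interval at 99% around its null
frequency evaluated at the same n. True-clone frequencies plus the
residual class are renormalized and H = −Σ p ln p (nats by default,
bits available). ΔH = |H_A − H_B| between a patient's two tumor cores
("net difference" read as absolute, since reported ΔH values are
nonnegative); a patient is not evaluable if either core has fewer than
20 evaluable cells. A cohort-level inclusion gate flags the analysis
when the pooled-normal FPR exceeds a configurable threshold (default
0.106); the per-core-vs-per-cohort reading of that gate is ambiguous in
the source procedure, and the cohort-level reading is implemented.

Group comparisons use the two-sided Wilcoxon rank-sum test: exact null
distribution when the combined sample is ≤ 20 without ties, otherwise
the normal approximation with midranks, tie-corrected variance and a
*signed* continuity correction (so the correction vanishes when W
equals its null mean and identical groups give p = 1 exactly). The
implementation matches full enumeration for all combined n ≤ 12 in the
test suite. Recurrence-score bins are low 0–15, intermediate 16–25,
high 26–100.

## Synthetic-cohort generators

All generators are deterministic in (seed, config); each uses its own
sub-stream so changing one cohort's parameters never perturbs another.
Every cohort carries its latent truth for recovery testing.

**Expression.** Counts are negative binomial (dispersion r = 10,
var = μ + μ²/r, NanoString-like overdispersion; the upstream chemistry
gives no distributional detail, so NB is a modeling choice). Per-gene
baselines are log-normal (log2 mean 8, SD 1.5); 60% of non-HK genes
get a tumor shift ~ N(0.5, 1) in log2 (skewed toward overexpression, as
observed in panels of this kind); housekeeping genes have no tumor
effect and minimal biological variation; per-sample library depth is
log-normal (SD 0.3 in log2). Twenty hidden driver genes (|weight|
uniform on [0.5, 1.5], 70% positive) with between-tumor biological SD
1.0 generate the recurrence score as an affine function of their
centered log2 activity plus N(0, 6) noise, clipped to [0, 100]
(intercept 20, scale 2.5). These defaults place the score distribution
(mean ≈ 20.5, median ≈ 19.7) and the achievable model correlation
(R ≈ 0.8) in the regime the analysis was designed for; the score's
full distribution beyond mean/median is a free parameter of the
generator. Recovery properties (≥ 90% driver-sign recovery) are tested
at the stated stronger condition |effect|/noise ≥ 2 (driver weights
≥ 1.0, score noise SD 1.25).

**Copy number.** 250 bins of 1 Mb over 5 chromosomes; 20 fabricated
non-overlapping CTC regions of 1–3 Mb offset by half a bin so overlap
tests exercise partial intersection. Normals are N(0, 0.08) log-ratio
noise (n = 55); tumors (n = 327) add a per-sample Beta(2,2) gain dosage
times +0.5 log-ratio on 5 CTC-overlapping driver bins, and the dosage
drives the cohort's recurrence score with noise chosen so the fitted
model correlation is moderate (R ≈ 0.6), the regime reported for
copy-number models of this signature. 15% of tumors violate a QC gate
by construction.

**Survival.** Latent risk is linear in the same hidden driver genes as
the expression cohort (both generators share one driver draw per seed,
so an internally trained signature transfers meaningfully); events are
exponential with hazard 0.004·exp(0.7·risk_std) per month, censored by
an independent uniform time and administratively at 240 months
(20-year horizon). Observed expression is 2^(offset + scale·latent)
with per-gene scale uniform on [0.5, 2] and offset N(0, 1): positive
but non-uniform gene-wise rescaling, which is exactly the situation
sign-only transfer addresses. Replicate external cohorts
(`replicate=k`) redraw everything except the panel truth.

**FISH.** 108 patients × (2 tumor + 1 normal) cores × 100 cells.
A clone library holds the diploid clone, one single-gain clone per
probe and two double-gain clones (gained probes at 4 copies, control
diploid). Each patient activates 3 gain clones with Dirichlet weights
under a diploid fraction uniform on [0.3, 0.6]. Core B reallocates
core A's weights multiplicatively, w_B ∝ w_A·exp(d·1.5·ε) with
ε ~ N(0,1) — identical cores at divergence d = 0 and stochastically
growing composition gaps (hence ΔH) as d rises. Convex weight mixing
was rejected: mixtures have inflated entropy, which breaks ΔH
monotonicity at intermediate divergence. Observed spot counts lose
each copy independently with probability 0.0562; because all five
probes in a cell share one control draw, a false gain essentially
requires the diploid control to drop to a single spot, so the
normal-core any-gain false-positivity rate is ≈ 2p(1−p) ≈ 10.6%, the
empirical gate value the generator is calibrated to.

What the generators do **not** emulate: NanoString lane/QC artifacts,
raw reads or HMM segmentation (segment-level output is the interface),
gene-gene correlation beyond the shared drivers, FISH imaging noise or
spatial structure within a core, and informative censoring. Passing
tests therefore demonstrate correctness of the procedures under the
stated statistical assumptions, not performance on real cohorts.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open (BED convention) everywhere.
- Stepwise acceptance requires an AIC improvement > 1e-10 (guards
  float-tie cycling); cutpoint ties break toward the lower threshold.
- Constant regression response returns the intercept-only model with a
  warning; zero-variance vectors make Pearson correlation an error,
  not a NaN.
- Log-rank variance terms with a single subject at risk are skipped
  (n − 1 = 0 guard); a zero total variance yields statistic 0, p = 1.
- Wilson bounds use z = Φ⁻¹(0.995) ≈ 2.576 at the default 99% level.
- Shannon input must sum to 1 within 1e-9; 0·ln 0 ≡ 0.

## Problem sizes

The test suite runs mostly on reduced cohorts (≈ 30 genes × 100
samples, 60 CN tumors, 10 FISH patients) with full-size cohorts
(132 × 403, 327 + 55, 200 FISH patients per divergence level) reserved
for the recovery and calibration checks; `scripts/acceptance.py` uses
full-size cohorts throughout, 1000-replicate robustness at three
fractions, and 200 patients per FISH divergence level.

## Known limitations

- The cutpoint scan's uncorrected maximal selection inflates the
  significance of the resulting stratification (acknowledged above).
- Stepwise-AIC equals the global all-subsets optimum on the
  well-conditioned designs tested; on strongly collinear designs it
  can stop at a local optimum, as any greedy search can.
- The ≥ 90% sign-recovery property concerns the generator's
  uncorrelated-driver regime; correlated real panels would shift
  selection among correlated genes.
- The exact Wilcoxon branch defers to the tie-free case; tied small
  samples use the (tie-corrected) normal approximation rather than a
  midrank-exact enumeration.
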