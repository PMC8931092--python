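# Methods

This note records the models, the choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Data model and normalization

The pipeline's currency is a samples × proteins matrix of log2 relative
expression (one value per antibody per sample, as produced by RPPA
dilution-series quantification, which is upstream of this package) with
per-sample metadata and a clinical table (`{OS,TTFT,TTST}_time` in
years, `_event` with 1 = event, 0 = censored — one convention
throughout).

Normalization is a single pass of row-median then column-median
subtraction, followed by subtraction of the per-protein median over
CD19+ control samples, so that 0 means "at the normal B-cell level".
Whether the row/column pass should be iterated to convergence is
genuinely open; we default to the single pass (the simplest reading)
and expose full Tukey median polish behind `median_center(...,
polish=True)`. Note the single pass already leaves column medians
exactly zero; iterating changes row residuals only.

Missingness policy (the source protocols are silent): values may be
missing on ingest; median operations skip them; before clustering,
proteins missing in >20% of samples are dropped (logged) and the rest
median-imputed per protein (`prepare_complete`). Slide-position
(topographical) normalization is out of scope because slide layout is
not part of the input; it is an ingestion assumption.

Pre-analysis bias screening (`qc_bias_screen`) tests every protein
against pre-analytic factors (organ, fresh/frozen, therapy class,
collection interval) with Kruskal–Wallis, after Shapiro–Wilk and Levene
prechecks document why a rank test is appropriate, BH-FDR within each
factor.

## PFG clustering and k selection

Each protein functional group (PFG) is clustered over patients with
k-means (`n_init` restarts, best inertia; labels renumbered 1..k by
descending cluster size with centroid-lexicographic tie-break, which
makes the whole stage deterministic given data and seed).

The default k-selection criterion is the gap statistic:
`Gap(k) = mean_b log W_b(k) − log W(k)` over B uniform reference
draws, selecting the smallest k with `Gap(k) ≥ Gap(k+1) − se(k+1)`.
References are drawn uniformly over the PCA-aligned bounding box of the
data, which makes selection equivariant under rescaling (verified by a
property test). A progeny-resampling stability criterion (offspring
resampled feature-wise within clusters, co-assignment stability score)
is available via `method="progeny"`. Default search range is k = 1..8:
observed per-group pattern counts in cohorts of this kind average ~4,
so 8 is a generous ceiling. Zero-variance input yields k = 1 with a
warning.

Normal-like labeling: controls are projected into the PFG's PCA space
and classified by an LDA trained on the patient cluster labels; a
cluster is *normal-like* iff at least one control is assigned to it.
This "≥1 control" rule is an interpretive choice; it permits several
normal-like clusters per PFG (observed in real cohorts) and degrades
gracefully with few controls. With k = 1 there is nothing to
discriminate, so the single cluster is flagged iff the controls fall
inside its 95% Mahalanobis (chi-square) contour.

## The Metagalaxy block model

Cluster memberships are one-hot encoded into a binary patients ×
patterns matrix (each PFG's column block sums to exactly 1 per row).
Co-clustering uses a Bernoulli latent block model fitted by
classification EM: given column labels and block rates, each row moves
to its maximum-likelihood signature; columns likewise; rates are
re-estimated as block means; iterate to label convergence (cap 200
sweeps), best of `n_restarts` seeded initializations by log-likelihood.
The classification log-likelihood is non-decreasing across sweeps
(asserted), except immediately after an empty-cluster repair, which
splits the largest cluster by moving its worst-fitting half. We author
the block model directly rather than wrapping an external co-clustering
package.

Model-order selection uses the block chi-square score
`Σ_rc (O_rc − E_rc)²/E_rc` on the fitted partition with
`E_rc = (ones in constellation c) · (n_r/n)` — the standard
independence expectation, making the score the Pearson chi-square of
the collapsed R × C count table (verified against a brute-force double
loop). A literal variant that *divides* by the signature proportion is
retained behind a flag for comparison, but it is dimensionally
inconsistent (it grows ~R² regardless of structure) and is never used
for selection. Boxes with zero expectation are excluded with a warning.

The raw score cannot select (R, C) directly: because CEM chooses the
partition adaptively to fit the data, each added row or column cluster
buys a positive score increment even on structureless data (~10–12 per
block degree of freedom at n = 300 in our experiments), so the argmax
always sits at the largest grid corner. `search_grid` therefore
maximizes `score − 2·log(np)·(R−1)(C−1)` by default: charging
`2·log(np)` per degree of freedom is the usual risk-inflation rate for
a parameter selected among ~np candidates, and in planted-structure
experiments (n = 300, 4 signatures × 5 constellations, preferred-rate
0.9) it recovers the truth in 10/10 seeds where the raw argmax (still
available via `criterion="raw"`) never does. The grid of raw scores is
always returned; ties break toward smaller R+C, then smaller R.

Signature groups: average-linkage hierarchical clustering of the
signatures' constellation-prevalence profiles (their rows of block
rates, Euclidean distance), cut at the requested group count and
lettered A, B, … by smallest member signature. Whether such merges
should be algorithmic or curated is open; we default to the documented
algorithm, report (not enforce) pairwise log-rank checks between merged
signatures, and accept a manual override map.

## Survival analytics

KM, log-rank and Cox go through lifelines: product-limit estimator with
median = earliest t with S(t) ≤ 0.5 (NaN if never reached); k-sample
log-rank with a BH-corrected all-pairs table; Cox partial likelihood
with Efron tie handling, Wald CIs, and Harrell's c-index on the fitted
risk score. Degenerate Cox inputs (no events, constant or collinear
covariates, non-convergence) return flagged results, not exceptions.
The engines are cross-checked in tests against independent oracles: a
hand product-limit computation, a from-scratch at-risk-table log-rank,
and null coverage/parameter-recovery simulations.

Protein screening fits four forms per protein (continuous Cox;
median/tertile/sextile quantile groups tested by log-rank — the
grouped forms' natural test) with BH-FDR across proteins within each
form. Iterative validation (200 iterations, 66/34 train/test) estimates
cutpoints on train only, picks the form with the best train c-index,
applies train cutpoints to test, and records test significance at
p < 0.05 (log-rank for grouped forms, Cox Wald for continuous);
iterations with <5 test events are skipped with the denominator
adjusted. A protein is validated when >70% of evaluable iterations are
significant. One caveat discovered in testing: c-index selection does
not systematically prefer a grouped form even for a true step effect,
because tied predictions score 0.5 — the same expectation as the
continuous form's random within-group ordering — so the continuous
form, whose c-index fluctuates, often wins the argmax. Validation of a
real signal is unaffected (planted step effects validate at fraction
1.0); only the identity of the winning form is less interpretable than
one might hope.

CLL-IPI uses the published weights (TP53/del17p abnormal 4, IGHV
unmutated 2, β2M > 3.5 mg/L 2, Rai I–IV 1, age > 65 1; table
configurable) and groups low 0–1, intermediate 2–3, high 4–6, very
high 7–10; patients missing any component are excluded with the reason
recorded. Nested stratification runs log-rank across grouping B within
each level of A and vice versa, BH within each direction, flagging
strata with <2 groups or <5 events.

The Watch-and-Wait score counts adverse marker levels (low ANXA1, low
TFRC, high SMAD2.p245 against cohort medians; marker set configurable)
and bins ≥2 as the short-TTFT risk group. At-median convention: "low"
markers use strict `<` (at-median not adverse), "high" markers use `≥`
(at-median adverse).

## Targets and the reduced classifier

Differential expression versus CD19 controls: per protein, one-way
ANOVA across signature groups ∪ controls, then Tukey HSD contrasts of
each group against the controls; contrasts below the adjusted-p
threshold are reported with direction = sign of the median log2
difference. Tukey controls the family per protein, so no additional
FDR layer is applied.

The classifier panel: a random forest over all proteins is ranked by
per-tree out-of-bag permutation importance (mean decrease in OOB
accuracy, each tree's bootstrap reconstructed exactly). We implement
this rather than whole-forest permutation importance deliberately:
with redundant informative proteins — the norm in functional groups —
whole-forest permutation gives every copy zero credit because the
remaining copies compensate, whereas per-tree OOB credit reaches each
member. The top-n panel (default 30) is refitted and reported with
out-of-bag confusion, per-group recall and error rate; OOB (not
resubstitution) is the honest error of the procedure.
Misclassification analysis compares correct vs OOB-misclassified
patients within each true group (log-rank, KM medians, Welch-t
differential expression with BH).

## Synthetic cohorts

`synthdata` emulates the target study conditions: default 800 patients
+ 5 CD19+ controls, 384 proteins in 40 PFGs (150 planted patterns, mean
3.75 per group), 16 signatures, 13 constellations, log2 noise SD 0.5,
centroid separation 2.0 log2 units, preferred-pattern rate 0.9,
censoring uniform over a 25-year window, and per-group exponential
hazards spanning median survivals of roughly 6–23 years (OS) and
3.5–14 years (TTFT/TTST), the scale seen in indolent B-cell leukemia
cohorts.

Centroids sit on scaled simplex vertices so every pairwise centroid
distance equals `centroid_separation` exactly (one interpretable
separation knob; requires PFG size ≥ k). Cluster draws per
(signature, PFG) use categorical weights p_in on the preferred cluster
and p_out on each other, normalized — exact rates when
`p_in + (k−1)p_out = 1`. Signature r prefers constellation
`(r−1) mod C`; pattern (g, j) maps to constellation j when the PFG's
k equals C, else `(g+j) mod C`; when a signature's preferred
constellation has no column in a PFG its draw there is uniform. The
planted block structure is cleanest when all true k equal the number of
constellations. The truth's signature→group map defaults to identity,
since group merging is a data-driven downstream step.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: antibody cross-reactivity, dilution-series
and slide-position artifacts, non-Gaussian heavy-tailed expression,
correlated proteins across PFGs, informative censoring, and
covariate–outcome confounding (clinical covariates are drawn
independently of the planted survival structure, which is precisely
what makes the nested-stratification null checks interpretable).

## Problem sizes and numerics

Test and acceptance-script simulations use deliberately compact
cohorts — e.g. 300–400 patients, 8 PFGs, grids of a few dozen block
models, 200 validation iterations, 200 coverage replicates — chosen so
that recovery rates and calibration bands are statistically meaningful
(3-SE binomial tolerances) while a full run stays in the minutes range
on one CPU. Null calibration of the iterative validation is averaged
over several independent cohorts: within one cohort the resampled
splits are strongly correlated, so a single cohort's null fraction is
heavy-tailed (a chance r ≈ 0.1 protein–outcome correlation flags most
of its splits) and only the across-cohort mean estimates the 5% rate. Bernoulli rates are clipped to [1e-9, 1 − 1e-9] inside the
block-model likelihood; k-means uses 5–10 restarts; all stages are
deterministic given their seed, and every stochastic check derives its
RNG streams from a single seed.

## Known limitations

* The block model assumes constant fill within blocks; the one-hot
  constraint makes this only approximately true per PFG block.
* Grouped-form Cox fits use the group index as a single ordinal
  covariate when computing the train c-index (adequate for monotone
  quantile groups; a dummy-coded variant would cost events per level).
* The Tukey step uses scipy's studentized-range implementation, which
  assumes balanced-ish cells; heavily unbalanced groups lean on its
  unequal-n generalization.
* CLL-IPI's TP53 component is approximated by del(17p) alone when no
  TP53 mutation column is supplied.
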