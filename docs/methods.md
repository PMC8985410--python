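# Methods

This note records the models behind each stage, the defaults and why,
what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Differential expression

logFC is the difference of group means on log2-scale expression (AD
minus control); DEG calls require |logFC| > 0.1 **and** BH-FDR < 0.05,
both strict inequalities. The per-gene test is Welch's unequal-variance
t-test; a pooled-variance t is available behind a flag. We deliberately
use a plain two-sample test rather than an empirical-Bayes moderated
one: moderation matters most at very small n, adds a dependency on the
full-matrix variance pooling, and changes none of the downstream
contracts. The degenerate case — zero variance in both groups with
equal means — returns p = 1 (no evidence either way); unequal constant
groups return p = 0.

The control-resampling filter (for cohorts with a large control excess,
e.g. 194 controls vs 40 cases in blood) draws `n_subsample = 40`
controls without replacement per repeat, keeps all cases, reruns the
complete DEG call (test + BH) per repeat, and selects genes flagged in
≥ 3 of 10 repeats. Per-repeat seeds are `master_seed + repeat`, so
repeats are independent streams and the whole result is reproducible.

## Coexpression network

The network is **unsigned**: a_ij = |r_ij|^β. A signed power of a
negative correlation is ill-defined at non-integer exponents, and
unsigned is the common default when no sign convention is stated.
Zero-variance genes get correlation 0 with a warning rather than NaN.

Soft-threshold selection scans β = 1..20. For each β, connectivity
k_i = Σ_{j≠i} a_ij is binned into 10 equal-width bins; log10 frequency
is regressed on log10 mean connectivity; the fit index is R² signed
opposite to the slope, so only a *decreasing* degree distribution can
qualify. The chosen β is the smallest with fit > 0.80; when no power
qualifies the argmax is returned with `target_reached = False` and a
warning — downstream code proceeds, as the flag is advisory.

Topological overlap uses
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),
TOM_ii = 1, with k excluding the diagonal. It is computed from one
matrix product with the u = i and u = j terms subtracted, and is tested
against a triple-loop oracle to 1e-12.

Clustering is average-linkage on 1 − TOM with a **fixed-height cut**
instead of a full dynamic tree cut: deterministic and directly
testable. The cut parameter is *relative to the dendrogram*: the tree
is cut at q5 + cut_height · (max − q5), where q5 and max are the 5th
percentile and maximum of the merge heights. An absolute cut is useless
here — at higher soft-threshold powers all TOM distances concentrate
just below 1, so any fixed absolute threshold lands either below every
merge or above all of them; cutting within the observed height range is
the same normalization the dynamic tree-cut family applies. Clusters
below `min_module_size = 30` become unassigned (label 0); surviving
modules are renumbered by decreasing size. The default minimum of 30
sits well below typical reported module sizes (~100–140 genes).

Module eigengenes are the first right singular vector of the per-gene
z-scored module submatrix, oriented so the mean correlation with member
genes is positive (PCA sign is arbitrary; orientation makes
module–trait signs reproducible), and scaled to unit sample variance.
Module–trait association is the Pearson r of each eigengene with the
0/1 phenotype and the two-sided p from t = r·sqrt((n−2)/(1−r²)). The
AD module is the one with the largest positive r among those with
p < 0.05, ties broken by the smaller label; an explicit `None` is
returned when nothing qualifies.

## Enrichment

Over-representation uses the EASE variant of the hypergeometric test:
the observed overlap is reduced by one (floored at zero) before taking
the one-sided tail, which is strictly conservative relative to the
plain tail (available via `ease=False`). The default significance
threshold is raw p < 0.005; BH-adjusted values are reported alongside.
The background is the assay universe (all genes on the platform), not
the genome. The raw-p convention mirrors the common desktop-tool
default; whether to prefer the adjusted column is left to the caller.

## CFG scoring

Five binary criteria, one point each: gwas_locus_count > 0,
eqtl_count > 0, non-empty core-gene PPI partner set (partners restricted
to APP, PSEN1, PSEN2, APOE, MAPT), pathology correlation significant for
Aβ **or** Tau (any starred marker counts; per-star thresholds are not
modeled), early_deg = "yes". NA in any channel scores 0 for that
channel. These rules reproduce the packaged 40-row evidence table's
printed score column exactly, including the corner rows (NA GWAS count,
zero counts, both-ns pathology). Prioritization keeps genes with score
≥ min_score (default 4), sorted by score with input order preserved
within ties; duplicate gene ids are legal and scored independently.

## Drug–target matrix completion

The model is Score(i, j) = x_i W Hᵀ y_jᵀ with W: f_d × k, H: f_t × k.
The objective puts squared error with weight 1 on observed entries
(Ω⁺ = nonzero entries of P) and weight α on all remaining entries
treated as negatives, plus λ(‖W‖²_F + ‖H‖²_F). Defaults: k = 5,
α = 0.1, λ = 0.01 — α well below 1 encodes that unobserved pairs are
only weak negatives; all three are ordinary tuning parameters, not
claims.

Fitting is alternating least squares. With H fixed, W solves a ridge
problem whose normal matrix is α (BᵀB ⊗ XᵀX) plus a sparse sum of
(b_j b_jᵀ) ⊗ (x_i x_iᵀ) over observed entries (B = YH); the system is
f_d·k × f_d·k, solved exactly, so the objective is non-increasing by
construction and the trace is recorded. λ is floored at 1e-12 to keep
the normal equations nonsingular. Supporting real-valued observed
entries makes the planted-recovery check well-posed: with α = 1 and
λ → 0 on an exactly realizable score matrix, ALS recovers the planted
scores to ~1e-11.

The feature embedder is a single-hidden-layer denoising autoencoder
(sigmoid activations, masking corruption 0.2, L2 penalty, mini-batch
gradient descent) implemented directly in NumPy — the model is small
enough that explicit gradients are clearer than a framework dependency.
A `linear=True` switch removes the nonlinearities, which makes the
identity-reconstruction test exact. Raw features can bypass the
embedder entirely.

## Network proximity

p(T, S) is the mean over drug targets of the BFS hop distance to the
nearest disease gene (edges unweighted — "shortest path" with no stated
weights). Targets with no path to S are excluded with a warning; if no
target reaches S the proximity is an error rather than a silent
infinity. The adjusted similarity is

  f(p) = 1 / (1 + exp(−c[(1 + QC)(m − p)/m − d]))

with m = max(p) over the evaluated pairs of the current run, so f is a
relative score within a run. The exponent is parenthesized so that
(m − p)/m is the normalized closeness and d acts as the sigmoid
midpoint — the reading under which m being the maximum proximity makes
dimensional sense. QC, a quality-cluster weighting whose defining
formula is not fixed here, defaults to 0 (plain sigmoid) and is
injectable per drug. Defaults c = 30, d = 0.33 put a steep switch in
the lower third of normalized closeness; both are configuration.

Significance uses a degree-aware permutation null: nodes are sorted by
degree and chunked into bins of ≥ 10; each target is replaced by a
random unused node from its bin (widening to the whole graph when a
bin is exhausted); the empirical p-value is
(1 + #{null p ≤ observed}) / (n_perm + 1), which is never exactly zero.
Under the null (random T) the empirical p is approximately uniform
(KS-checked in the tests at 500 draws × 199 permutations).

## Synthetic data

`simulate_expression` plants modules by a latent factor: member genes
are √ρ · factor + √(1−ρ) · noise, so the within-module Pearson
correlation is ρ in closed form and generator properties are directly
checkable. DEGs get an additive shift (default 1.0 log2 units) on AD
samples only, so E[logFC] equals the shift. DEGs are planted
preferentially inside modules (`deg_module_enrichment`, default 0.7):
disease-responsive coexpression modules are precisely the structure the
pipeline is built to find, and without that overlap the DEG subset
carries no module signal for the coexpression stage. Defaults — 600
genes, 60 samples per group, three modules of 50, ρ = 0.7, 10% DEGs,
noise SD 0.5 on a baseline of 7 log2 units — are chosen as plausible
for brain microarray cohorts of this size; no per-dataset variance
parameters exist to calibrate against.

What the generator does **not** emulate: array-platform artifacts,
batch effects, normalization pipelines, correlated noise between
modules, heavy-tailed expression, or realistic LD/eQTL structure in the
evidence channels. Passing the planted-recovery tests therefore shows
the algorithms are correct on data satisfying their own assumptions,
not that real cohorts will behave as cleanly.

`simulate_drug_target` samples rank-k factors, takes the top `density`
fraction of the score matrix as observed positives, and embeds the
factors into feature space through random linear maps, so a rank-k
bilinear model on the features can realize the planted scores exactly.
`simulate_interactome` plants a disease quasi-clique on a random
background graph and attaches each drug's targets by paths of
configurable length, making the planted proximity exact by
construction.

## Pipeline

Stage order: DEG call → coexpression on the DEG subset → CFG on the
AD-module genes → matrix completion → proximity. One master seed
derives every stage seed by fixed offsets, and the manifest records
parameters, output paths, SHA-256 hashes, and captured warnings;
rerunning with the same master seed is byte-identical. When no module
shows a significant positive phenotype correlation, CFG falls back to
all DEGs with a recorded warning rather than aborting.

## Problem sizes

Tests and examples run at desk scale by design: hundreds of genes,
tens of samples, 40 × 30 interaction matrices, ≤ 60-node graphs, 10–20
null replicates, ≤ 500-draw calibrations. These sizes make every
oracle comparison (triple-loop TOM, pairwise BFS, step-up BH,
enumerated hypergeometric) exact and fast while leaving the algorithms
identical to what larger inputs would use; none of the implementations
are blockwise or out-of-core, so very large cohorts (> 20k genes) are
out of scope.

## Known limitations

- Fixed-height cutting cannot resolve nested or unevenly dense modules
  the way full dynamic tree cutting does.
- The DEG test does not adjust for covariates (age, sex, batch).
- The EASE p-value is conservative by construction; calibrated FDR for
  enrichment should use the adjusted column.
- f(p) is only comparable within a run (m is run-relative).
- CFG treats channels as independent binary evidence; it neither
  weights channel strength nor models correlation between channels.
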