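# Methods

This note documents the models and procedures implemented in `panminer`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic benchmarks do and do not demonstrate.

## Data model and preprocessing

The unit of analysis is a gene-by-sample real matrix (`OmicsMatrix`) with
a binary phenotype (case/control) and a datatype tag (expression or
methylation; methylation matrices carry gene-level β- or M-values and are
processed identically). Preprocessing is order-sensitive:

1. *Probe collapsing* — multiple probes mapping to one gene symbol are
   replaced by their arithmetic mean, per sample.
2. *Variance filter* — rows with sample variance (ddof = 1) below a
   threshold are dropped. Default threshold 0 (off); it exists mainly to
   remove constant probes before z-scoring.
3. *Row z-scoring* — each row is centered and divided by its sample sd.
   Unit scaling (not just centering) is used because the activity
   aggregation below sums genes; without a common scale, high-variance
   genes would dominate the sum regardless of their discriminative
   value. Missing values are rejected, never imputed.

Normalization is idempotent (re-normalizing changes nothing beyond 1e-9)
and read/write round-trips preserve full float precision
(`float_precision="round_trip"` on the reading side).

## Significant-pathway selection

Gene-set enrichment uses the weighted Kolmogorov–Smirnov running sum:
genes are ordered by a class-contrast metric r, members of a set
increment the sum by |r|^p normalized by the total hit weight, non-members
decrement by 1/(N−N_hit), and the enrichment score (ES) is the extreme
deviation, signed. Defaults: weight exponent p = 1; minimum set size 5
after intersection with the matrix. Two ranking metrics are used: the
signal-to-noise ratio with each group sd floored at
max(sd, 0.2·|mean|, 1e-8) (the usual guard against near-zero
denominators), and the Welch t statistic.

Significance is assessed by **phenotype permutation** (class labels are
reshuffled, not genes, so gene–gene correlation is preserved):
two-sided empirical p = (1 + #{|ES_perm| ≥ |ES_obs|})/(1 + n_perm), with
n_perm = 1000 by default; if fewer distinct label assignments exist they
are enumerated exhaustively. FDR is Benjamini–Hochberg across sets — a
deliberately simple, monotone estimator rather than the NES-pool FDR of
the original GSEA implementations. A pathway is *significant* when
q < 0.05 under both ranking metrics; in paired expression/methylation
designs the two datatypes' significant lists are unioned.

The permutation p-values are validated to be super-uniform under the
null, and the whole selector is calibrated on label-noise synthetic data
(≤ 10% of pathways at q < 0.05 in every seed) with near-complete power
for pathways whose members are shifted by 2 sd.

## Pathway activity (CORG) and its orientation

A pathway's activity is built from its condition-responsive genes:
member gene rows are z-scored, ranked by |Welch t|, and accumulated
greedily — each gene sign-aligned so its class contrast points the same
way — into a_S = Σ_{g∈S} ±z_g /√|S|, accepting a gene only while the
|t| of a_S strictly increases. The greedy score trajectory is therefore
strictly increasing and terminates within |members| steps.

One subtlety: the sign-aligned sum always discriminates "case-upward",
which would erase the up/down semantics the rest of the pipeline needs
(binary encoding, node colors, expression–methylation comparison). The
final activity is therefore multiplied by the top-ranked gene's own
t-sign, so a coherently down-regulated pathway keeps *lower* activity in
cases while mixed-sign pathways still combine constructively. The same
rule applies to pathway-set activities (below); it makes a singleton set
marked "down" evaluate to exactly the sign-flipped pathway activity.

**Pathway-set activity** (used when markers become classification
features) runs the identical greedy scheme over the sign-aligned
activity rows of the set's pathways, scored by the moderated t. The
combination can be fit on a designated sample subset and applied to all
samples, which is how fold-internal refitting works in cross-validation.

**Moderated t.** The two-sample t with empirical-Bayes variance
shrinkage: per-feature pooled variances s² (df = n₁+n₂−2) are modeled as
s₀²·F(df, d₀) and (d₀, s₀²) estimated by method of moments on log s²
(trigamma inversion by Newton iteration; infinite d₀ means complete
shrinkage to the prior, in which case the prior is the mean variance;
total df is capped at the pooled df across features). With fewer than 30
features no prior is estimable and d₀ = 0, i.e. the ordinary pooled t.
The implementation agrees with Bioconductor limma's eBayes to ~1e-8 on
both t and p, which a test asserts via Rscript.

## Discretization and the 2n-bit encoding

Each activity row is thresholded at its **median**: above → +1, at or
below → −1. The median (rather than 0) balances the two states per
pathway and is robust to skew; ties go down. Discretization is invariant
to strictly monotone transforms of a row. The n-dimensional state vector
of each sample is then encoded as 2n bits — bit i set iff pathway i is
up (+1), bit n+i set iff it is down — so exactly one of each pair is set
and decoding is lossless. Hyper-/hypo-methylation maps onto the same
up/down layout.

## BiMax biclustering

Mining runs separately on each class's sample columns of the 2n-item
matrix (the encoding forbids an up and down item of the same pathway
from co-occurring). A bicluster is an all-ones submatrix with at least 2
distinct pathways and at least ⌈min_support·n_class⌉ samples
(min_support = 0.25 by default, i.e. "25% of the class's samples"),
inclusion-maximal among biclusters meeting those thresholds. Because
every reported sample set is the full support of its item set, the
admissible maximal biclusters are exactly the **closed frequent
itemsets**; they are enumerated by a depth-first search with
prefix-preserving closure extensions (LCM-style). Output order is
deterministic: (−|samples|, −|items|, lexicographic items).

A brute-force oracle (exhaustive item-subset enumeration, ≤ 16 items)
pins the semantics; the miner is verified set-equal to it on hand
instances and on 200 random matrices at densities 0.2/0.5/0.8.

## Association rules and markers

Each bicluster's itemset becomes a candidate rule {itemset} ⇒ {mined
class}. Metrics are computed over **all** samples from integer counts
(kept as exact rationals internally): support = |cover ∩ class|/N,
confidence = |cover ∩ class|/|cover|, lift = confidence/(n_class/N).
Note the two support notions: bicluster admission uses class-relative
support; rule support is the classical all-sample joint frequency. Rules
are kept when confidence ≥ 0.8 (inclusive) and lift > 1 (strict). An
itemset predicting both classes keeps only its stronger rule — higher
lift, then confidence, then support, then the case rule (lift is the
only class-contrast measure among the three, hence "less significant" =
lower lift). Survivors are ranked per class by (lift, confidence,
support, itemset size) descending with a lexicographic tie-break, and
the top 250 per class (default) become the pathway-set markers.

## Pathway activity networks

A PAN is built per class from that class's markers: nodes are the
pathways occurring in ≥ 1 marker, sized by −log₂(p) of a **Welch** t-test
on the continuous activity between classes (Welch rather than the
moderated t so a node's size does not depend on how many other pathways
were profiled; p floored at 1e-300) and colored by the majority
discretized state over the class's samples (ties → down). Edges ignore
item direction: two pathways are connected with weight = (number of the
class's markers containing both)/(number of markers), so weights lie in
(0, 1]. Export formats: GraphML (lossless, round-trip tested), JSON, and
SIF with a TSV attribute sidecar; `plot_pan` gives a basic matplotlib
rendering.

## Marker evaluation

Three marker types are compared as features: differentially expressed
genes (selected by moderated t, default p < 0.05, re-selected inside
each training fold; if nothing passes, the top-10 |t| genes are used so
a model can still be fit), pathway activities, and pathway-set
activities (the CORG-of-pathways combination re-fit inside each training
fold only — test labels never influence feature construction, which a
test asserts by corrupting them). Protocol: stratified 4-fold CV, 8
repetitions with fresh partitions (repetition r uses random state
seed + r), metrics pooled over folds per repetition, reported as mean
(sd over repetitions) in percent. Classifiers and their fixed settings:
kNN (k = 3, Euclidean), SVM (linear kernel, C = 1), random forest (500
trees), Gaussian naive Bayes. Differences between marker types are
tested with a two-sided paired t-test on the 8 repetition accuracies;
when the paired differences have zero variance (identical or uniformly
shifted vectors) the statistic is undefined and NaN is reported.

## Synthetic data

The generator emulates a paired tumor/normal cohort: background genes
are iid standard normal; a planted *active pathway* shifts all its
member genes by ±δ (sd units) in one class's samples; a planted
*pathway-set* is a tuple of direction-annotated pathways that switch on
jointly per sample — Bernoulli(penetrance) in its class,
Bernoulli(leak) in the other — shifting each member pathway's genes by
±δ in exactly the "on" samples; the optional methylation mirror applies
the sign-flipped shifts to an independent noise matrix. Defaults follow
the regime of a mid-sized microarray study: 40 + 40 samples, ~20–50
pathways of 10–25 genes, δ = 2, noise sd 1. The standard recovery
scenario plants one case-specific set {P1↑, P2↑, P3↓} with penetrance
0.8 and leak 0.05. Output is fully determined by the seed, and the
ground-truth record (planted pathways, sets, per-sample module states)
travels with the data.

What the generator does **not** model: probe-level effects, batch
structure, heavy-tailed noise, correlated background genes, overlapping
gene sets. Passing benchmarks therefore show the machinery is correct
and calibrated under the assumed signal model, not that real cohorts of
this size will yield equally clean markers.

## Problem sizes and numerical choices

The shipped benchmarks use deliberately small instances: enrichment
calibration at 50 pathways × 10 genes + 250 background genes, 20 + 20
samples, 1000 permutations over 20 seeds; end-to-end recovery at 20
pathways × 15 genes + 200 background genes, 40 + 40 samples, 200
permutations per run over 100 seeded runs; oracle equivalence on
10-item × 12-sample matrices. These sizes were chosen so the full suite
runs quickly on one CPU while leaving each statistical check enough
resolution to fail visibly if the implementation drifts.

Other numerical details: empirical p-values use the add-one estimator
(never zero); SNR denominators are floored as above; the running-sum
falls back to equal hit weights if all member metrics are exactly zero;
rule thresholds are compared on exact rationals so confidence = 0.8
passes and lift = 1 fails by construction rather than by float luck;
all orderings (pathways, biclusters, rules, markers) are given
deterministic total orders so identical inputs and seeds produce
byte-identical outputs.

## Known limitations

- Enrichment reports no normalized ES or leading-edge subsets; FDR is
  plain BH on empirical p-values.
- The BiMax stage enumerates *maximal* itemsets only; sub-itemsets of a
  maximal bicluster are not emitted as separate rules.
- The moderated t covers the two-group contrast only, not a general
  linear-model framework (no covariates, contrasts, or array weights).
- With many strongly co-active pathways the number of closed itemsets
  (and hence rules) can grow combinatorially; the top-n ranking keeps
  output bounded but mining time can still grow on dense state matrices.
- Expression–methylation comparison assumes gene-level matrices on a
  shared pathway vocabulary; sample sets may differ between datatypes
  but each class must be represented in both.
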