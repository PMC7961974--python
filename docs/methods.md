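# Methods

This note documents the models and procedures implemented in `cdsom`,
the defaults and why they were chosen, what the synthetic cohort does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## Preprocessing

Raw intensities are clamped at 1 and log2-transformed, quantile-normalized
across samples, and gene-centralized (row mean subtracted), yielding Δe —
log2 expression relative to the cohort mean. Quantile normalization uses
the average-tie dialect: tied values within a sample receive the mean of
the reference values at their tied ranks. Centralization is mean-based;
median centralization would differ only for strongly skewed genes and is
not offered. Quantile normalization is idempotent and removes any
monotone per-sample distortion, which is why the generator's per-sample
multiplicative distortions vanish after preprocessing. No variance
filtering is applied: the SOM is designed to absorb the full transcript
complement.

## Batch SOM and portraits

Genes are data points in sample space. Training is the deterministic
batch algorithm: per epoch, every gene is assigned to its nearest
prototype (Euclidean), then every prototype is recomputed as the
Gaussian-neighborhood-weighted mean of assigned genes. The neighborhood
radius decays linearly from `max(rows, cols)/2` to 0.5 over the epochs
(default 50), so early epochs order the map globally and late epochs
approximate a k-means refinement; at a vanishing final radius each
non-empty prototype is exactly the mean of its genes (a fixed point of
one further batch step). Initialization spans the plane of the first two
principal components with a deterministic sign convention; a seeded
random-sampling fallback exists for degenerate inputs. Metagene
expression is the prototype component value itself, not a post-hoc mean
over mapped genes, which keeps empty nodes well defined. Node indexing is
0-based row-major with node (0, 0) rendered top-left.

The full-scale grid is 50×50 (2500 metagenes); development and test
fixtures use 20×20, which preserves all qualitative behavior at a
fraction of the cost. The quantization error is recorded per epoch and is
non-increasing over the final epochs.

## Spot modules

The over-expression summary map holds each node's maximum metagene value
over samples. Nodes strictly above a quantile of this map (default 0.95)
form the foreground; 8-connected components of at least `min_size = 5`
nodes become spots, labeled A, B, … by decreasing peak height.
8-connectivity was chosen because portraits are smooth and 4-connectivity
fragments ridges; a quantile threshold keeps segmentation invariant to
additive shifts of the map. Under-expression modules are not segmented
separately: after centralization they are the over-expression modules of
the complementary groups.

The pipeline segments fixture-scale (20×20) maps at the 0.92 quantile
rather than 0.95. The reason is arithmetic, not tuning: five planted
100-gene modules out of 5000 genes occupy ≈7 % of the map's nodes as
best-matching-unit footprints (node allocation is measured at ≈0.7× the
gene fraction), so a 5 % foreground cannot contain five modules at this
scale. A spot's activation in a sample requires at least half of its
nodes to rank in that sample's top decile of node values — a rank rule,
hence portrait-scale invariant.

Known limitation: compact planted modules are surrounded by "halo" nodes
— prototypes interpolating between a module cluster and the unstructured
background that win no genes but retain elevated values — and modules
sharing an activation group (the shared disease module with its
group-specific neighbours) are connected by bridge nodes of comparable
height. Both cap the node-set agreement between detected spots and
planted BMU footprints at Jaccard ≈0.5–0.8 and can merge adjacent spots;
the shared module D, planted at reduced amplitude (see below), often does
not segment as its own spot. Real transcriptomes fill expression space
continuously and do not produce isolated point clusters, so this is a
geometry artifact of the synthetic cohort rather than of the
segmentation; attempts to restore continuity with weakly structured
background genes re-couple the sample groups and destroy the four-class
silhouette optimum, and were therefore rejected.

## Class discovery

Samples are clustered by Ward linkage on Euclidean distances between
metagene columns (Ward pairs naturally with the Euclidean metagene
geometry and yields compact classes). Cluster quality uses the
correlation-difference silhouette: per sample, the mean Pearson
correlation to its own class (self excluded) minus the best mean
correlation to any other class. This is deliberately *not* the classical
silhouette — there is no denominator — and scores live in [−2, 2].
Singleton-cluster members score 0 (intra-class similarity undefined).
`choose_k` maximizes the mean score over k = 2…8, ties toward smaller k.

A structural property of this score worth knowing: it rewards partitions
whose classes are mutually anti-correlated and penalizes nested
structure. If a shared axis (e.g., a disease-severity continuum) carries
variance comparable to the class-specific modules, merging classes along
that axis raises the score and the optimum collapses to k = 2. The
synthetic cohort is therefore calibrated so that group-specific modules
dominate (see below); on data where a severity continuum dominates, the
argmax rule will legitimately prefer coarser partitions.

The sample diversity map is a second SOM trained on samples as data
points in metagene space (default 10×10, 30 epochs); each sample sits at
its best-matching node.

## Gene-set scoring and enrichment

The gene set Z-score of set S in sample j is
`√N_S · (mean_{g∈S} Δe_gj − mean_g Δe_gj) / sd_g(Δe_gj)` with N_S the set
size after intersection with the expression universe. Under independence
it is approximately standard normal (verified: 1000 random 50-gene sets
on null data give mean ≈0, sd ≈1), so group-level polar diagrams can read
±2 as clear activation. The original GSZ literature defines a
parametrized family; this one-sample z-of-set-mean form is the simplest
calibrated member and is used throughout; group-level GSZ is the mean of
per-sample scores over group members.

Spot enrichment uses the one-sided (greater) Fisher exact test per
(spot, set) with BH adjustment across sets within each spot — only
over-representation is meaningful inside a spot. Phenotype contingency
tables use the two-sided test. Odds ratios are the sample ratio ad/bc
(∞ when bc = 0), not the conditional MLE. The accumulation/depletion
call for arbitrary gene lists in spots uses the two-sided test at
p < 0.05 with the direction taken from observed versus expected overlap.

## Marker discovery

AUC is the midrank Mann–Whitney statistic (ties count ½), verified
against all-pairs counting. AUC maps score each node's metagene profile
against a binary phenotype; the down map is 1 − up. Marker selection
takes genes whose best-matching unit reaches the AUC cutoff and ranks
them by their own per-gene AUC. Differential expression uses Welch's
unequal-variance t-test with BH control; fold change is the class-mean
difference of centralized log2 values, so its sign always matches the t
statistic. Degenerate rows (zero variance in both classes) get p = 1
when the class means agree and p = 0 otherwise.

The headline contrast — the marker module's averaged metagene classifies
diagnosis perfectly while no member gene does — is a noise-compensation
effect: averaging ~12 genes per node shrinks measurement noise by ~3.5×,
which turns the weakest per-gene margin (the attenuated disease signal of
mixed-group CD samples) from overlapping into separable.

## Immune-cell deconvolution

Relative fractions solve `min ‖S f − m‖ over f ≥ 0` on the genes shared
between mixture and signature, then normalize to sum 1. This constrained
least-squares formulation replaces the ν-SVR machinery of the popular
deconvolution tool: it is transparent, deterministic and exactly testable
(noiseless mixtures in the signature's column space are recovered to
numerical precision; fractions are invariant to positive rescaling of the
mixture). Deconvolution operates in linear intensity space; log-scale
matrices are exponentiated first and centralized matrices are rejected.
Rank deficiency of the shared signature raises an error naming the
collinear columns (QR with column pivoting).

Atrophy trajectories order samples by the lower-crypt GSZ and smooth each
cell type's fraction profile with LOESS — tricube-weighted local linear
regression over the span-fraction nearest neighbours (span 0.75, no
robustness iterations; the simplest defensible choice). Duplicate
ordering scores are collapsed by averaging before fitting.

## Pathway signal flow

Pathways are signed directed acyclic graphs (edge-list TSV,
`source  target  ±1`). Node values are positive fold changes
(`2^(group-mean Δe)`, guaranteeing positivity); unmapped nodes default to
1. In topological order, a source's signal is its own value; any other
node's signal is its value times the sum of incoming contributions — the
parent's signal for activation, its reciprocal for inhibition. Summation
over multiple parents preserves monotonicity and is the simplest
composition consistent with the rule; cyclic topologies are out of scope.
Three toy fixtures (chain, fork, inhibition diamond) ship with the
package.

## Synthetic cohort: what it emulates, and calibration

The generator reproduces the statistical skeleton of a four-group
paediatric duodenal-biopsy cohort (N = 17/9/8/12 for R/M/CD-L/CD-H, 46
samples, 5000 genes):

* **Modules.** Five 100-gene co-expression modules: A up in R, B in M,
  C in CD-L, D in CD-L + CD-H, E in CD-H. Effects are scaled so each
  module's *centralized* amplitude is comparable — 1.7 log2 units for the
  group-specific modules. The shared module D is planted at 0.6:
  a design study showed that the correlation-difference silhouette keeps
  k = 4 optimal only while group-specific variance dominates shared
  disease axes; D at parity flips the optimum to k = 2. D is also the CD
  marker module: mixed-group CD samples express it at 0.47 of its effect,
  the weak margin that keeps single genes below AUC 1 while the metagene
  reaches 1.
* **Atrophy gradient.** A latent score per sample, uniform within
  group-specific ranges rising from R to CD-H. Two dedicated 80-gene
  blocks load on it with opposite signs (±0.75 log2 per unit score): the
  upper-crypt (healthy villi) block falls with atrophy, the lower-crypt
  (proliferative) block rises. Their block means track the latent score
  at r > 0.95 and their metagenes anti-correlate below −0.85.
* **Immune layer.** A 22-cell-type signature matrix (10 exclusive markers
  per type plus shared background genes, linear scale, full column rank)
  mixed per sample with fractions whose log-weights drift along the
  atrophy score (activated T cells and M0/M1 macrophages up, M2, resting
  NK and resting dendritic cells down), added to a dedicated block of
  low-baseline genes.
* **Noise.** Gene-wise Gaussian log2 noise (sd 0.5), per-sample
  multiplicative distortions (log2 sd 0.2; removed by quantile
  normalization), lognormal mixture noise for deconvolution benchmarks.
* **Phenotypes.** Diagnosis is drawn first (R pure control, CD groups
  pure CD, the mixed group at its published 5:3:1 CD/control/unclear
  composition) and drives the expression of module D; serology and Marsh
  stages are sampled per group at the published empirical rates, so the
  contingency structure is reproduced in expectation and is significant
  for every seed.

Not emulated: probe-level bead chemistry, hospital batch effects,
ncRNA-specific biology, and — importantly — the continuous correlation
manifold of real transcriptomes: background genes are independent noise,
which makes planted modules isolated point clusters and is the root cause
of the spot-segmentation halo artifact described above. Passing tests on
this cohort therefore demonstrate correctness of the algorithms under
their stated assumptions, not segmentation robustness on real data.

## Problem sizes and determinism

Test fixtures run the full cohort (5000 × 46) on a 20×20 grid for 50
epochs — a few seconds on one CPU; the acceptance script re-runs the
whole analysis from scratch in well under a minute, using a 50×50 grid on
a reduced matrix for the structural check. All randomness flows through
`numpy.random.default_rng` seeded explicitly; identical configuration and
seed give bit-identical outputs, including rendered portrait PNGs and the
pipeline manifest digests.
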