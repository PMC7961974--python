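# cdsom — SOM portrayal of intestinal biopsy transcriptomes

`cdsom` re-implements, as a tested and reusable Python library, a
self-organizing-map (SOM) "portrayal" workflow for bulk transcriptomes of
duodenal biopsies, of the kind used to stratify coeliac-disease (CD)
cohorts into molecular subgroups. It is aimed at computational biologists
who want the individual stages of such an analysis — normalization, SOM
training, expression-module ("spot") segmentation, class discovery,
gene-set scoring, marker discovery, immune-cell deconvolution and pathway
scoring — as composable, unit-tested building blocks rather than a
monolithic pipeline.

## The method

Gene expression profiles (genes × samples, quantile-normalized and
gene-centralized log2 intensities Δe) are clustered by a batch SOM in
which each **gene** is a data point and each of the `r × c` grid nodes
holds a *metagene* — a prototype expression vector. Reshaping the node
values of one sample gives its mosaic **portrait**; averaging over group
members gives group portraits and their differences give difference
portraits.

Downstream stages all operate on the metagene grid:

* **Spot modules** — connected regions (8-neighborhood) of the node-wise
  over-expression summary map `max_j Δe_kj` above a quantile threshold;
  spot genes are those whose best-matching unit lies inside.
* **Class discovery** — Ward clustering of samples in Euclidean metagene
  space, validated by a correlation-difference silhouette
  `s_i = r̄(intra) − max_other r̄(inter)` (Pearson correlation of metagene
  landscapes; no denominator, so s ∈ [−2, 2]).
* **Gene set Z-score (GSZ)** — per sample,
  `GSZ = √N_S (mean_S Δe − mean Δe) / sd(Δe)`, approximately standard
  normal for random sets.
* **AUC maps** — per node, the midrank Mann–Whitney AUC of the metagene
  profile against a binary phenotype; genes from maximum-AUC metagenes are
  marker candidates, refined by Welch-t/Volcano statistics with
  Benjamini–Hochberg control.
* **Immune deconvolution** — non-negative least squares of linear-scale
  mixtures against a cell-type signature matrix, fractions normalized to
  one; fraction trajectories along the villous-atrophy axis (samples
  ordered by the lower-crypt GSZ) are LOESS-smoothed.
* **Pathway signal flow (PSF)** — expression fold changes propagated
  through signed acyclic pathway topologies (activation multiplies by the
  parent signal, inhibition by its reciprocal).

Because the original patient data are not required for development, the
package ships a first-class synthetic cohort generator that emulates the
statistical structure such a study rests on: four sample groups of sizes
17/9/8/12 (reference R, mixed M, CD-low, CD-high), five planted
co-expression modules A–E with group-specific activation, antagonistic
upper-/lower-crypt gradient blocks driven by a latent villous-atrophy
score, an immune-cell mixing layer over 22 cell types, per-sample
intensity distortions, and a phenotype table whose serology/Marsh
contingency follows the published group rates.

## Worked example

```python
from cdsom import (CohortConfig, GeneSet, choose_k, correlation_silhouette,
                   detect_spots, gsz_score, hierarchical_clusters,
                   overexpression_summary_map, preprocess,
                   sample_correlation_matrix, simulate_cohort, train_som)
from cdsom.markers import auc_map

em, phenotype, truth = simulate_cohort(CohortConfig(seed=1))
expr = preprocess(em)                      # log2 -> quantile norm -> centralize
model = train_som(expr, grid_rows=20, grid_cols=20, epochs=50, seed=1)

k = choose_k(model)
corr = sample_correlation_matrix(model)
sil = correlation_silhouette(hierarchical_clusters(model, k), corr)
print(f"chosen k = {k}, mean silhouette = {sil.overall_mean:.3f}")

spots = detect_spots(overexpression_summary_map(model), model,
                     quantile_threshold=0.92)
for s in spots:
    print(f"spot {s.label}: {len(s.member_nodes)} nodes, {len(s.member_genes)} genes")

lower = GeneSet("lower_crypt", "proliferative crypt signature",
                truth.crypt_genes["lower_crypt"])
print(gsz_score(lower, expr, grouping=truth.group_labels).group_means.round(2))

cd = (phenotype["diagnosis"] == "CD").to_numpy()
up, _ = auc_map(model, cd)
print(f"max metagene AUC (CD vs non-CD) = {up.values.max():.3f}")
```

Output:

```
chosen k = 4, mean silhouette = 0.709
spot A: 14 nodes, 200 genes
spot B: 9 nodes, 121 genes
spot C: 9 nodes, 130 genes
group
CD-H    3.99
CD-L    2.44
M      -0.35
R      -3.89
Name: lower_crypt, dtype: float64
max metagene AUC (CD vs non-CD) = 1.000
```

Reading the numbers: class discovery finds the four planted groups
(k = 4) with a solidly positive silhouette; segmentation of the
over-expression summary map yields three spots at this resolution (two
correlated planted modules merge into one spot and the weak shared
module does not segment on its own — see `docs/methods.md`); the planted lower-crypt signature rises monotonically
from the reference group to CD-high, the transcriptomic face of
progressive villous atrophy; and the best metagene classifies CD versus
non-CD diagnosis perfectly (AUC = 1) even though no single gene does —
node-level averaging cancels measurement noise.

A thin CLI mirrors the library
(`cdsom simulate|preprocess|train|spots|stratify|gsz|enrich|markers|deconvolve|psf|run`),
and `cdsom run --seed 1 --outdir out/` executes the whole synthetic
pipeline with a digest-carrying run manifest.

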