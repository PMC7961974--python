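"""Sample class discovery from metagene landscapes.

Samples are compared through Pearson correlation of their metagene vectors
and grouped by Ward hierarchical clustering in Euclidean metagene space.
Cluster quality uses a correlation-difference silhouette: per sample, the
mean correlation to its own class (self excluded) minus the best mean
correlation to any other class. Unlike the classical silhouette there is no
denominator, so scores live in [-2, 2]; positive scores mean the sample
fits its assigned class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .som import BatchSOM, SOMModel


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample id -> cluster label (1..k)
    k: int
    linkage: np.ndarray  # scipy linkage record (merge heights)


@dataclass
class SilhouetteReport:
    scores: pd.Series  # per-sample correlation-difference silhouette
    cluster_means: pd.Series
    overall_mean: float


def sample_correlation_matrix(model: SOMModel) -> pd.DataFrame:
    """Samples x samples Pearson correlation of metagene columns."""
    if model.n_samples < 2:
        raise ValueError("need at least two samples")
    sd = model.prototypes.std(axis=0)
    if np.any(sd == 0):
        bad = [s for s, v in zip(model.sample_ids, sd) if v == 0]
        raise ValueError(f"zero-variance sample columns: {bad}")
    r = np.corrcoef(model.prototypes.T)
    return pd.DataFrame(r, index=model.sample_ids, columns=model.sample_ids)


def hierarchical_clusters(model: SOMModel, k: int) -> ClusterAssignment:
    """Ward clustering of samples in Euclidean metagene space, cut at k."""
    n = model.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    z = linkage(model.prototypes.T, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=model.sample_ids, name="cluster"),
        k=int(len(np.unique(labels))),
        linkage=z,
    )


def correlation_silhouette(
    assignment: ClusterAssignment, corr: pd.DataFrame
) -> SilhouetteReport:
    """Intra-class minus best other-class mean correlation, per sample.

    Members of singleton clusters score 0 (intra-class similarity is
    undefined); with a single cluster every score is 0.
    """
    labels = assignment.labels
    missing = set(corr.index) - set(labels.index)
    if missing:
        raise ValueError(f"assignment does not cover samples: {sorted(missing)}")
    samples = list(corr.index)
    r = corr.to_numpy()
    lab = labels.loc[samples].to_numpy()
    uniq = np.unique(lab)
    scores = np.zeros(len(samples))
    for i in range(len(samples)):
        own = lab[i]
        mates = np.flatnonzero((lab == own) & (np.arange(len(samples)) != i))
        if len(mates) == 0 or len(uniq) < 2:
            scores[i] = 0.0
            continue
        intra = r[i, mates].mean()
        best_other = max(
            r[i, np.flatnonzero(lab == other)].mean() for other in uniq if other != own
        )
        scores[i] = intra - best_other
    scores = pd.Series(scores, index=samples, name="silhouette")
    cluster_means = scores.groupby(labels.loc[samples]).mean()
    return SilhouetteReport(
        scores=scores,
        cluster_means=cluster_means,
        overall_mean=float(scores.mean()),
    )


def choose_k(
    model: SOMModel,
    k_range=range(2, 9),
    corr: Optional[pd.DataFrame] = None,
) -> int:
    """k maximizing the mean correlation silhouette; ties -> smaller k."""
    if corr is None:
        corr = sample_correlation_matrix(model)
    best_k, best_score = None, -np.inf
    for k in k_range:
        if k > model.n_samples:
            continue
        rep = correlation_silhouette(hierarchical_clusters(model, k), corr)
        if rep.overall_mean > best_score + 1e-12:
            best_k, best_score = k, rep.overall_mean
    if best_k is None:
        raise ValueError("k_range contains no feasible k")
    return best_k


def sample_som_coords(
    model: SOMModel,
    grid: tuple[int, int] = (10, 10),
    seed: int = 0,
    epochs: int = 30,
) -> pd.DataFrame:
    """2-D sample diversity map: a second SOM trained on samples as data
    points in metagene space; each sample sits at its best-matching unit."""
    som = BatchSOM(
        grid_rows=grid[0], grid_cols=grid[1], epochs=epochs, random_state=seed
    ).fit(model.prototypes.T)
    bmu = som.labels_
    rows, cols = np.divmod(bmu, grid[1])
    return pd.DataFrame(
        {"row": rows, "col": cols}, index=pd.Index(model.sample_ids, name="sample_id")
    )
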