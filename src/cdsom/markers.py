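"""ROC/AUC marker discovery on genes, gene sets and metagenes.

The AUC equals the midrank Mann-Whitney statistic: the probability that a
randomly drawn positive sample scores above a randomly drawn negative one,
with ties counting one half. Scoring every SOM node's metagene profile
against a binary phenotype yields an *AUC map*; genes mapping to
high-AUC nodes are marker candidates, refined by Welch t / Volcano
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .genesets import GeneSet, bh_adjust
from .matrix import ExpressionMatrix
from .som import Portrait, SOMModel


@dataclass
class AUCMap:
    values: np.ndarray  # grid of AUC in [0, 1]
    direction: str  # {"up", "down"}
    phenotype: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("AUC values must lie in [0, 1]")


def _check_labels(labels, n: int) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.shape != (n,):
        raise ValueError(f"labels must have length {n}")
    if y.all() or not y.any():
        raise ValueError("both classes must be non-empty")
    return y


def rank_auc(values, labels) -> float:
    """Midrank AUC of ``values`` for binary ``labels`` (ties count 1/2)."""
    values = np.asarray(values, dtype=float)
    y = _check_labels(labels, len(values))
    return float(roc_auc_score(y, values))


def auc_map(model: SOMModel, labels, phenotype: str = "") -> tuple[AUCMap, AUCMap]:
    """Up- and down-AUC maps: per node, the AUC of its metagene profile."""
    y = _check_labels(labels, model.n_samples)
    up = np.array([roc_auc_score(y, row) for row in model.prototypes])
    shape = (model.grid_rows, model.grid_cols)
    return (
        AUCMap(up.reshape(shape), "up", phenotype),
        AUCMap((1.0 - up).reshape(shape), "down", phenotype),
    )


def signature_auc(
    gene_set: GeneSet, m: ExpressionMatrix, labels
) -> tuple[pd.DataFrame, float]:
    """ROC of the set's mean centralized expression; returns (curve, AUC)."""
    members = m.data.index.intersection(list(gene_set.genes))
    if len(members) == 0:
        raise ValueError(f"gene set {gene_set.name!r} does not intersect the universe")
    score = m.data.loc[members].to_numpy().mean(axis=0)
    y = _check_labels(labels, m.n_samples)
    fpr, tpr, _ = roc_curve(y, score)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), float(roc_auc_score(y, score))


def phenotype_map(model: SOMModel, covariate, name: str = "") -> Portrait:
    """Per-node Pearson correlation of the metagene profile with a
    real-valued per-sample covariate (zero-variance nodes map to 0)."""
    cov = np.asarray(covariate, dtype=float)
    if cov.shape != (model.n_samples,):
        raise ValueError("covariate must cover all samples")
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate must be finite")
    if cov.std() == 0:
        raise ValueError("covariate is constant")
    x = model.prototypes
    xc = x - x.mean(axis=1, keepdims=True)
    cc = cov - cov.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ cc) / denom, 0.0)
    return Portrait(
        r.reshape(model.grid_rows, model.grid_cols), name or "phenotype", "phenotype"
    )


def volcano(
    m: ExpressionMatrix, labels, genes: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Welch t-test per gene between the two label classes.

    Fold change is the class-mean difference of (centralized) log2 values,
    positive = higher in the True class; q is BH-adjusted across the genes
    tested. Genes with zero variance in both classes get p = 1 when the
    class means agree and p = 0 otherwise.
    """
    y = _check_labels(labels, m.n_samples)
    data = m.data if genes is None else m.data.loc[list(genes)]
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least two samples per class")
    x1 = data.to_numpy()[:, y]
    x0 = data.to_numpy()[:, ~y]
    fc = x1.mean(axis=1) - x0.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(x1, x0, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    with np.errstate(invalid="ignore"):
        p = np.where(degenerate, np.where(fc == 0, 1.0, 0.0), p)
        t = np.where(degenerate, np.where(fc == 0, 0.0, np.sign(fc) * np.inf), t)
    return pd.DataFrame(
        {"log2fc": fc, "t": t, "p": p, "q": bh_adjust(p)}, index=data.index
    )


def select_markers(
    up_map: AUCMap,
    model: SOMModel,
    m: ExpressionMatrix,
    labels,
    auc_min: float = 0.9,
) -> pd.DataFrame:
    """Genes whose best-matching node reaches ``auc_min`` on the up-AUC
    map, ranked by their own per-gene AUC (descending)."""
    if not 0.5 <= auc_min <= 1.0:
        raise ValueError("auc_min must lie in [0.5, 1]")
    y = _check_labels(labels, m.n_samples)
    node_auc = up_map.values.ravel()
    rows = []
    for gene, node in zip(model.gene_ids, model.gene_to_node):
        if node_auc[int(node)] >= auc_min:
            g_auc = roc_auc_score(y, m.data.loc[gene].to_numpy())
            rows.append({"gene": gene, "node": int(node),
                         "node_auc": node_auc[int(node)], "gene_auc": g_auc})
    df = pd.DataFrame(rows, columns=["gene", "node", "node_auc", "gene_auc"])
    return df.sort_values("gene_auc", ascending=False, kind="stable").reset_index(drop=True)
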