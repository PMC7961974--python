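"""Batch self-organizing map over gene expression and its portraits.

Genes are the data points (dimension = number of samples); the trained
prototype grid yields one *metagene* expression vector per node. Reshaping a
prototype column gives the mosaic *portrait* of one sample; averaging over
group members and subtracting group means give group and difference
portraits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix


class BatchSOM(ClusterMixin, BaseEstimator):
    """Batch self-organizing map with a Gaussian neighborhood kernel.

    Per epoch every data point is assigned to its nearest prototype
    (Euclidean distance) and each prototype is recomputed as the
    neighborhood-weighted mean of the assigned points. The neighborhood
    radius decays linearly from ``initial_radius`` (default
    ``max(grid_rows, grid_cols) / 2``) to ``final_radius``; a final radius
    of 0.5 makes late epochs approximate a k-means refinement while
    preserving grid topology.

    Initialization spans the plane of the first two principal components of
    the data cloud (deterministic); ``init="random"`` samples data points
    with ``random_state`` instead.

    Attributes
    ----------
    prototypes_ : ndarray of shape (grid_rows * grid_cols, n_features)
        Metagene vectors, 0-based row-major node order.
    labels_ : ndarray of shape (n_points,)
        Best-matching unit (node index) of every data point.
    quantization_errors_ : ndarray of shape (epochs,)
        Mean point-to-BMU distance per epoch, before that epoch's update.
    """

    def __init__(
        self,
        grid_rows: int = 50,
        grid_cols: int = 50,
        epochs: int = 50,
        initial_radius: Optional[float] = None,
        final_radius: float = 0.5,
        init: str = "pca",
        random_state: Optional[int] = None,
    ):
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.epochs = epochs
        self.initial_radius = initial_radius
        self.final_radius = final_radius
        self.init = init
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _grid_sqdist(self) -> np.ndarray:
        rows, cols = np.divmod(np.arange(self.grid_rows * self.grid_cols), self.grid_cols)
        dr = rows[:, None] - rows[None, :]
        dc = cols[:, None] - cols[None, :]
        return (dr**2 + dc**2).astype(float)

    def _init_prototypes(self, X: np.ndarray) -> np.ndarray:
        n_nodes = self.grid_rows * self.grid_cols
        mean = X.mean(axis=0)
        if self.init == "random" or min(X.shape) < 2:
            rng = np.random.default_rng(self.random_state)
            idx = rng.integers(0, X.shape[0], size=n_nodes)
            return X[idx].copy()
        if self.init != "pca":
            raise ValueError(f"unknown init {self.init!r}")
        xc = X - mean
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        dirs = vt[:2].copy()
        # deterministic sign: largest-magnitude component positive
        for d in dirs:
            if d[np.argmax(np.abs(d))] < 0:
                d *= -1
        sds = s[:2] / np.sqrt(max(X.shape[0] - 1, 1))
        a = np.linspace(-2.0, 2.0, self.grid_rows) if self.grid_rows > 1 else np.zeros(1)
        b = np.linspace(-2.0, 2.0, self.grid_cols) if self.grid_cols > 1 else np.zeros(1)
        proto = (
            mean[None, None, :]
            + a[:, None, None] * sds[0] * dirs[0][None, None, :]
            + b[None, :, None] * (sds[1] * dirs[1][None, None, :] if len(s) > 1 else 0.0)
        )
        return proto.reshape(n_nodes, X.shape[1])

    @staticmethod
    def _bmu(X: np.ndarray, proto: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d2 = (
            np.einsum("ij,ij->i", X, X)[:, None]
            - 2.0 * X @ proto.T
            + np.einsum("ij,ij->i", proto, proto)[None, :]
        )
        bmu = np.argmin(d2, axis=1)
        mind2 = np.maximum(d2[np.arange(len(X)), bmu], 0.0)
        return bmu, mind2

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array of data points")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be at least 1 x 1")
        n_nodes = self.grid_rows * self.grid_cols
        proto = self._init_prototypes(X)
        grid_d2 = self._grid_sqdist()
        r0 = (
            self.initial_radius
            if self.initial_radius is not None
            else max(self.grid_rows, self.grid_cols) / 2.0
        )
        r1 = self.final_radius
        qe = np.empty(self.epochs)
        bmu = np.zeros(X.shape[0], dtype=int)
        for t in range(self.epochs):
            frac = t / (self.epochs - 1) if self.epochs > 1 else 1.0
            sigma = max(r0 + (r1 - r0) * frac, 1e-6)
            bmu, mind2 = self._bmu(X, proto)
            qe[t] = float(np.sqrt(mind2).mean())
            h = np.exp(-grid_d2 / (2.0 * sigma**2))
            counts = np.bincount(bmu, minlength=n_nodes).astype(float)
            sums = np.zeros((n_nodes, X.shape[1]))
            np.add.at(sums, bmu, X)
            num = h @ sums
            den = h @ counts
            ok = den > 1e-12
            proto[ok] = num[ok] / den[ok, None]
        self.prototypes_ = proto
        self.labels_, mind2 = self._bmu(X, proto)
        self.quantization_errors_ = qe
        self.quantization_error_ = float(np.sqrt(mind2).mean())
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "prototypes_")
        X = np.asarray(X, dtype=float)
        return self._bmu(X, self.prototypes_)[0]

    def transform(self, X):
        """Distances from each point to every prototype."""
        check_is_fitted(self, "prototypes_")
        X = np.asarray(X, dtype=float)
        d2 = (
            np.einsum("ij,ij->i", X, X)[:, None]
            - 2.0 * X @ self.prototypes_.T
            + np.einsum("ij,ij->i", self.prototypes_, self.prototypes_)[None, :]
        )
        return np.sqrt(np.maximum(d2, 0.0))


# ---------------------------------------------------------------------------


@dataclass
class SOMModel:
    """Trained SOM bound to gene / sample identifiers.

    ``prototypes`` holds metagene expression values (centralized log2),
    shape (grid_rows * grid_cols, n_samples); ``gene_to_node`` maps every
    gene to its best-matching unit, node indices 0-based row-major.
    """

    gene_ids: list
    sample_ids: list
    prototypes: np.ndarray
    gene_to_node: np.ndarray
    grid_rows: int
    grid_cols: int
    training_meta: dict

    def __post_init__(self):
        if self.prototypes.shape[0] != self.grid_rows * self.grid_cols:
            raise ValueError("prototype count must equal grid_rows * grid_cols")
        if len(self.gene_to_node) != len(self.gene_ids):
            raise ValueError("every gene needs exactly one node assignment")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def node_coord(self, node: int) -> tuple[int, int]:
        return divmod(int(node), self.grid_cols)

    def sample_portrait(self, sample_id: str) -> np.ndarray:
        j = self.sample_ids.index(sample_id)
        return self.prototypes[:, j].reshape(self.grid_rows, self.grid_cols)

    def genes_in_nodes(self, nodes: Iterable[int]) -> list:
        nodes = set(int(n) for n in nodes)
        return [g for g, n in zip(self.gene_ids, self.gene_to_node) if int(n) in nodes]

    # ------------------------------------------------------------------ I/O
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.prototypes,
            index=pd.RangeIndex(self.n_nodes, name="node"),
            columns=self.sample_ids,
        ).to_csv(d / "prototypes.tsv", sep="\t")
        pd.DataFrame(
            {"gene_id": self.gene_ids, "node": self.gene_to_node}
        ).to_csv(d / "gene_to_node.tsv", sep="\t", index=False)
        meta = dict(self.training_meta)
        meta.update(grid_rows=self.grid_rows, grid_cols=self.grid_cols)
        (d / "training_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "SOMModel":
        d = Path(directory)
        proto = pd.read_csv(d / "prototypes.tsv", sep="\t", index_col=0)
        g2n = pd.read_csv(d / "gene_to_node.tsv", sep="\t")
        meta = json.loads((d / "training_meta.json").read_text())
        return cls(
            gene_ids=g2n["gene_id"].tolist(),
            sample_ids=list(proto.columns),
            prototypes=proto.to_numpy(),
            gene_to_node=g2n["node"].to_numpy(),
            grid_rows=meta.pop("grid_rows"),
            grid_cols=meta.pop("grid_cols"),
            training_meta=meta,
        )


def train_som(
    m: ExpressionMatrix,
    grid_rows: int = 50,
    grid_cols: int = 50,
    epochs: int = 50,
    seed: int = 0,
    initial_radius: Optional[float] = None,
    final_radius: float = 0.5,
    init: str = "pca",
) -> SOMModel:
    """Train the metagene SOM on a centralized expression matrix."""
    if m.stage != "centralized":
        raise ValueError("train_som expects a centralized matrix; run preprocess first")
    som = BatchSOM(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        epochs=epochs,
        initial_radius=initial_radius,
        final_radius=final_radius,
        init=init,
        random_state=seed,
    ).fit(m.values)
    meta = {
        "seed": seed,
        "epochs": epochs,
        "initial_radius": (
            initial_radius if initial_radius is not None else max(grid_rows, grid_cols) / 2.0
        ),
        "final_radius": final_radius,
        "init": init,
        "quantization_error": som.quantization_error_,
    }
    return SOMModel(
        gene_ids=m.gene_ids,
        sample_ids=m.sample_ids,
        prototypes=som.prototypes_,
        gene_to_node=som.labels_,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        training_meta=meta,
    )


# ---------------------------------------------------------------------------


@dataclass
class Portrait:
    """Grid of metagene values for one sample, group mean or difference."""

    values: np.ndarray
    label: str
    kind: str  # {sample, group_mean, difference, variance, phenotype}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("portrait values must be a 2-D grid")


def portraits(
    model: SOMModel,
    grouping: Optional[pd.Series] = None,
    diff_pairs: Optional[Iterable[tuple]] = "all",
) -> list[Portrait]:
    """Sample portraits, plus group-mean and difference portraits.

    ``grouping`` maps sample id -> group label; ``diff_pairs`` names ordered
    group pairs for difference portraits ("all" = every unordered pair).
    """
    shape = (model.grid_rows, model.grid_cols)
    out = [
        Portrait(model.prototypes[:, j].reshape(shape), sid, "sample")
        for j, sid in enumerate(model.sample_ids)
    ]
    if grouping is None:
        return out
    grouping = pd.Series(grouping)
    unknown = set(grouping.index) - set(model.sample_ids)
    if unknown:
        raise ValueError(f"grouping names unknown samples: {sorted(unknown)}")
    group_means: dict[str, np.ndarray] = {}
    for grp in pd.unique(grouping):
        members = [model.sample_ids.index(s) for s in grouping.index[grouping == grp]]
        group_means[grp] = model.prototypes[:, members].mean(axis=1)
        out.append(Portrait(group_means[grp].reshape(shape), str(grp), "group_mean"))
    if diff_pairs is None:
        return out
    if diff_pairs == "all":
        labels = list(group_means)
        diff_pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    for a, b in diff_pairs:
        out.append(
            Portrait(
                (group_means[a] - group_means[b]).reshape(shape),
                f"{a}-{b}",
                "difference",
            )
        )
    return out


def variance_map(model: SOMModel) -> Portrait:
    """Per-node variance of the metagene value across samples."""
    v = model.prototypes.var(axis=1)
    return Portrait(v.reshape(model.grid_rows, model.grid_cols), "variance", "variance")


def metagene_correlation_edges(
    model: SOMModel, r_threshold: float
) -> list[tuple[int, int, float]]:
    """Unordered node pairs whose metagene profiles correlate with
    ``|r| >= r_threshold``; zero-variance profiles are excluded."""
    if abs(r_threshold) > 1:
        raise ValueError("|r_threshold| must be <= 1")
    sd = model.prototypes.std(axis=1)
    keep = np.flatnonzero(sd > 0)
    if len(keep) < model.n_nodes:
        warnings.warn(
            f"excluding {model.n_nodes - len(keep)} zero-variance node profiles"
        )
    if len(keep) < 2:
        return []
    r = np.corrcoef(model.prototypes[keep])
    iu, ju = np.triu_indices(len(keep), k=1)
    mask = np.abs(r[iu, ju]) >= r_threshold
    return [
        (int(keep[i]), int(keep[j]), float(r[i, j]))
        for i, j in zip(iu[mask], ju[mask])
    ]
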