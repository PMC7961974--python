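"""Over-expression spot modules on the metagene grid.

A *spot* is a connected region of nodes (8-neighborhood) that rises above a
quantile of the over-expression summary map; its member genes are those
whose best-matching unit lies inside, and its profile is the per-sample
mean of the member-node metagene values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import fisher_exact as _scipy_fisher

from .som import Portrait, SOMModel

_EIGHT = np.ones((3, 3), dtype=int)


def _spot_label(i: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if i < 26:
        return letters[i]
    return letters[i // 26 - 1] + letters[i % 26]


@dataclass
class Spot:
    label: str
    member_nodes: set
    member_genes: list
    profile: Optional[np.ndarray]  # per-sample mean of member-node metagenes
    peak_node: int
    peak_height: float


@dataclass
class SpotSet:
    spots: list
    summary_map: Portrait
    threshold: float

    def __iter__(self):
        return iter(self.spots)

    def __len__(self):
        return len(self.spots)

    def __getitem__(self, label: str) -> Spot:
        for s in self.spots:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> list:
        return [s.label for s in self.spots]


def overexpression_summary_map(model: SOMModel) -> Portrait:
    """Per-node maximum of the metagene value over all samples."""
    v = model.prototypes.max(axis=1)
    return Portrait(
        v.reshape(model.grid_rows, model.grid_cols), "overexpression summary", "summary"
    )


def detect_spots(
    summary: Portrait,
    model: Optional[SOMModel] = None,
    quantile_threshold: float = 0.95,
    min_size: int = 5,
) -> SpotSet:
    """Segment the summary map into spots.

    Nodes strictly above the ``quantile_threshold`` quantile of the map are
    foreground; 8-connected components of at least ``min_size`` nodes become
    spots, labeled A, B, ... in decreasing order of peak height. A constant
    map yields no spots (strict inequality leaves no foreground). When a
    model is given, member genes and the spot profile are filled in.
    """
    values = summary.values
    if not np.all(np.isfinite(values)):
        raise ValueError("summary map must be finite")
    thr = float(np.quantile(values, quantile_threshold))
    foreground = values > thr
    labeled, n_comp = ndimage.label(foreground, structure=_EIGHT)
    comps = []
    for c in range(1, n_comp + 1):
        nodes_2d = np.argwhere(labeled == c)
        if len(nodes_2d) < min_size:
            continue
        flat = nodes_2d[:, 0] * values.shape[1] + nodes_2d[:, 1]
        heights = values[nodes_2d[:, 0], nodes_2d[:, 1]]
        peak = int(flat[np.argmax(heights)])
        comps.append((float(heights.max()), peak, set(int(f) for f in flat)))
    comps.sort(key=lambda t: (-t[0], t[1]))
    spots = []
    for i, (height, peak, nodes) in enumerate(comps):
        genes: list = []
        profile = None
        if model is not None:
            genes = model.genes_in_nodes(nodes)
            profile = model.prototypes[sorted(nodes)].mean(axis=0)
        spots.append(
            Spot(
                label=_spot_label(i),
                member_nodes=nodes,
                member_genes=genes,
                profile=profile,
                peak_node=peak,
                peak_height=height,
            )
        )
    return SpotSet(spots=spots, summary_map=summary, threshold=thr)


def spot_activation_table(
    spots: SpotSet,
    model: SOMModel,
    top_fraction: float = 0.10,
    member_fraction: float = 0.5,
) -> pd.DataFrame:
    """Binary spots x samples table.

    A spot is active in a sample when at least ``member_fraction`` of its
    nodes rank within the top ``top_fraction`` of that sample's portrait.
    """
    n_top = max(1, int(np.floor(top_fraction * model.n_nodes)))
    table = pd.DataFrame(
        0, index=spots.labels, columns=model.sample_ids, dtype=int
    )
    for j, sid in enumerate(model.sample_ids):
        order = np.argsort(-model.prototypes[:, j], kind="stable")
        top = set(int(k) for k in order[:n_top])
        for s in spots:
            inside = len(s.member_nodes & top)
            if inside >= member_fraction * len(s.member_nodes):
                table.loc[s.label, sid] = 1
    return table


def spot_cooccurrence(activation: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise co-activation counts and the implication matrix
    ``implication[s, t] = P(t active | s active)`` (0 for never-active s)."""
    a = activation.to_numpy().astype(int)
    counts = a @ a.T
    freq = np.diag(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        implication = np.where(freq[:, None] > 0, counts / freq[:, None], 0.0)
    idx = activation.index
    return (
        pd.DataFrame(counts, index=idx, columns=idx),
        pd.DataFrame(implication, index=idx, columns=idx),
    )


def gene_list_spot_association(
    spots: SpotSet,
    model: SOMModel,
    gene_list: Iterable[str],
    universe: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Accumulation / depletion of a gene list in each spot's gene set.

    Per spot a 2x2 table (in list x in spot) over the universe is tested
    with a two-sided Fisher test; spots with odds ratio > 1 and p < 0.05 are
    called "accumulated", < 1 and p < 0.05 "depleted", else "neutral".
    """
    gene_list = set(gene_list)
    if not gene_list:
        raise ValueError("gene_list must be non-empty")
    universe = set(universe) if universe is not None else set(model.gene_ids)
    if not gene_list <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    rows = []
    for s in spots:
        spot_genes = set(s.member_genes) & universe
        a = len(gene_list & spot_genes)
        b = len(gene_list) - a
        c = len(spot_genes) - a
        d = len(universe) - a - b - c
        odds, p = _scipy_fisher([[a, b], [c, d]], alternative="two-sided")
        expected = len(gene_list) * len(spot_genes) / max(len(universe), 1)
        if p < 0.05 and a > expected:
            call = "accumulated"
        elif p < 0.05 and a < expected:
            call = "depleted"
        else:
            call = "neutral"
        rows.append(
            {
                "spot": s.label,
                "overlap": a,
                "expected": expected,
                "odds_ratio": np.inf if b * c == 0 and a * d > 0 else (
                    np.nan if b * c == 0 else a * d / (b * c)
                ),
                "p": p,
                "call": call,
            }
        )
    columns = ["spot", "overlap", "expected", "odds_ratio", "p", "call"]
    return pd.DataFrame(rows, columns=columns).set_index("spot")
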