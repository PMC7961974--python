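"""Gene-set scoring and enrichment machinery.

The per-sample gene set Z-score (GSZ) standardizes a set's mean centralized
log2 expression against the whole-transcriptome distribution:

    GSZ_j = sqrt(N_S) * (mean_{g in S} de_gj - mean_g de_gj) / sd_g de_gj

where de is centralized log2 expression and N_S the set size inside the
expression universe. Under independence the score is approximately standard
normal, so values beyond +-2 read as clear activation / repression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix
from .spots import SpotSet


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self):
        return len(self.genes)


@dataclass
class GSZProfile:
    name: str
    scores: pd.Series  # per-sample z-scale activity
    group_means: Optional[pd.Series] = None


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file (name, description, genes...; tab-separated).

    Lines with fewer than three fields are skipped with a warning;
    duplicate genes within a line are removed.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"{path}:{lineno}: fewer than 3 fields, skipped")
                continue
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(name=name, description=desc, genes=frozenset(genes)))
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def gsz_score(
    gene_set: GeneSet,
    m: ExpressionMatrix,
    grouping: Optional[pd.Series] = None,
) -> GSZProfile:
    """Per-sample GSZ of one gene set on a centralized matrix."""
    if m.stage != "centralized":
        raise ValueError("gsz_score expects a centralized matrix")
    members = m.data.index.intersection(list(gene_set.genes))
    if len(members) == 0:
        raise ValueError(f"gene set {gene_set.name!r} does not intersect the universe")
    x = m.values
    set_mean = m.data.loc[members].to_numpy().mean(axis=0)
    global_mean = x.mean(axis=0)
    global_sd = x.std(axis=0)
    scores = np.sqrt(len(members)) * (set_mean - global_mean) / global_sd
    scores = pd.Series(scores, index=m.sample_ids, name=gene_set.name)
    group_means = None
    if grouping is not None:
        grouping = pd.Series(grouping)
        group_means = scores.groupby(grouping.loc[scores.index]).mean()
    return GSZProfile(name=gene_set.name, scores=scores, group_means=group_means)


def gsz_matrix(
    sets: Iterable[GeneSet],
    m: ExpressionMatrix,
    grouping: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Sets x samples GSZ table."""
    return pd.DataFrame({s.name: gsz_score(s, m, grouping).scores for s in sets}).T


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)`` with the sample odds ratio ad/bc (infinity
    when bc = 0 and ad > 0, NaN when both products vanish). The p-value sums
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed one. An all-zero table
    gives p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = (int(v) for v in t.ravel())
    if a + b + c + d == 0:
        return np.nan, 1.0
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = a * d / (b * c)
    _, p = _scipy_fisher([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spot_enrichment(
    spots: SpotSet,
    sets: Iterable[GeneSet],
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided (greater) Fisher enrichment of every gene set in every
    spot's member genes, BH-adjusted across sets within each spot."""
    universe = set(universe)
    sets = list(sets)
    rows = []
    for s in spots:
        spot_genes = set(s.member_genes) & universe
        ps = []
        for gs in sets:
            members = gs.genes & universe
            a = len(members & spot_genes)
            b = len(members) - a
            c = len(spot_genes) - a
            d = len(universe) - a - b - c
            _, p = _scipy_fisher([[a, b], [c, d]], alternative="greater")
            ps.append(p)
            rows.append(
                {"spot": s.label, "set": gs.name, "overlap": a,
                 "set_size": len(members), "spot_size": len(spot_genes), "p": p}
            )
        qs = bh_adjust(ps)
        for r, q in zip(rows[-len(sets):], qs):
            r["q"] = q
    columns = ["spot", "set", "overlap", "set_size", "spot_size", "p", "q"]
    return pd.DataFrame(rows, columns=columns).set_index(["spot", "set"])
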