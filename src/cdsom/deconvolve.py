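"""Immune-cell deconvolution and atrophy-axis trajectories.

Bulk mixtures are decomposed over a linear-scale cell-type signature matrix
by non-negative least squares (min ||S f - m|| over f >= 0), then the
coefficient vector is normalized to relative fractions summing to one.
Fraction trajectories along the villous-atrophy axis (samples ordered by
the lower-crypt gene-set score) are smoothed with LOESS (tricube-weighted
local linear regression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import ExpressionMatrix


@dataclass
class CellFractions:
    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    group_means: Optional[pd.DataFrame] = None


@dataclass
class TrajectoryFit:
    x: pd.Series  # ordering score per sample, ascending
    raw: pd.DataFrame  # fractions at the ordered samples
    fitted: pd.DataFrame  # LOESS-smoothed fractions
    span: float


def _check_signature_rank(s: np.ndarray, columns: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(s)
    if rank < s.shape[1]:
        # QR with column pivoting: columns beyond the numerical rank are
        # linearly dependent on the preceding ones
        _, _, piv = qr(s, pivoting=True, mode="economic")
        bad = sorted(str(columns[i]) for i in piv[rank:])
        raise ValueError(
            f"signature matrix is rank-deficient on the shared genes; "
            f"collinear columns: {bad}"
        )


def deconvolve(mixture: pd.Series, signature: pd.DataFrame) -> pd.Series:
    """Relative cell-type fractions of one linear-scale mixture vector."""
    shared = signature.index.intersection(mixture.index)
    n_types = signature.shape[1]
    if len(shared) < n_types:
        raise ValueError(
            f"only {len(shared)} shared genes for {n_types} cell types"
        )
    s = signature.loc[shared].to_numpy(dtype=float)
    _check_signature_rank(s, signature.columns)
    f, _ = nnls(s, mixture.loc[shared].to_numpy(dtype=float))
    total = f.sum()
    if total <= 0:
        raise ValueError("mixture has no support on the signature (all-zero fit)")
    return pd.Series(f / total, index=signature.columns)


def deconvolve_cohort(
    m: ExpressionMatrix,
    signature: pd.DataFrame,
    grouping: Optional[pd.Series] = None,
) -> CellFractions:
    """Per-sample deconvolution of a cohort matrix.

    Log-scale matrices are exponentiated back to linear intensities first;
    centralized matrices cannot be inverted and are rejected.
    """
    if m.stage == "centralized":
        raise ValueError("centralized matrices cannot be converted to linear scale")
    lin = m.values if m.stage == "raw" else np.power(2.0, m.values)
    lin_df = pd.DataFrame(lin, index=m.data.index, columns=m.data.columns)
    rows = {}
    for sid in m.sample_ids:
        try:
            rows[sid] = deconvolve(lin_df[sid], signature)
        except ValueError as exc:
            raise ValueError(f"sample {sid!r}: {exc}") from exc
    fractions = pd.DataFrame(rows).T
    group_means = None
    if grouping is not None:
        grouping = pd.Series(grouping)
        group_means = fractions.groupby(grouping.loc[fractions.index]).mean()
    return CellFractions(fractions=fractions, group_means=group_means)


class NNLSDeconvolution(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: samples x genes -> samples x fractions.

    Parameters
    ----------
    signature : pandas.DataFrame
        Linear-scale genes x cell-types reference matrix.
    """

    def __init__(self, signature: Optional[pd.DataFrame] = None):
        self.signature = signature

    def fit(self, X=None, y=None):
        if self.signature is None:
            raise ValueError("a signature matrix is required")
        _check_signature_rank(
            self.signature.to_numpy(dtype=float), self.signature.columns
        )
        self.cell_types_ = list(self.signature.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cell_types_"):
            self.fit()
        out = {
            sid: deconvolve(X.loc[sid], self.signature) for sid in X.index
        }
        return pd.DataFrame(out).T


def loess_smooth(x, y, span: float = 0.75) -> np.ndarray:
    """LOESS (tricube, local degree-1) fit evaluated at the input x.

    Duplicate x positions are collapsed by averaging y before fitting; the
    fitted value is broadcast back to every duplicate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    ux, inverse = np.unique(x, return_inverse=True)
    if span * len(ux) < 3:
        raise ValueError("span * n must be at least 3")
    uy = np.bincount(inverse, weights=y) / np.bincount(inverse)
    fitted_u = lowess(uy, ux, frac=span, it=0, return_sorted=False)
    return fitted_u[inverse]


def atrophy_trajectory(
    fractions: CellFractions,
    ordering_scores: pd.Series,
    cell_types: Optional[Sequence[str]] = None,
    span: float = 0.75,
) -> TrajectoryFit:
    """Cell-fraction curves along the atrophy axis.

    Samples are ordered by ``ordering_scores`` (per-sample activity of the
    lower-crypt set); each requested cell type's fraction profile is
    LOESS-smoothed along that ordering.
    """
    frac = fractions.fractions
    missing = set(frac.index) - set(ordering_scores.index)
    if missing:
        raise ValueError(f"ordering scores missing for samples: {sorted(missing)}")
    order = ordering_scores.loc[frac.index].sort_values(kind="stable").index
    x = ordering_scores.loc[order]
    if cell_types is None:
        cell_types = list(frac.columns)
    raw = frac.loc[order, list(cell_types)]
    fitted = pd.DataFrame(
        {ct: loess_smooth(x.to_numpy(), raw[ct].to_numpy(), span=span) for ct in cell_types},
        index=order,
    )
    return TrajectoryFit(x=x, raw=raw, fitted=fitted, span=span)
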