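"""Raw intensity -> centralized log2 preprocessing.

The portrayal pipeline consumes quantile-normalized, gene-centralized log2
expression: every sample is forced onto one common intensity distribution
(removing sample-wide distortions such as labeling or scanning efficiency)
and every gene row is shifted to mean zero so values read as log2 fold
changes versus the cohort mean (denoted delta-e).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import ExpressionMatrix


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform raw intensities, clamping values below 1 to 1."""
    x = m.values
    if not np.all(np.isfinite(x)):
        raise ValueError("raw matrix contains non-finite values")
    y = np.log2(np.maximum(x, 1.0))
    return m.with_values(y, stage="log2")


def _quantile_normalize_values(x: np.ndarray) -> np.ndarray:
    """Map every column onto the mean of the column-sorted value vectors.

    Ties within a column receive the mean of the reference values at their
    tied ranks (average-rank dialect).
    """
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        # average ranks are half-integers; linear interpolation between the
        # two flanking reference values equals the mean over the tied block
        out[:, j] = np.interp(ranks, positions, reference)
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples of a log2 matrix.

    With a single sample there is nothing to align; the matrix is returned
    unchanged (stage still advances) with a warning.
    """
    if m.n_samples < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input")
        return m.with_values(m.values.copy(), stage="normalized")
    return m.with_values(_quantile_normalize_values(m.values), stage="normalized")


def centralize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples (rows -> mean zero)."""
    x = m.values
    return m.with_values(x - x.mean(axis=1, keepdims=True), stage="centralized")


def preprocess(m: ExpressionMatrix) -> ExpressionMatrix:
    """Full chain: log2 -> quantile normalize -> centralize."""
    return centralize(quantile_normalize(log_transform(m)))


class ExpressionPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer over genes x samples arrays.

    Parameters
    ----------
    log : bool, default True
        Apply the clamped log2 transform.
    quantile : bool, default True
        Quantile-normalize sample columns.
    center : bool, default True
        Centralize gene rows to mean zero.
    """

    def __init__(self, log: bool = True, quantile: bool = True, center: bool = True):
        self.log = log
        self.quantile = quantile
        self.center = center

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D genes x samples array")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.log:
            X = np.log2(np.maximum(X, 1.0))
        if self.quantile and X.shape[1] >= 2:
            X = _quantile_normalize_values(X)
        if self.center:
            X = X - X.mean(axis=1, keepdims=True)
        return X
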