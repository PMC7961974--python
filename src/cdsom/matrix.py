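"""Expression matrix container and TSV round-trip.

The universal payload between pipeline stages is a genes x samples table of
real values carrying a *stage* tag that records how far along the
log2 -> quantile-normalized -> gene-centralized preprocessing chain it is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Preprocessing stages in pipeline order.
STAGES = ("raw", "log2", "normalized", "centralized")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with a preprocessing stage tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are genes (index = gene ids), columns are samples. Values are
        intensities on the scale implied by ``stage``.
    stage : str
        One of :data:`STAGES`.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not self.data.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("sample ids must be unique")
        # reject non-numeric payloads early
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"expression values must be numeric: {exc}") from exc

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray, stage: str) -> "ExpressionMatrix":
        """Return a new matrix with the same ids, new values and stage."""
        if np.shape(values) != self.data.shape:
            raise ValueError("replacement values must keep the matrix shape")
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(df, stage=stage)

    def advance_stage(self, stage: str) -> "ExpressionMatrix":
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage may not move backwards ({self.stage} -> {stage})")
        return replace(self, stage=stage)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, stage: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, stage=stage)
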