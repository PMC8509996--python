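"""Expression-matrix handling: batch correction, filtering, correlation.

Expression values are kept on their normalized scale (RPKM/FPKM for genes,
TPM for mature miRNAs); an optional log2 transform is exposed but off by
default. Batch effects are removed by fitting, per row, a linear model with
an intercept, condition effects and batch blocking terms, then reconstructing
the values with the batch coefficients set to zero. Batch columns are coded
as centered dummies, which makes the correction exactly mean-preserving per
row and idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "remove_batch_effects", "filter_expressed", "pearson"]


@dataclass
class ExpressionMatrix:
    """Rows (genes / pre-miRNAs / mature miRNAs) x samples real matrix.

    ``batch`` and ``condition`` map sample id -> label; samples absent from a
    map default to a single level.
    """

    values: pd.DataFrame
    batch: dict = field(default_factory=dict)
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.values, np.ndarray):
            self.values = pd.DataFrame(self.values)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    @property
    def col_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def batch_labels(self) -> list:
        return [self.batch.get(c, "batch0") for c in self.col_ids]

    def condition_labels(self) -> list:
        return [self.condition.get(c, "cond0") for c in self.col_ids]

    def subset_rows(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)], self.batch, self.condition)

    def log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        return ExpressionMatrix(
            np.log2(self.values + pseudocount), self.batch, self.condition
        )


def _dummies(labels, drop_first: bool, center: bool) -> np.ndarray:
    levels = sorted(set(labels))
    if drop_first:
        levels = levels[1:]
    cols = []
    for lev in levels:
        col = np.asarray([1.0 if l == lev else 0.0 for l in labels])
        if center:
            col = col - col.mean()
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(labels), 0))


def remove_batch_effects(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove additive batch effects via a blocking-term linear model.

    Per row, value ~ intercept + condition + batch is fit by least squares
    (two-way additive model, no interaction); the batch blocking terms are
    then zeroed and the values recomputed from the remaining terms plus
    residuals. Single batch -> input returned unchanged (logged). Batch
    perfectly aliased with condition -> error.
    """
    batches = m.batch_labels()
    if len(set(batches)) < 2:
        logger.info("single batch; no correction applied")
        return ExpressionMatrix(m.values.copy(), m.batch, m.condition)
    conds = m.condition_labels()

    X_cond = _dummies(conds, drop_first=True, center=False)
    X_batch = _dummies(batches, drop_first=True, center=True)
    n = len(batches)
    design = np.column_stack([np.ones(n), X_cond, X_batch])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "batch structure is confounded with condition (aliased design); "
            "batch effects cannot be separated from condition effects"
        )

    Y = m.values.to_numpy(dtype=float)  # rows x samples
    coef, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # (1+c+b) x rows
    n_batch = X_batch.shape[1]
    batch_part = X_batch @ coef[-n_batch:, :]  # samples x rows
    corrected = Y - batch_part.T
    out = pd.DataFrame(corrected, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, m.batch, m.condition)


def filter_expressed(m: ExpressionMatrix, min_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep rows expressed (value > 0) in at least ``min_fraction`` of samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = (m.values > 0).mean(axis=1)
    keep = frac >= min_fraction - 1e-12
    return ExpressionMatrix(m.values.loc[keep], m.batch, m.condition)


def pearson(x, y) -> float:
    """Sample Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)
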