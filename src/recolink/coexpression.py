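"""Coexpression layers from expression matrices.

Each expression dataset (genes x samples) becomes one unweighted graph
layer: an edge connects two genes when the Pearson correlation of their
expression profiles is significant at a p-value cutoff (0.01 by default).
Only the significance of the correlation matters -- an edge is never added
for a strong but non-significant correlation, and by default both strongly
positive and strongly negative correlations qualify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .graph_core import LayerGraph, Link

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression_tsv",
    "correlation_test",
    "build_coexpression_layer",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix for one dataset."""

    dataset_id: str
    genes: tuple
    samples: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels in expression matrix")
        if np.isnan(vals).any():
            raise ValueError("expression matrix contains missing values "
                             "after loading")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "samples", tuple(self.samples))

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def read_expression_tsv(path: str | Path,
                        dataset_id: str | None = None) -> ExpressionMatrix:
    """Read an expression TSV: first column gene id, header row of sample
    names.  Rows with any missing value are dropped (with a logged count)."""
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    dropped = n_before - len(df)
    if dropped:
        logger.info("%s: dropped %d gene rows with missing values",
                    path.name, dropped)
    return ExpressionMatrix(
        dataset_id=dataset_id,
        genes=tuple(str(g) for g in df.index),
        samples=tuple(str(s) for s in df.columns),
        values=df.to_numpy(dtype=float),
    )


def correlation_test(x: np.ndarray, y: np.ndarray) -> tuple:
    """Pearson correlation and its two-sided p-value.

    The p-value comes from the t statistic ``t = r * sqrt((n-2)/(1-r^2))``
    with ``n - 2`` degrees of freedom; ``|r| = 1`` gives ``p = 0``.  A
    constant input vector has no defined correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("vectors must have equal length")
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, min(p, 1.0)


def _pvalue_matrix(values: np.ndarray) -> tuple:
    """All-pairs correlation and p-value matrices for rows of ``values``.

    Rows with zero variance get NaN correlations (and p = NaN), which the
    caller treats as non-significant.
    """
    n = values.shape[1]
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def build_coexpression_layer(expr: ExpressionMatrix, p_cutoff: float = 0.01,
                             positive_only: bool = False) -> LayerGraph:
    """Build the unweighted coexpression layer for one dataset.

    An edge joins genes i and j iff their correlation p-value is <= the
    cutoff (inclusive).  Pairs involving a constant-expression gene are
    excluded.  With ``positive_only`` the edge additionally requires r > 0.
    """
    if not (0.0 < p_cutoff < 1.0):
        raise ValueError(f"p_cutoff must be in (0, 1), got {p_cutoff}")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples to build a coexpression layer")
    r, p = _pvalue_matrix(expr.values)
    sig = p <= p_cutoff
    if positive_only:
        sig &= r > 0
    sig = np.triu(sig, k=1)
    ii, jj = np.nonzero(sig)
    edges = frozenset(Link(expr.genes[i], expr.genes[j]) for i, j in zip(ii, jj))
    return LayerGraph(layer_id=expr.dataset_id, edges=edges)
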