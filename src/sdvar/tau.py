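"""Pseudo-bulk aggregation and the tau expression-specificity index.

Raw single-cell counts are summed within each cell-type label to give one
pseudo-bulk profile per type; each profile is scaled to counts per million
and log2(CPM + 1) transformed. For a gene with per-type expression vector x,

    tau = sum(1 - x / max(x)) / (len(x) - 1),

which is 0 for perfectly uniform expression and 1 for expression exclusive
to a single type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PseudoBulk", "pseudobulk", "tau", "tau_profile"]


@dataclass
class PseudoBulk:
    counts: pd.DataFrame  # cell type x gene, summed raw counts
    cpm: pd.DataFrame  # rows sum to 1e6
    log2_cpm: pd.DataFrame  # log2(CPM + 1)


def pseudobulk(sc_counts: pd.DataFrame, cell_labels: pd.Series) -> PseudoBulk:
    """Sum cells x genes counts within each cell type and CPM-normalize."""
    labels = cell_labels.reindex(sc_counts.index)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()[:5]
        raise ValueError(f"unlabeled cells, e.g. {missing}")
    if labels.nunique() < 2:
        raise ValueError("need at least two cell types")
    agg = sc_counts.groupby(labels).sum()
    totals = agg.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("a cell type has zero total counts")
    cpm = agg.mul(1e6 / totals, axis=0)
    return PseudoBulk(counts=agg, cpm=cpm, log2_cpm=np.log2(cpm + 1.0))


def tau(expr) -> float:
    """Specificity of one expression vector across contexts; NaN if all zero."""
    x = np.asarray(expr, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expr must be a vector over at least two contexts")
    if np.any(x < 0):
        raise ValueError("expression must be nonnegative")
    m = x.max()
    if m == 0:
        return float("nan")
    x_hat = x / m
    return float(np.sum(1.0 - x_hat) / (x.size - 1))


def tau_profile(sc_counts: pd.DataFrame, cell_labels: pd.Series) -> pd.Series:
    """Per-gene tau on log2(CPM + 1) pseudo-bulk profiles."""
    pb = pseudobulk(sc_counts, cell_labels)
    X = pb.log2_cpm.to_numpy()
    m = X.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (1.0 - X / m).sum(axis=0) / (X.shape[0] - 1)
    t = np.where(m > 0, t, np.nan)
    return pd.Series(t, index=pb.log2_cpm.columns, name="tau")
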