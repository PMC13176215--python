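"""Differential expression between disease and non-disease groups.

Welch's unequal-variance t-test per gene, Benjamini-Hochberg FDR control,
log2 fold change as the difference of class means (the matrix is already on
the log2 scale), and dual-threshold selection: FDR < 0.05 and |log2FC| > 0.5,
both strict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "welch_t",
    "benjamini_hochberg",
    "log2_fold_change",
    "deg_table",
    "select_degs",
]

FDR_MAX_DEFAULT = 0.05
LFC_MIN_DEFAULT = 0.5


def welch_t(x, y):
    """Welch's two-sided t-test; returns ``(t_stat, p_raw)``.

    Groups with zero variance in both arms yield t = 0, p = 1 so downstream
    FDR correction stays well defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        return (0.0, 1.0) if x.mean() == y.mean() else (np.inf * np.sign(x.mean() - y.mean()), 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def benjamini_hochberg(p_values):
    """Step-up BH adjusted values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def log2_fold_change(matrix: pd.DataFrame, class_of_sample) -> pd.Series:
    """Per-gene mean over class-1 samples minus mean over class-0 samples."""
    cls = pd.Series(class_of_sample).loc[matrix.columns]
    g1 = matrix.loc[:, (cls == 1).to_numpy()]
    g0 = matrix.loc[:, (cls == 0).to_numpy()]
    if g1.shape[1] == 0 or g0.shape[1] == 0:
        raise ValueError("both classes must be non-empty")
    return g1.mean(axis=1) - g0.mean(axis=1)


def deg_table(
    matrix: pd.DataFrame,
    class_of_sample,
    fdr_max: float = FDR_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
) -> pd.DataFrame:
    """Full per-gene table: log2fc, t, p, fdr, direction, selected.

    Welch's test is vectorized over genes; zero-variance-in-both-groups genes
    receive p = 1.
    """
    cls = pd.Series(class_of_sample).loc[matrix.columns]
    X1 = matrix.loc[:, (cls == 1).to_numpy()].to_numpy(dtype=float)
    X0 = matrix.loc[:, (cls == 0).to_numpy()].to_numpy(dtype=float)
    if X1.shape[1] < 2 or X0.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(X1, X0, axis=1, equal_var=False)
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    lfc = X1.mean(axis=1) - X0.mean(axis=1)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "p": p,
            "fdr": benjamini_hochberg(p),
        },
        index=matrix.index.rename("gene"),
    )
    return select_degs(table, fdr_max=fdr_max, lfc_min=lfc_min)


def select_degs(
    table: pd.DataFrame,
    fdr_max: float = FDR_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
) -> pd.DataFrame:
    """Apply the dual strict thresholds and set direction/selected columns."""
    table = table.copy()
    selected = (table["fdr"] < fdr_max) & (table["log2fc"].abs() > lfc_min)
    direction = np.where(
        selected & (table["log2fc"] > 0),
        "up",
        np.where(selected & (table["log2fc"] < 0), "down", "none"),
    )
    table["direction"] = direction
    table["selected"] = selected
    return table
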