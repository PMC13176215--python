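"""Cross-dataset harmonization of log2 expression matrices.

Per-dataset preprocessing (probe collapsing, gene intersection, quantile
normalization), parametric empirical-Bayes batch correction treating each
dataset as a batch, and PCA-based diagnostics of residual batch structure.

Matrices are pandas DataFrames with genes in rows (unique symbols) and
samples in columns, on the log2 scale throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizationReport",
    "collapse_probes",
    "intersect_genes",
    "quantile_normalize",
    "combat_correct",
    "pca_batch_diagnostics",
    "harmonize_cohorts",
]

#: floor applied to pooled and per-batch variances so zero-variance genes
#: do not produce division by zero during standardization
VARIANCE_FLOOR = 1e-8


@dataclass
class HarmonizationReport:
    """Batch-structure diagnostics before and after correction."""

    pc1_variance_before: float
    pc1_variance_after: float
    batch_assoc_before: float
    batch_assoc_after: float
    n_common_genes: int

    def __post_init__(self):
        for name in (
            "pc1_variance_before",
            "pc1_variance_after",
            "batch_assoc_before",
            "batch_assoc_after",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} must be a proportion in [0, 1]: {v}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def collapse_probes(values: pd.DataFrame, probe_to_symbol: dict) -> pd.DataFrame:
    """Average probe rows mapping to the same gene symbol.

    Probes absent from ``probe_to_symbol`` are dropped; each output gene row
    is the arithmetic mean of its probes' rows.
    """
    if not probe_to_symbol:
        raise ValueError("probe_to_symbol mapping is empty")
    mapped = values.loc[values.index.intersection(list(probe_to_symbol))]
    if mapped.empty:
        raise ValueError("no probe in the matrix maps to a symbol")
    symbols = mapped.index.map(probe_to_symbol)
    collapsed = mapped.groupby(symbols, sort=True).mean()
    collapsed.index.name = values.index.name
    return collapsed


def intersect_genes(matrices: list) -> list:
    """Restrict every matrix to the lexicographically sorted common gene set."""
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].index)
    for m in matrices[1:]:
        common &= set(m.index)
    if not common:
        raise ValueError("empty gene intersection across matrices")
    order = sorted(common)
    return [m.loc[order] for m in matrices]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common per-rank mean distribution.

    The reference distribution is the mean of the sorted columns; within-column
    rank order is preserved, and tied values receive the mean of the reference
    values over the tied span (deterministic, order-independent).
    """
    if matrix.shape[1] < 2:
        logger.warning("quantile_normalize: single sample, returned unchanged")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = reference.copy()
        # resolve ties: average the reference over each run of equal values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        for start, stop in zip(
            np.concatenate([[0], boundaries]),
            np.concatenate([boundaries, [len(col)]]),
        ):
            if stop - start > 1:
                ranked[start:stop] = ranked[start:stop].mean()
        out[order, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _batch_series(matrix: pd.DataFrame, batch_of_sample) -> pd.Series:
    batch = pd.Series(batch_of_sample)
    missing = [s for s in matrix.columns if s not in batch.index]
    if missing:
        raise ValueError(f"samples without batch assignment: {missing[:5]}")
    return batch.loc[matrix.columns]


def combat_correct(
    matrix: pd.DataFrame,
    batch_of_sample,
    tol: float = 1e-4,
    max_iter: int = 100,
    check_batches: bool = True,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch correction.

    Implements the classic ComBat procedure with an intercept-only model:
    gene-wise standardization against the pooled mean and variance, per-batch
    estimation of additive (gamma) and multiplicative (delta^2) effects,
    shrinkage of gamma toward a batch-level normal prior and delta^2 toward an
    inverse-gamma prior (both fitted by moment matching across genes), with the
    posterior pair iterated to convergence, followed by back-transformation.
    """
    batch = _batch_series(matrix, batch_of_sample)
    counts = batch.value_counts()
    if check_batches:
        if len(counts) < 2:
            raise ValueError("combat_correct requires at least 2 batches")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"batch with a single sample: {sorted(small.index.tolist())}"
            )
    elif len(counts) < 2:
        logger.warning("combat_correct: single batch, returning input unchanged")
        return matrix.copy()

    Y = matrix.to_numpy(dtype=float)
    n_genes, n_samples = Y.shape
    batch_names = sorted(counts.index.tolist())
    masks = {b: (batch == b).to_numpy() for b in batch_names}
    n_i = {b: int(masks[b].sum()) for b in batch_names}

    batch_means = np.column_stack([Y[:, masks[b]].mean(axis=1) for b in batch_names])
    weights = np.array([n_i[b] / n_samples for b in batch_names])
    grand_mean = batch_means @ weights

    fitted = np.zeros_like(Y)
    for k, b in enumerate(batch_names):
        fitted[:, masks[b]] = batch_means[:, [k]]
    var_pooled = ((Y - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, VARIANCE_FLOOR)

    Z = (Y - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    adjusted = np.empty_like(Z)
    for b in batch_names:
        Zb = Z[:, masks[b]]
        n = n_i[b]
        gamma_hat = Zb.mean(axis=1)
        if n > 1:
            delta_hat = Zb.var(axis=1, ddof=1)
        else:
            delta_hat = np.ones(n_genes)
        delta_hat = np.maximum(delta_hat, VARIANCE_FLOOR)

        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1) if n_genes > 1 else 1.0
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1) if n_genes > 1 else 1.0
        s2 = max(s2, VARIANCE_FLOOR)
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            gamma_new = (n * tau2 * gamma_hat + delta_star * gamma_bar) / (
                n * tau2 + delta_star
            )
            sum_sq = ((Zb - gamma_new[:, None]) ** 2).sum(axis=1)
            delta_new = (0.5 * sum_sq + b_prior) / (n / 2.0 + a_prior - 1.0)
            delta_new = np.maximum(delta_new, VARIANCE_FLOOR)
            change = max(
                np.abs(gamma_new - gamma_star).max(),
                np.abs(delta_new - delta_star).max(),
            )
            gamma_star, delta_star = gamma_new, delta_new
            if change < tol:
                break
        adjusted[:, masks[b]] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[
            :, None
        ]

    corrected = adjusted * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    return pd.DataFrame(corrected, index=matrix.index, columns=matrix.columns)


def pca_batch_diagnostics(matrix: pd.DataFrame, batch_of_sample) -> dict:
    """PC1 variance share and one-way batch R^2 on PC1 scores.

    PCA is run on gene-centered data across samples; the batch association is
    the fraction of PC1-score variance explained by a one-way grouping on the
    batch label.
    """
    if matrix.shape[1] < 3:
        raise ValueError("pca_batch_diagnostics requires at least 3 samples")
    batch = _batch_series(matrix, batch_of_sample)
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=1)
    scores = pca.fit_transform(X)[:, 0]
    pc1_share = float(pca.explained_variance_ratio_[0])

    total_ss = ((scores - scores.mean()) ** 2).sum()
    if total_ss <= 0:
        r2 = 0.0
    else:
        within = 0.0
        for b in batch.unique():
            s = scores[(batch == b).to_numpy()]
            within += ((s - s.mean()) ** 2).sum()
        r2 = float(1.0 - within / total_ss)
    return {"pc1_variance": pc1_share, "batch_assoc": max(0.0, min(1.0, r2))}


def harmonize_cohorts(
    matrices: list,
    batch_names: list,
    tol: float = 1e-4,
) -> tuple:
    """Full harmonization: per-dataset quantile normalization, gene
    intersection, ComBat across datasets; returns (matrix, report)."""
    if len(matrices) != len(batch_names):
        raise ValueError("one batch name per matrix required")
    normed = [quantile_normalize(m) for m in matrices]
    normed = intersect_genes(normed)
    merged = pd.concat(normed, axis=1)
    if merged.columns.duplicated().any():
        raise ValueError("duplicate sample ids across datasets")
    batch_map = {}
    for m, b in zip(normed, batch_names):
        for s in m.columns:
            batch_map[s] = b
    before = pca_batch_diagnostics(merged, batch_map)
    corrected = combat_correct(merged, batch_map, tol=tol)
    after = pca_batch_diagnostics(corrected, batch_map)
    report = HarmonizationReport(
        pc1_variance_before=before["pc1_variance"],
        pc1_variance_after=after["pc1_variance"],
        batch_assoc_before=before["batch_assoc"],
        batch_assoc_after=after["batch_assoc"],
        n_common_genes=merged.shape[0],
    )
    return corrected, report
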