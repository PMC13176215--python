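"""Permutation significance and bootstrap stability of CV performance.

The permutation test shuffles class labels before fold assignment each
iteration, reruns the full cross-validation pipeline, and uses the smoothed
estimator p = (1 + #{permuted AUC >= true AUC}) / (n_iter + 1), so p < 0.001
is attainable at 1,000 iterations only when no permutation beats the truth.

Bootstrap confidence intervals resample pooled out-of-fold (label,
probability) pairs with replacement within each class and report percentile
intervals; this avoids refitting models per replicate (a ``refit`` variant
is available at reduced iteration counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .ensemble import compute_metrics, rank_auc, run_cv

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "permutation_test",
    "bootstrap_ci",
    "bootstrap_ci_refit",
]


@dataclass
class PermutationResult:
    true_auc: float
    mean_permuted_auc: float
    p_value: float
    n_iter: int
    permuted_aucs: list | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("permuted_aucs")
        return d


@dataclass
class BootstrapResult:
    metric: str
    mean: float
    ci_low: float
    ci_high: float
    level: float
    n_iter: int

    def __post_init__(self):
        if not self.ci_low <= self.mean <= self.ci_high:
            # percentile intervals can exclude the point estimate only through
            # Monte-Carlo noise; flag loudly rather than fail
            logger.warning(
                "bootstrap mean %s outside [%s, %s] for %s",
                self.mean,
                self.ci_low,
                self.ci_high,
                self.metric,
            )

    def as_dict(self) -> dict:
        return asdict(self)


def permutation_test(
    X: pd.DataFrame,
    y,
    n_iter: int = 1000,
    seed: int = 0,
    k: int = 5,
    model: str = "ensemble",
    search: bool = False,
    fixed_params: dict | None = None,
    keep_null: bool = False,
) -> PermutationResult:
    """Label-permutation test of the out-of-fold CV AUC.

    ``model`` selects which column of the CV result is tested (one of rf,
    gbt, svm, ensemble).  Permutation CV uses fixed modest hyperparameters
    by default; pass ``search=True`` to tune inside every permutation.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y = np.asarray(y)
    true_cv = run_cv(X, y, k=k, seed=seed, search=search, fixed_params=fixed_params)
    true_auc = true_cv.metrics[model].auc
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_iter)
    for i in range(n_iter):
        y_perm = rng.permutation(y)
        cv = run_cv(
            X,
            y_perm,
            k=k,
            seed=int(rng.integers(2**31 - 1)),
            search=search,
            fixed_params=fixed_params,
        )
        permuted[i] = cv.metrics[model].auc
    p = (1 + int((permuted >= true_auc).sum())) / (n_iter + 1)
    return PermutationResult(
        true_auc=float(true_auc),
        mean_permuted_auc=float(permuted.mean()),
        p_value=float(p),
        n_iter=n_iter,
        permuted_aucs=permuted.tolist() if keep_null else None,
    )


def bootstrap_ci(
    y,
    proba,
    n_iter: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    metrics: tuple = ("auc", "f1"),
) -> list:
    """Percentile bootstrap CIs for metrics of pooled out-of-fold predictions.

    Resampling is stratified: (label, probability) pairs are drawn with
    replacement within each class, so every replicate retains both classes.
    """
    y = np.asarray(y)
    proba = np.asarray(proba, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    stats_rows = {m: np.empty(n_iter) for m in metrics}
    for b in range(n_iter):
        take = np.concatenate(
            [
                rng.choice(idx1, size=len(idx1), replace=True),
                rng.choice(idx0, size=len(idx0), replace=True),
            ]
        )
        yb, pb = y[take], proba[take]
        for m in metrics:
            if m == "auc":
                stats_rows[m][b] = rank_auc(yb, pb)
            else:
                stats_rows[m][b] = getattr(compute_metrics(yb, pb), m)
    return _percentile_results(stats_rows, metrics, level, n_iter)


def _percentile_results(stats_rows, metrics, level, n_iter):
    alpha = (1.0 - level) / 2.0
    out = []
    for m in metrics:
        vals = stats_rows[m]
        out.append(
            BootstrapResult(
                metric=m,
                mean=float(vals.mean()),
                ci_low=float(np.quantile(vals, alpha)),
                ci_high=float(np.quantile(vals, 1 - alpha)),
                level=level,
                n_iter=n_iter,
            )
        )
    return out


def bootstrap_ci_refit(
    X: pd.DataFrame,
    y,
    n_iter: int = 100,
    level: float = 0.95,
    seed: int = 0,
    k: int = 5,
    metrics: tuple = ("auc", "f1"),
    fixed_params: dict | None = None,
) -> list:
    """Expensive bootstrap variant: resample samples (stratified, with
    replacement), rerun the full CV per replicate.  Meant for reduced
    iteration counts; pair-resampling (:func:`bootstrap_ci`) is the default
    elsewhere."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    stats_rows = {m: np.empty(n_iter) for m in metrics}
    for b in range(n_iter):
        take = np.concatenate(
            [
                rng.choice(idx1, size=len(idx1), replace=True),
                rng.choice(idx0, size=len(idx0), replace=True),
            ]
        )
        Xb = X.iloc[take].copy()
        # resampled duplicates need unique ids for the sorted-id fold keying
        Xb.index = [f"{s}_b{i}" for i, s in enumerate(Xb.index)]
        cv = run_cv(Xb, y[take], k=k, seed=int(rng.integers(2**31 - 1)),
                    search=False, fixed_params=fixed_params)
        rep = cv.metrics["ensemble"]
        for m in metrics:
            stats_rows[m][b] = getattr(rep, m)
    return _percentile_results(stats_rows, metrics, level, n_iter)
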