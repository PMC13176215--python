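"""Shapley attribution for the ensemble and derived gene-level scores.

Per-model explainers:

* random forest — an in-package implementation of path-dependent Tree SHAP
  (the polynomial-time EXTEND/UNWIND algorithm) applied to each tree's
  class-1 probability and averaged, so attributions plus the cover-weighted
  expected value reproduce the forest's predicted probability exactly;
* gradient-boosted trees — XGBoost's native Tree SHAP (``pred_contribs``),
  which explains the log-odds margin; per-sample attributions are rescaled
  by (p - expit(base)) / (margin - base) so they sum exactly to the
  predicted probability;
* kernel margin classifier (SVM) — an in-package Kernel SHAP: coalitions are
  enumerated exhaustively when feasible, otherwise sampled from the Shapley
  kernel, hybrids are imputed against a background sample, and the weighted
  least squares is solved under the efficiency constraint so local accuracy
  holds by construction.

Consensus attribution is the elementwise arithmetic mean of the three
matrices; by linearity it satisfies local accuracy against the soft-vote
probability whenever each base explainer does.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionMatrix",
    "tree_shap_values",
    "forest_expected_value",
    "explain_base_model",
    "explain_ensemble",
    "consensus_attributions",
    "global_importance",
    "cross_cohort_consistency",
    "mechanosensitivity",
    "kernel_shap",
]

MECHANO_CUT_HIGH = 0.6
MECHANO_CUT_LOW = 0.3


@dataclass
class AttributionMatrix:
    """Samples x genes Shapley values with a base value and a model tag.

    Local accuracy: base_value + row sum equals the model's predicted
    probability for that sample (exact for the tree explainers, enforced by
    the efficiency constraint for the sampling explainer).
    """

    values: pd.DataFrame
    base_value: float
    model_tag: str

    def local_accuracy_error(self, proba) -> float:
        recon = self.base_value + self.values.to_numpy().sum(axis=1)
        return float(np.max(np.abs(recon - np.asarray(proba))))


# ---------------------------------------------------------------------------
# path-dependent Tree SHAP (EXTEND / UNWIND)


class _Tree:
    """Minimal array view of a decision tree for SHAP traversal."""

    def __init__(self, children_left, children_right, feature, threshold,
                 leaf_value, node_weight):
        self.left = np.asarray(children_left)
        self.right = np.asarray(children_right)
        self.feature = np.asarray(feature)
        self.threshold = np.asarray(threshold, dtype=float)
        self.value = np.asarray(leaf_value, dtype=float)
        self.weight = np.asarray(node_weight, dtype=float)

    @classmethod
    def from_sklearn(cls, tree, class_index: int = 1):
        t = tree.tree_
        raw = t.value[:, 0, :]
        totals = raw.sum(axis=1)
        prob = np.where(totals > 0, raw[:, class_index] / np.where(totals > 0, totals, 1.0), 0.0)
        return cls(t.children_left, t.children_right, t.feature, t.threshold,
                   prob, t.weighted_n_node_samples)

    def expected_value(self) -> float:
        leaves = self.left == -1
        return float((self.value[leaves] * self.weight[leaves]).sum() / self.weight[0])


def _extend(d, z, o, w, pz, po, pi):
    l = len(d)
    d.append(pi)
    z.append(pz)
    o.append(po)
    w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1) / (l + 1)
        w[i] = pz * w[i] * (l - i) / (l + 1)


def _unwind(d, z, o, w, i0):
    l = len(d)
    one, zero = o[i0], z[i0]
    n = w[l - 1]
    # the weight recursion must run over the whole path, not stop at the
    # removed element: weights of earlier elements change too
    for j in range(l - 2, -1, -1):
        if one != 0:
            t = w[j]
            w[j] = n * l / ((j + 1) * one)
            n = t - w[j] * zero * (l - j - 1) / l
        else:
            w[j] = w[j] * l / (zero * (l - j - 1))
    for j in range(i0, l - 1):
        d[j] = d[j + 1]
        z[j] = z[j + 1]
        o[j] = o[j + 1]
    d.pop(); z.pop(); o.pop(); w.pop()


def _unwound_sum(d, z, o, w, i0) -> float:
    dd, zz, oo, ww = list(d), list(z), list(o), list(w)
    _unwind(dd, zz, oo, ww, i0)
    return sum(ww)


def tree_shap_values(tree: _Tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact path-dependent Shapley values of a single tree for one sample."""
    phi = np.zeros(n_features)

    def recurse(j, d, z, o, w, pz, po, pi):
        d, z, o, w = list(d), list(z), list(o), list(w)
        _extend(d, z, o, w, pz, po, pi)
        if tree.left[j] == -1:
            for i in range(1, len(d)):
                s = _unwound_sum(d, z, o, w, i)
                phi[d[i]] += s * (o[i] - z[i]) * tree.value[j]
            return
        f = tree.feature[j]
        if x[f] <= tree.threshold[j]:
            hot, cold = tree.left[j], tree.right[j]
        else:
            hot, cold = tree.right[j], tree.left[j]
        iz, io = 1.0, 1.0
        k = next((i for i in range(len(d)) if d[i] == f), None)
        if k is not None:
            iz, io = z[k], o[k]
            _unwind(d, z, o, w, k)
        rj = tree.weight[j]
        recurse(hot, d, z, o, w, iz * tree.weight[hot] / rj, io, f)
        recurse(cold, d, z, o, w, iz * tree.weight[cold] / rj, 0.0, f)

    recurse(0, [], [], [], [], 1.0, 1.0, -1)
    return phi


def forest_expected_value(forest) -> float:
    return float(np.mean([_Tree.from_sklearn(e).expected_value()
                          for e in forest.estimators_]))


def _explain_forest(forest, X_std: np.ndarray) -> tuple:
    trees = [_Tree.from_sklearn(e) for e in forest.estimators_]
    n, m = X_std.shape
    phi = np.zeros((n, m))
    for t in trees:
        for i in range(n):
            phi[i] += tree_shap_values(t, X_std[i], m)
    phi /= len(trees)
    base = float(np.mean([t.expected_value() for t in trees]))
    return phi, base


# ---------------------------------------------------------------------------
# Kernel SHAP


def _kernel_weight(m: int, s: int) -> float:
    return (m - 1) / (math.comb(m, s) * s * (m - s))


def kernel_shap(
    predict,
    x: np.ndarray,
    background: np.ndarray,
    n_coalitions: int = 1000,
    seed: int = 0,
) -> tuple:
    """Kernel SHAP for one sample; returns (phi, base_value).

    ``predict`` maps an (n, M) array to a probability vector.  Coalitions of
    size 1..M-1 are enumerated exhaustively when 2^M - 2 <= n_coalitions,
    otherwise sampled from the Shapley kernel (size drawn proportional to
    (M-1)/(s(M-s)), members uniform).  Hybrid rows impute coalition features
    from ``x`` into each background row; the weighted least squares is solved
    with the efficiency constraint eliminated, so phi sums exactly to
    f(x) - base.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    m = x.size
    base = float(np.mean(predict(background)))
    fx = float(predict(x[None, :])[0])
    if m == 1:
        return np.array([fx - base]), base

    rng = np.random.default_rng(seed)
    if 2**m - 2 <= n_coalitions:
        masks = np.zeros((2**m - 2, m), dtype=bool)
        weights = np.empty(len(masks))
        row = 0
        for s in range(1, m):
            for combo in combinations(range(m), s):
                masks[row, list(combo)] = True
                weights[row] = _kernel_weight(m, s)
                row += 1
    else:
        sizes = np.arange(1, m)
        size_p = (m - 1) / (sizes * (m - sizes))
        size_p = size_p / size_p.sum()
        drawn = rng.choice(sizes, size=n_coalitions, p=size_p)
        masks = np.zeros((n_coalitions, m), dtype=bool)
        for row, s in enumerate(drawn):
            masks[row, rng.choice(m, size=s, replace=False)] = True
        weights = np.ones(n_coalitions)

    # coalition values: mean prediction over background-imputed hybrids
    n_bg = background.shape[0]
    hybrids = np.repeat(background[None, :, :], len(masks), axis=0)
    hybrids[masks[:, None, :].repeat(n_bg, axis=1)] = np.broadcast_to(
        x, (len(masks), n_bg, m)
    )[masks[:, None, :].repeat(n_bg, axis=1)]
    preds = predict(hybrids.reshape(-1, m)).reshape(len(masks), n_bg)
    v = preds.mean(axis=1) - base

    # efficiency-constrained WLS: phi_last = (fx - base) - sum(others)
    Z = masks.astype(float)
    A = Z[:, :-1] - Z[:, [-1]]
    t = v - Z[:, -1] * (fx - base)
    sw = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], t * sw, rcond=None)
    phi = np.empty(m)
    phi[:-1] = coef
    phi[-1] = (fx - base) - coef.sum()
    return phi, base


# ---------------------------------------------------------------------------
# per-model explainers


def _split_pipeline(model):
    return model.named_steps["scaler"], model.named_steps["clf"]


def stratified_background(X: pd.DataFrame, y, size: int = 50, seed: int = 0) -> pd.DataFrame:
    """Class-stratified subsample of the training split used as the
    background distribution for the sampling-based explainer."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    parts = []
    classes = np.unique(y)
    per_class = max(1, size // len(classes))
    for c in classes:
        idx = np.flatnonzero(y == c)
        take = rng.choice(idx, size=min(per_class, len(idx)), replace=False)
        parts.append(X.iloc[take])
    return pd.concat(parts)


def explain_base_model(
    model,
    X: pd.DataFrame,
    background: pd.DataFrame | None = None,
    model_tag: str = "rf",
    n_coalitions: int = 1000,
    seed: int = 0,
) -> AttributionMatrix:
    """Shapley attribution of one fitted base pipeline on ``X``.

    ``model`` is a scaler+classifier pipeline from :func:`cdikit.ensemble.fit_fold`;
    attributions are reported per gene in the pipeline's input space (the
    standardizer is feature-wise, so gene identity is preserved).
    """
    scaler, clf = _split_pipeline(model)
    if X.shape[1] != scaler.n_features_in_:
        raise ValueError(
            f"feature mismatch: matrix has {X.shape[1]} features, "
            f"model expects {scaler.n_features_in_}"
        )
    X_std = scaler.transform(X.to_numpy(dtype=float))

    if model_tag == "rf":
        phi, base = _explain_forest(clf, X_std)
    elif model_tag == "gbt":
        booster = clf.get_booster()
        import xgboost as xgb

        contribs = booster.predict(
            xgb.DMatrix(X_std), pred_contribs=True, validate_features=False
        )
        margin_phi, margin_base = contribs[:, :-1], contribs[:, -1]
        margin = contribs.sum(axis=1)
        p = expit(margin)
        p_base = expit(margin_base)
        denom = margin - margin_base
        factor = np.where(np.abs(denom) > 1e-12, (p - p_base) / np.where(denom == 0, 1.0, denom), 0.0)
        phi = margin_phi * factor[:, None]
        base = float(p_base[0])
    elif model_tag == "svm":
        if background is None:
            raise ValueError("the sampling-based explainer requires a background")
        bg_std = scaler.transform(background.to_numpy(dtype=float))
        predict = lambda A: clf.predict_proba(A)[:, 1]
        phis, bases = [], []
        for i in range(X_std.shape[0]):
            ph, b = kernel_shap(
                predict, X_std[i], bg_std, n_coalitions=n_coalitions,
                seed=seed + i,
            )
            phis.append(ph)
            bases.append(b)
        phi, base = np.vstack(phis), float(bases[0])
    else:
        raise ValueError(f"unknown model tag {model_tag!r}")

    return AttributionMatrix(
        values=pd.DataFrame(phi, index=X.index, columns=X.columns),
        base_value=float(base),
        model_tag=model_tag,
    )


def explain_ensemble(
    ensemble,
    X: pd.DataFrame,
    background: pd.DataFrame,
    n_coalitions: int = 1000,
    seed: int = 0,
) -> dict:
    """Attribution matrices for all three base models plus the consensus."""
    X = X.loc[:, ensemble.feature_names]
    background = background.loc[:, ensemble.feature_names]
    out = {}
    for tag in ("rf", "gbt", "svm"):
        out[tag] = explain_base_model(
            ensemble.models[tag], X, background=background, model_tag=tag,
            n_coalitions=n_coalitions, seed=seed,
        )
    out["consensus"] = consensus_attributions([out["rf"], out["gbt"], out["svm"]])
    return out


def consensus_attributions(matrices: list) -> AttributionMatrix:
    """Elementwise arithmetic mean of the base attribution matrices."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape or \
                list(m.values.columns) != list(first.values.columns) or \
                list(m.values.index) != list(first.values.index):
            raise ValueError("attribution matrices must share sample/gene ordering")
    values = sum(m.values.to_numpy() for m in matrices) / len(matrices)
    base = sum(m.base_value for m in matrices) / len(matrices)
    return AttributionMatrix(
        values=pd.DataFrame(values, index=first.values.index,
                            columns=first.values.columns),
        base_value=base,
        model_tag="consensus",
    )


# ---------------------------------------------------------------------------
# derived gene-level scores


def global_importance(attrib: AttributionMatrix) -> pd.DataFrame:
    """Mean |SHAP| per gene with 1-based descending ranks, ties broken
    lexicographically by symbol."""
    if attrib.values.empty:
        raise ValueError("empty attribution matrix")
    mean_abs = attrib.values.abs().mean(axis=0)
    order = sorted(mean_abs.index, key=lambda g: (-mean_abs[g], str(g)))
    table = pd.DataFrame({"mean_abs_shap": mean_abs.loc[order]})
    table.index.name = "gene"
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def cross_cohort_consistency(rankings: dict, k: int = 20) -> dict:
    """Pairwise Spearman rho of mean-|SHAP| vectors and per-gene top-k counts.

    ``rankings`` maps cohort name to a :func:`global_importance` table; all
    tables must share a common gene universe.
    """
    names = list(rankings)
    shared = set(rankings[names[0]].index)
    for n in names[1:]:
        shared &= set(rankings[n].index)
    if not shared:
        raise ValueError("cohorts share no genes")
    genes = sorted(shared)
    vectors = {n: rankings[n].loc[genes, "mean_abs_shap"].to_numpy() for n in names}
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                r = stats.spearmanr(vectors[a], vectors[b]).statistic
                rho.loc[a, b] = rho.loc[b, a] = float(r)
    top_counts = pd.Series(0, index=pd.Index(genes, name="gene"))
    for n in names:
        topk = rankings[n].index[rankings[n]["rank"] <= k]
        top_counts.loc[top_counts.index.intersection(topk)] += 1
    return {"spearman": rho, "top_k_counts": top_counts, "k": k}


def mechanosensitivity(attrib: AttributionMatrix, strain_mask) -> pd.DataFrame:
    """Per-gene mechanosensitivity from strain-cohort attributions.

    raw_diff(g) = |mean SHAP over strained samples - mean over controls|;
    scores are the min-max normalization of raw_diff across genes; categories
    use strict cuts (> 0.6 high, < 0.3 low, boundary values moderate).
    """
    mask = np.asarray(strain_mask, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both strain and control groups must be non-empty")
    vals = attrib.values.to_numpy()
    raw = np.abs(vals[mask].mean(axis=0) - vals[~mask].mean(axis=0))
    span = raw.max() - raw.min()
    if span == 0:
        logger.warning("mechanosensitivity: all raw differences equal; scores set to 0")
        score = np.zeros_like(raw)
    else:
        score = (raw - raw.min()) / span
    category = np.where(
        score > MECHANO_CUT_HIGH, "high",
        np.where(score < MECHANO_CUT_LOW, "low", "moderate"),
    )
    return pd.DataFrame(
        {"raw_diff": raw, "score": score, "category": category},
        index=attrib.values.columns.rename("gene"),
    ).sort_values("raw_diff", ascending=False)
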