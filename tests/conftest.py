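"""Shared fixtures and independent brute-force oracles.

The oracles here recompute Shapley values, AUC and hypergeometric tails by
exhaustive enumeration; they must stay independent of the package code paths
they check.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cdikit import attribution, ensemble
from cdikit.synthetic import CohortSpec, generate_multibatch_expression


# ---------------------------------------------------------------------------
# independent oracles


def tree_conditional_expectation(tree, x, S, j=0):
    """Value function of path-dependent tree Shapley: descend the tree,
    averaging by node cover whenever the split feature is outside S."""
    if tree.left[j] == -1:
        return tree.value[j]
    f = tree.feature[j]
    if f in S:
        nxt = tree.left[j] if x[f] <= tree.threshold[j] else tree.right[j]
        return tree_conditional_expectation(tree, x, S, nxt)
    l, r = tree.left[j], tree.right[j]
    wl, wr = tree.weight[l], tree.weight[r]
    return (
        wl * tree_conditional_expectation(tree, x, S, l)
        + wr * tree_conditional_expectation(tree, x, S, r)
    ) / (wl + wr)


def exhaustive_shapley(value_fn, m):
    """Shapley values by full enumeration of all 2^m coalitions."""
    phi = np.zeros(m)
    for i in range(m):
        others = [f for f in range(m) if f != i]
        for k in range(m):
            for S in itertools.combinations(others, k):
                w = (
                    math.factorial(len(S))
                    * math.factorial(m - len(S) - 1)
                    / math.factorial(m)
                )
                phi[i] += w * (value_fn(set(S) | {i}) - value_fn(set(S)))
    return phi


def brute_force_auc(y, proba):
    """Fraction of concordant positive/negative pairs, ties counted half."""
    y = np.asarray(y)
    proba = np.asarray(proba, dtype=float)
    pos = proba[y == 1]
    neg = proba[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def hypergeom_upper_tail(N, K, n, k):
    """P(X >= k) by exact summation of binomial coefficients."""
    total = 0
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


# ---------------------------------------------------------------------------
# shared cohorts / models (session-scoped: several modules reuse them)


@pytest.fixture(scope="session")
def separable_xy():
    """Single-batch balanced cohort, 93 features all carrying signal; the
    regime where the ensemble should separate nearly perfectly."""
    spec = CohortSpec(
        n_genes=93,
        n_datasets=1,
        n_train_datasets=1,
        samples_per_condition={"healthy": 60, "advanced": 60},
        batch_shift_sd=0.0,
        batch_scale_sd=0.0,
        n_deg_up=74,
        n_deg_down=19,
        n_mechano=0,
        strain_samples_per_group=0,
        deg_effect=1.5,
        seed=42,
    )
    expression, metadata, _ = generate_multibatch_expression(spec)
    return expression.T, metadata["class"].to_numpy()


@pytest.fixture(scope="session")
def light_cv(separable_xy):
    X, y = separable_xy
    return ensemble.run_cv(X, y, seed=7, search=False)


@pytest.fixture(scope="session")
def mechano_setup():
    """Default-condition cohort with strain mini-cohort, trained light
    ensemble, and consensus attributions on the strain samples."""
    spec = CohortSpec(batch_shift_sd=0.0, batch_scale_sd=0.0, seed=1)
    expression, metadata, truth = generate_multibatch_expression(spec)
    features = truth.deg_symbols
    train = metadata.index[metadata["role"] == "train"]
    X_train = expression.loc[features, train].T
    y_train = metadata.loc[train, "class"].to_numpy()
    model = ensemble.fit_fold(X_train, y_train, search=False, seed=1)
    strain_meta = metadata[metadata["role"] == "strain"]
    X_strain = expression.loc[features, strain_meta.index].T
    strain_mask = (strain_meta["condition"] == "strain").to_numpy()
    background = attribution.stratified_background(X_train, y_train, size=30, seed=1)
    attribs = attribution.explain_ensemble(
        model, X_strain, background, n_coalitions=2000, seed=1
    )
    return {
        "spec": spec,
        "truth": truth,
        "model": model,
        "X_train": X_train,
        "y_train": y_train,
        "X_strain": X_strain,
        "strain_mask": strain_mask,
        "background": background,
        "attribs": attribs,
        "expression": expression,
        "metadata": metadata,
    }


@pytest.fixture(scope="session")
def toy_forest():
    """Small 3-feature random forest plus the data it was fitted on."""
    from sklearn.ensemble import RandomForestClassifier

    rng = np.random.default_rng(0)
    X = rng.normal(size=(80, 3))
    y = (X[:, 0] + 0.5 * X[:, 1] - 0.3 * X[:, 2] + 0.3 * rng.normal(size=80) > 0)
    rf = RandomForestClassifier(n_estimators=7, max_depth=4, random_state=0)
    rf.fit(X, y.astype(int))
    return rf, X


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
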