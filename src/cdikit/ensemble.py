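"""Soft-voting ensemble classifier and the Cartilage Degradation Index.

Three base learners spanning distinct paradigms — bagged trees (random
forest), gradient-boosted trees (XGBoost) and a kernel margin classifier
(SVM with Platt-calibrated probabilities) — are tuned by randomized search
on the training split only, with feature standardization fitted strictly
inside each cross-validation fold.  The ensemble class-1 probability is the
equal-weight arithmetic mean of the base probabilities and is used directly
as the CDI, a continuous 0-1 severity score with risk zones
[0, 0.2] low, (0.2, 0.5] intermediate, (0.5, 0.8) elevated, [0.8, 1] high.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import loguniform, randint, uniform
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "MODEL_NAMES",
    "HYPERPARAM_SPACE",
    "LIGHT_PARAMS",
    "EnsembleModel",
    "MetricsReport",
    "stratified_kfold",
    "fit_fold",
    "soft_vote",
    "rank_auc",
    "compute_metrics",
    "run_cv",
    "CVResult",
    "ablation",
    "compute_cdi",
    "cdi_zone",
    "summarize_cdi",
]

MODEL_NAMES = ("rf", "gbt", "svm")

#: randomized-search spaces for the three base learners; multiplicative
#: parameters (learning rate, gamma, C) are sampled log-uniformly
HYPERPARAM_SPACE = {
    "rf": {
        "clf__n_estimators": randint(100, 501),
        "clf__max_depth": [3, 5, 7, 10, None],
        "clf__max_features": ["sqrt", "log2", 0.3, 0.4, 0.5, 0.6, 0.7],
    },
    "gbt": {
        "clf__n_estimators": randint(50, 401),
        "clf__max_depth": randint(2, 9),
        "clf__learning_rate": loguniform(0.01, 0.31),
        "clf__subsample": uniform(0.5, 0.5),
    },
    "svm": {
        "clf__estimator__C": loguniform(0.01, 50),
        "clf__estimator__gamma": loguniform(1e-4, 1e-1),
        "clf__estimator__kernel": ["rbf", "linear"],
    },
}

#: fixed modest configurations used where the search is not the point
#: (permutation nulls, quick CV) — small forests and shallow boosters
LIGHT_PARAMS = {
    "rf": {"n_estimators": 40, "max_depth": 4, "max_features": "sqrt"},
    "gbt": {"n_estimators": 40, "max_depth": 2, "learning_rate": 0.25, "subsample": 0.9},
    "svm": {"C": 1.0, "gamma": "scale", "kernel": "rbf"},
}


def _base_estimator(name: str, seed: int, params: dict | None = None):
    params = dict(params or {})
    if name == "rf":
        clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    elif name == "gbt":
        clf = XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
            **params,
        )
    elif name == "svm":
        # Platt-style sigmoid calibration fitted on the training split only
        clf = CalibratedClassifierCV(
            SVC(random_state=seed, **params), method="sigmoid", cv=3,
            ensemble=False,
        )
    else:
        raise ValueError(f"unknown base model {name!r}")
    return Pipeline([("scaler", StandardScaler()), ("clf", clf)])


@dataclass
class EnsembleModel:
    """Three fitted probabilistic base pipelines plus the soft-vote contract.

    Each pipeline carries its own standardizer fitted on the training split
    only; voting weights are fixed at 1/3.
    """

    models: dict
    feature_names: list
    seed: int
    weights: tuple = (1 / 3, 1 / 3, 1 / 3)

    def _check_features(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        return X.loc[:, self.feature_names]

    def predict_proba_base(self, X: pd.DataFrame) -> pd.DataFrame:
        """Class-1 probability of each base model (columns rf, gbt, svm)."""
        X = self._check_features(X)
        return pd.DataFrame(
            {name: self.models[name].predict_proba(X.to_numpy())[:, 1]
             for name in MODEL_NAMES},
            index=X.index,
        )

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return soft_vote(self.predict_proba_base(X).to_numpy())


def soft_vote(probas) -> np.ndarray:
    """Equal-weight arithmetic mean of base-model class probabilities.

    Accepts a (n_samples, n_models) array or a sequence of per-model vectors.
    """
    arr = np.asarray(probas, dtype=float)
    if arr.ndim == 1:
        return float(arr.mean())
    if arr.ndim == 2:
        return arr.mean(axis=1)
    raise ValueError("probas must be 1- or 2-dimensional")


def stratified_kfold(labels, k: int = 5, seed: int = 0):
    """Stratified fold assignment; each fold's class ratio is within one
    sample of the global ratio.  Returns a list of (train_idx, test_idx)."""
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ValueError(
            f"every class needs >= k={k} members (counts: {counts.to_dict()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def fit_fold(
    train_X: pd.DataFrame,
    train_y,
    space: dict | None = None,
    n_iter: int = 80,
    seed: int = 0,
    search: bool = True,
    fixed_params: dict | None = None,
) -> EnsembleModel:
    """Fit the three base models on one training split.

    With ``search=True`` each base model is tuned by randomized search
    (``n_iter`` draws, inner 3-fold stratified CV on the training split)
    then refitted on the full split with the best parameters.  With
    ``search=False`` the fixed parameter sets (default ``LIGHT_PARAMS``)
    are used directly.
    """
    y = np.asarray(train_y)
    if len(np.unique(y)) < 2:
        raise ValueError("training split contains a single class")
    space = HYPERPARAM_SPACE if space is None else space
    fixed = LIGHT_PARAMS if fixed_params is None else fixed_params
    Xv = train_X.to_numpy(dtype=float)
    models = {}
    for i, name in enumerate(MODEL_NAMES):
        model_seed = seed + 1000 * i
        if search:
            inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=model_seed)
            rs = RandomizedSearchCV(
                _base_estimator(name, model_seed),
                space[name],
                n_iter=n_iter,
                scoring="roc_auc",
                cv=inner,
                random_state=model_seed,
                n_jobs=1,
                refit=True,
            )
            rs.fit(Xv, y)
            models[name] = rs.best_estimator_
        else:
            est = _base_estimator(name, model_seed, fixed[name])
            est.fit(Xv, y)
            models[name] = est
    return EnsembleModel(models=models, feature_names=list(train_X.columns), seed=seed)


def save_model(model: EnsembleModel, path) -> None:
    """Persist a fitted ensemble as a versioned archive (feature list,
    per-model fitted pipelines with their standardizer statistics, seed)."""
    import joblib

    joblib.dump(
        {
            "format_version": 1,
            "feature_names": model.feature_names,
            "seed": model.seed,
            "weights": model.weights,
            "models": model.models,
        },
        path,
    )


def load_model(path) -> EnsembleModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model archive version: "
                         f"{payload.get('format_version')!r}")
    return EnsembleModel(
        models=payload["models"],
        feature_names=payload["feature_names"],
        seed=payload["seed"],
        weights=tuple(payload["weights"]),
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    brier: float
    train_auc: float | None = None
    cv_train_gap: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def rank_auc(y, proba) -> float:
    """ROC AUC by the rank (Mann-Whitney) formulation with tie correction."""
    y = np.asarray(y)
    proba = np.asarray(proba, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(proba)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(y, proba, threshold: float = 0.5) -> MetricsReport:
    y = np.asarray(y)
    proba = np.asarray(proba, dtype=float)
    pred = (proba >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsReport(
        accuracy=(tp + tn) / len(y),
        precision=precision,
        recall=recall,
        f1=f1,
        auc=rank_auc(y, proba),
        brier=float(np.mean((proba - y) ** 2)),
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Pooled out-of-fold probabilities and per-model metrics."""

    oof: pd.DataFrame  # columns rf, gbt, svm, ensemble; index = sample ids
    y: pd.Series
    metrics: dict = field(default_factory=dict)
    folds: list = field(default_factory=list)


def run_cv(
    X: pd.DataFrame,
    y,
    k: int = 5,
    seed: int = 0,
    n_iter: int = 80,
    search: bool = True,
    fixed_params: dict | None = None,
) -> CVResult:
    """Stratified k-fold CV of the soft-voting ensemble.

    Fold assignment is keyed to lexicographically sorted sample ids so the
    result is invariant to input row order.  Metrics are computed on the
    pooled out-of-fold predictions; the training AUC is averaged over folds
    and reported with the CV-train gap.
    """
    order = np.argsort(X.index.to_numpy())
    X = X.iloc[order]
    y = pd.Series(np.asarray(y)[order], index=X.index)
    folds = stratified_kfold(y.to_numpy(), k=k, seed=seed)
    oof = pd.DataFrame(
        np.nan, index=X.index, columns=list(MODEL_NAMES) + ["ensemble"]
    )
    train_aucs = {name: [] for name in list(MODEL_NAMES) + ["ensemble"]}
    for train_idx, test_idx in folds:
        model = fit_fold(
            X.iloc[train_idx],
            y.iloc[train_idx],
            n_iter=n_iter,
            seed=seed,
            search=search,
            fixed_params=fixed_params,
        )
        base_te = model.predict_proba_base(X.iloc[test_idx])
        oof.iloc[test_idx, : len(MODEL_NAMES)] = base_te.to_numpy()
        oof.iloc[test_idx, -1] = soft_vote(base_te.to_numpy())
        base_tr = model.predict_proba_base(X.iloc[train_idx])
        y_tr = y.iloc[train_idx].to_numpy()
        for name in MODEL_NAMES:
            train_aucs[name].append(rank_auc(y_tr, base_tr[name]))
        train_aucs["ensemble"].append(rank_auc(y_tr, soft_vote(base_tr.to_numpy())))

    metrics = {}
    for name in list(MODEL_NAMES) + ["ensemble"]:
        rep = compute_metrics(y.to_numpy(), oof[name].to_numpy())
        rep.train_auc = float(np.mean(train_aucs[name]))
        rep.cv_train_gap = rep.train_auc - rep.auc
        metrics[name] = rep
    return CVResult(oof=oof, y=y, metrics=metrics, folds=folds)


def ablation(cv: CVResult) -> pd.DataFrame:
    """Metrics for all 7 non-empty base-model combinations.

    Voting over a subset is the arithmetic mean of its members' out-of-fold
    probabilities; singletons bypass voting.
    """
    from itertools import combinations

    rows = []
    for r in range(1, len(MODEL_NAMES) + 1):
        for combo in combinations(MODEL_NAMES, r):
            if len(combo) == 0:
                raise ValueError("empty model subset")
            proba = cv.oof[list(combo)].to_numpy().mean(axis=1)
            rep = compute_metrics(cv.y.to_numpy(), proba)
            rows.append({"configuration": "+".join(combo), **rep.as_dict()})
    return pd.DataFrame(rows).drop(columns=["train_auc", "cv_train_gap"])


# ---------------------------------------------------------------------------
# CDI


def cdi_zone(cdi: float) -> str:
    if not 0.0 <= cdi <= 1.0:
        raise ValueError(f"CDI outside [0, 1]: {cdi}")
    if cdi <= 0.2:
        return "low"
    if cdi <= 0.5:
        return "intermediate"
    if cdi < 0.8:
        return "elevated"
    return "high"


def compute_cdi(
    model: EnsembleModel, X_new: pd.DataFrame, conditions=None
) -> pd.DataFrame:
    """CDI records (cdi, zone, condition) for new samples.

    The CDI is the soft-vote probability of the fitted ensemble; each base
    pipeline applies its own stored standardizer.
    """
    cdi = model.predict_proba(X_new)
    records = pd.DataFrame({"cdi": cdi}, index=X_new.index)
    records["zone"] = [cdi_zone(c) for c in cdi]
    if conditions is not None:
        records["condition"] = pd.Series(conditions).loc[X_new.index].to_numpy()
    return records


def summarize_cdi(records: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Grouped mean/SD/count of the CDI; singleton groups report SD 0 with a
    ``singleton`` flag."""
    grouped = records.groupby(by)["cdi"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["singleton"] = out["n"] == 1
    out["sd"] = out["sd"].fillna(0.0)
    return out
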