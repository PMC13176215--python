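"""Shapley attribution: tree/kernel explainers against exhaustive oracles,
consensus linearity, rankings, consistency, mechanosensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdikit.attribution import (
    AttributionMatrix,
    _Tree,
    consensus_attributions,
    cross_cohort_consistency,
    explain_base_model,
    global_importance,
    kernel_shap,
    mechanosensitivity,
    tree_shap_values,
)
from cdikit.ensemble import soft_vote
from conftest import exhaustive_shapley, tree_conditional_expectation


class TestTreeShap:
    def test_matches_exhaustive_coalition_shapley(self, toy_forest):
        rf, X = toy_forest
        for est in rf.estimators_:
            tree = _Tree.from_sklearn(est)
            for i in range(8):
                fast = tree_shap_values(tree, X[i], 3)
                slow = exhaustive_shapley(
                    lambda S: tree_conditional_expectation(tree, X[i], S), 3
                )
                np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_local_accuracy_against_forest_probability(self, toy_forest):
        rf, X = toy_forest
        Xdf = pd.DataFrame(X[:15], columns=["a", "b", "c"])
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        scaler = StandardScaler().fit(X[:15])
        pipe = Pipeline([("scaler", scaler), ("clf", rf)])
        # refit forest on scaled data so pipeline and explainer agree
        pipe.fit(X[:60], (X[:60, 0] > 0).astype(int))
        attrib = explain_base_model(pipe, Xdf, model_tag="rf")
        proba = pipe.predict_proba(Xdf.to_numpy())[:, 1]
        assert attrib.local_accuracy_error(proba) < 1e-6

    def test_constant_tree_gives_zero_attributions(self):
        # single-leaf tree: no splits, constant output
        tree = _Tree([-1], [-1], [-2], [0.0], [0.7], [10.0])
        phi = tree_shap_values(tree, np.zeros(3), 3)
        np.testing.assert_allclose(phi, 0.0)
        assert tree.expected_value() == pytest.approx(0.7)


class TestXGBoostExplainer:
    def test_local_accuracy_in_probability_space(self, separable_xy):
        X, y = separable_xy
        from cdikit.ensemble import fit_fold

        model = fit_fold(X.iloc[::2], y[::2], search=False, seed=0)
        attrib = explain_base_model(model.models["gbt"], X.iloc[1::2][:20],
                                    model_tag="gbt")
        proba = model.models["gbt"].predict_proba(
            X.iloc[1::2][:20].to_numpy())[:, 1]
        assert attrib.local_accuracy_error(proba) < 1e-4


class TestKernelShap:
    @staticmethod
    def _f(A):
        return 1 / (1 + np.exp(-(A[:, 0] + 2 * A[:, 1] * A[:, 2] - 0.5 * A[:, 3])))

    def test_enumeration_matches_exhaustive_shapley(self, rng):
        bg = rng.normal(size=(8, 4))
        x = rng.normal(size=4)

        def value(S):
            h = bg.copy()
            idx = sorted(S)
            if idx:
                h[:, idx] = x[idx]
            return float(self._f(h).mean())

        phi, base = kernel_shap(self._f, x, bg, n_coalitions=10**6, seed=0)
        np.testing.assert_allclose(phi, exhaustive_shapley(value, 4), atol=1e-10)
        assert base == pytest.approx(value(set()))

    def test_sampled_regime_keeps_exact_efficiency(self, rng):
        bg = rng.normal(size=(10, 9))
        x = rng.normal(size=9)
        phi, base = kernel_shap(self._f4pad(), x, bg, n_coalitions=200, seed=1)
        fx = self._f4pad()(x[None, :])[0]
        assert phi.sum() + base == pytest.approx(fx, abs=1e-10)

    @classmethod
    def _f4pad(cls):
        return lambda A: cls._f(A[:, :4])

    def test_irrelevant_features_near_zero(self, rng):
        bg = rng.normal(size=(10, 6))
        x = rng.normal(size=6)
        f = lambda A: A[:, 0]  # model uses feature 0 only
        phi, _ = kernel_shap(f, x, bg, n_coalitions=10**6, seed=2)
        np.testing.assert_allclose(phi[1:], 0.0, atol=1e-10)

    def test_constant_model_all_zero(self, rng):
        f = lambda A: np.full(len(A), 0.3)
        phi, base = kernel_shap(f, rng.normal(size=5),
                                rng.normal(size=(6, 5)), seed=3)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)
        assert base == pytest.approx(0.3)


class TestConsensus:
    def _matrices(self, rng, n=6, m=4):
        idx = [f"s{i}" for i in range(n)]
        cols = [f"g{j}" for j in range(m)]
        return [
            AttributionMatrix(
                values=pd.DataFrame(rng.normal(size=(n, m)), index=idx,
                                    columns=cols),
                base_value=float(rng.uniform()),
                model_tag=t,
            )
            for t in ("rf", "gbt", "svm")
        ]

    def test_mean_of_identical_matrices_is_identity(self, rng):
        ms = self._matrices(rng)
        same = [ms[0], ms[0], ms[0]]
        out = consensus_attributions(same)
        pd.testing.assert_frame_equal(out.values, ms[0].values)

    def test_matches_elementwise_oracle(self, rng):
        ms = self._matrices(rng)
        out = consensus_attributions(ms)
        expected = (ms[0].values + ms[1].values + ms[2].values) / 3
        pd.testing.assert_frame_equal(out.values, expected)
        assert out.base_value == pytest.approx(
            np.mean([m.base_value for m in ms])
        )

    def test_shape_mismatch_rejected(self, rng):
        ms = self._matrices(rng)
        ms[2] = AttributionMatrix(ms[2].values.iloc[:, :2], 0.0, "svm")
        with pytest.raises(ValueError):
            consensus_attributions(ms)

    def test_consensus_local_accuracy_vs_soft_vote(self, mechano_setup):
        """Linearity: consensus base + row sums reproduce the ensemble
        soft-vote probability."""
        attribs = mechano_setup["attribs"]
        model = mechano_setup["model"]
        proba = soft_vote(
            model.predict_proba_base(mechano_setup["X_strain"]).to_numpy()
        )
        assert attribs["consensus"].local_accuracy_error(proba) < 1e-2


class TestGlobalImportance:
    def test_absolute_mean_and_null_column(self):
        values = pd.DataFrame(
            {"a": [0.2, -0.2], "b": [0.0, 0.0], "c": [0.5, 0.5]},
            index=["s1", "s2"],
        )
        table = global_importance(AttributionMatrix(values, 0.0, "consensus"))
        assert table.loc["a", "mean_abs_shap"] == pytest.approx(0.2)
        assert table.loc["b", "mean_abs_shap"] == 0.0
        assert table["rank"].tolist() == [1, 2, 3]
        assert table.index.tolist() == ["c", "a", "b"]

    def test_matches_column_oracle_with_lexicographic_ties(self, rng):
        values = pd.DataFrame(rng.normal(size=(10, 5)),
                              columns=list("edcba"))
        table = global_importance(AttributionMatrix(values, 0.0, "rf"))
        expected = values.abs().mean(axis=0)
        for g in values.columns:
            assert table.loc[g, "mean_abs_shap"] == pytest.approx(expected[g])
        assert sorted(table["rank"]) == [1, 2, 3, 4, 5]


class TestConsistency:
    def _ranking(self, scores, genes):
        m = AttributionMatrix(
            pd.DataFrame([scores], columns=genes), 0.0, "consensus"
        )
        return global_importance(m)

    def test_identical_rankings(self):
        genes = [f"g{i}" for i in range(30)]
        scores = np.linspace(1, 0.01, 30)
        rankings = {c: self._ranking(scores, genes) for c in "abcde"}
        rep = cross_cohort_consistency(rankings, k=20)
        assert (rep["spearman"].to_numpy() == pytest.approx(1.0))
        top = rep["top_k_counts"]
        assert (top[top > 0] == 5).all() and (top > 0).sum() == 20

    def test_reversed_ranking_is_antitone(self):
        genes = [f"g{i}" for i in range(20)]
        scores = np.linspace(1, 0.01, 20)
        rankings = {
            "a": self._ranking(scores, genes),
            "b": self._ranking(scores[::-1], genes),
        }
        rep = cross_cohort_consistency(rankings)
        assert rep["spearman"].loc["a", "b"] == pytest.approx(-1.0)

    def test_random_rankings_center_at_zero(self, rng):
        genes = [f"g{i}" for i in range(93)]
        rhos = []
        for _ in range(100):
            rankings = {
                c: self._ranking(rng.uniform(size=93), genes) for c in "ab"
            }
            rhos.append(
                cross_cohort_consistency(rankings)["spearman"].loc["a", "b"]
            )
        assert abs(np.mean(rhos)) < 0.1

    def test_disjoint_universes_rejected(self):
        a = self._ranking([1.0, 0.5], ["g1", "g2"])
        b = self._ranking([1.0, 0.5], ["g3", "g4"])
        with pytest.raises(ValueError):
            cross_cohort_consistency({"a": a, "b": b})


class TestMechanosensitivity:
    def _attrib(self, values):
        n = values.shape[0]
        return AttributionMatrix(
            pd.DataFrame(values,
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"g{j}" for j in range(values.shape[1])]),
            0.0, "consensus",
        )

    def test_no_differential_response_scores_zero(self, rng):
        base = rng.normal(size=(1, 4)).repeat(8, axis=0)
        base[:, 0] += np.r_[np.ones(4), np.zeros(4)]  # only g0 responds
        table = mechanosensitivity(self._attrib(base),
                                   [True] * 4 + [False] * 4)
        assert table.loc["g0", "score"] == 1.0
        assert (table.drop("g0")["score"] == 0.0).all()
        assert (table.drop("g0")["category"] == "low").all()

    def test_boundary_cuts_are_moderate(self):
        # raw differences engineered so min-max scores hit 0, 0.3, 0.6, 1
        raw = np.array([0.0, 0.3, 0.6, 1.0])
        values = np.vstack([raw, np.zeros(4)])
        table = mechanosensitivity(self._attrib(values), [True, False])
        scores = table.set_index(table.index)["score"]
        cats = dict(zip(table.index, table["category"]))
        assert cats["g3"] == "high"        # score 1.0
        assert cats["g2"] == "moderate"    # score 0.6 (boundary)
        assert cats["g1"] == "moderate"    # score 0.3 (boundary)
        assert cats["g0"] == "low"         # score 0.0
        assert table["category"].isin(["high", "moderate", "low"]).all()

    def test_score_above_cut_is_high(self):
        values = np.vstack([np.array([1.0, 0.65, 0.0]), np.zeros(3)])
        table = mechanosensitivity(self._attrib(values), [True, False])
        assert table.loc["g1", "score"] == pytest.approx(0.65)
        assert table.loc["g1", "category"] == "high"

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_minmax_invariant_to_affine_rescaling(self, a, b):
        rng = np.random.default_rng(0)
        raw = rng.uniform(size=(2, 6))
        t1 = mechanosensitivity(self._attrib(raw), [True, False])
        t2 = mechanosensitivity(self._attrib(a * raw + b), [True, False])
        np.testing.assert_allclose(
            t1["score"].to_numpy(), t2["score"].to_numpy(), atol=1e-9
        )

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            mechanosensitivity(self._attrib(rng.normal(size=(3, 2))),
                               [True, True, True])

    def test_planted_strain_responders_recovered(self, mechano_setup):
        """Strain-responsive genes (also the strongest disease drivers)
        occupy the top attribution-difference ranks."""
        truth = mechano_setup["truth"]
        table = mechanosensitivity(
            mechano_setup["attribs"]["consensus"], mechano_setup["strain_mask"]
        )
        n_mech = len(truth.mechano_genes)
        top = set(table.index[:n_mech])
        recovery = len(top & set(truth.mechano_genes)) / n_mech
        assert recovery >= 0.8


def test_svm_explainer_local_accuracy(mechano_setup):
    """Sampling explainer on the fitted margin classifier: efficiency holds
    to the sampling tolerance on real model output."""
    model = mechano_setup["model"]
    attrib = mechano_setup["attribs"]["svm"]
    proba = model.models["svm"].predict_proba(
        mechano_setup["X_strain"].to_numpy())[:, 1]
    assert attrib.local_accuracy_error(proba) < 1e-2
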