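"""Harmonization: probe collapsing, quantile normalization, ComBat, PCA."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cdikit.harmonize import (
    collapse_probes,
    combat_correct,
    intersect_genes,
    pca_batch_diagnostics,
    quantile_normalize,
)
from cdikit.synthetic import CohortSpec, generate_multibatch_expression


def _df(values, index=None, columns=None):
    values = np.asarray(values, dtype=float)
    index = index or [f"g{i}" for i in range(values.shape[0])]
    columns = columns or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=index, columns=columns)


class TestCollapseProbes:
    def test_two_probes_average(self):
        probes = _df([[1, 3], [3, 5]], index=["p1", "p2"])
        out = collapse_probes(probes, {"p1": "A", "p2": "A"})
        assert out.index.tolist() == ["A"]
        np.testing.assert_allclose(out.loc["A"], [2, 4])

    def test_one_probe_per_symbol_is_relabeling(self):
        probes = _df([[1, 2], [3, 4]], index=["p1", "p2"])
        out = collapse_probes(probes, {"p1": "B", "p2": "A"})
        np.testing.assert_allclose(out.loc["A"], [3, 4])
        np.testing.assert_allclose(out.loc["B"], [1, 2])

    def test_matches_brute_force_group_mean(self, rng):
        probes = _df(rng.normal(size=(5, 4)), index=[f"p{i}" for i in range(5)])
        mapping = {"p0": "X", "p1": "Y", "p2": "X", "p3": "Z", "p4": "X"}
        out = collapse_probes(probes, mapping)
        for symbol in ("X", "Y", "Z"):
            members = [p for p, s in mapping.items() if s == symbol]
            np.testing.assert_allclose(
                out.loc[symbol], probes.loc[members].mean(axis=0)
            )

    def test_unmapped_probes_dropped_and_empty_map_rejected(self):
        probes = _df([[1, 2], [3, 4]], index=["p1", "p2"])
        out = collapse_probes(probes, {"p1": "A"})
        assert out.index.tolist() == ["A"]
        with pytest.raises(ValueError):
            collapse_probes(probes, {})


class TestIntersectGenes:
    def test_pairwise_intersection(self):
        a = _df(np.arange(6).reshape(3, 2), index=["A", "B", "C"])
        b = _df(np.arange(6).reshape(3, 2), index=["B", "C", "D"])
        out = intersect_genes([a, b])
        assert out[0].index.tolist() == ["B", "C"]
        assert out[1].index.tolist() == ["B", "C"]

    def test_single_matrix_sorted(self):
        a = _df(np.arange(6).reshape(3, 2), index=["C", "A", "B"])
        assert intersect_genes([a])[0].index.tolist() == ["A", "B", "C"]

    def test_matches_brute_force_fold(self, rng):
        lists = [rng.choice(50, size=30, replace=False) for _ in range(7)]
        mats = [_df(rng.normal(size=(30, 2)), index=[f"g{i}" for i in l])
                for l in lists]
        out = intersect_genes(mats)
        expected = set(f"g{i}" for i in lists[0])
        for l in lists[1:]:
            expected &= set(f"g{i}" for i in l)
        assert out[0].index.tolist() == sorted(expected)

    def test_empty_intersection_rejected(self):
        a = _df([[1]], index=["A"])
        b = _df([[1]], index=["B"])
        with pytest.raises(ValueError):
            intersect_genes([a, b])


class TestQuantileNormalize:
    def test_hand_computed_rank_means(self):
        m = _df(np.array([[1, 4], [2, 5], [3, 6]]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["s0"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["s1"], [2.5, 3.5, 4.5])

    def test_rank_order_preserved(self, rng):
        m = _df(rng.normal(size=(50, 4)))
        out = quantile_normalize(m)
        for c in m.columns:
            assert (np.argsort(out[c].to_numpy(), kind="stable")
                    == np.argsort(m[c].to_numpy(), kind="stable")).all()

    def test_identical_columns_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0])
        m = _df(np.column_stack([col, col, col]))
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_sorted_columns_identical_after(self, rng):
        m = _df(rng.normal(size=(40, 5)))
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_ties_receive_mean_of_spanned_reference(self):
        m = _df(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]))
        out = quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        np.testing.assert_allclose(out["s0"], [ref[:2].mean(), ref[:2].mean(), ref[2]])
        np.testing.assert_allclose(out["s1"], ref)

    @settings(deadline=None, max_examples=25)
    @given(arrays(np.float64, (12, 4), unique=True,
                  elements=st.floats(-50, 50, allow_nan=False)))
    def test_idempotent_on_tie_free_input(self, values):
        """Applying twice equals applying once; exact only without ties,
        since the tie rule re-mixes the reference distribution."""
        m = _df(values)
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-9)

    def test_single_sample_returned_unchanged(self):
        m = _df([[1.0], [2.0]])
        pd.testing.assert_frame_equal(quantile_normalize(m), m)


@pytest.fixture(scope="module")
def planted_batch_cohort():
    spec = CohortSpec(
        n_genes=500,
        n_datasets=2,
        n_train_datasets=2,
        samples_per_condition={"healthy": 50, "advanced": 50},
        strain_samples_per_group=0,
        n_deg_up=0, n_deg_down=0, n_mechano=0,
        batch_shift_sd=2.0,
        batch_scale_sd=0.4,
        seed=5,
    )
    expression, metadata, truth = generate_multibatch_expression(spec)
    return expression, metadata, truth


class TestCombat:
    def test_recovers_planted_location_scale(self, planted_batch_cohort):
        expression, metadata, _ = planted_batch_cohort
        corrected = combat_correct(expression, metadata["batch"])
        b1 = metadata.index[metadata["batch"] == "d1"]
        b2 = metadata.index[metadata["batch"] == "d2"]
        mean_delta = (corrected[b1].mean(axis=1)
                      - corrected[b2].mean(axis=1)).abs()
        assert mean_delta.mean() < 0.1
        ratio = corrected[b1].var(axis=1) / corrected[b2].var(axis=1)
        assert 0.8 < np.median(ratio) < 1.25

    def test_matches_reference_bioconductor_implementation(self, tmp_path, rng):
        """Cross-check against sva::ComBat on a small two-batch fixture."""
        G, n = 80, 15
        Y = rng.normal(8, 1, size=(G, 1)) + rng.normal(0, 0.5, size=(G, 2 * n))
        Y[:, n:] = Y[:, n:] * 1.4 + 1.0
        mat = pd.DataFrame(Y, index=[f"g{i}" for i in range(G)],
                           columns=[f"s{j}" for j in range(2 * n)])
        batch = {s: ("b1" if j < n else "b2")
                 for j, s in enumerate(mat.columns)}
        mine = combat_correct(mat, batch)
        mat.to_csv(tmp_path / "expr.tsv", sep="\t")
        pd.Series(batch).to_csv(tmp_path / "batch.tsv", sep="\t", header=False)
        script = tmp_path / "combat.R"
        script.write_text(
            'suppressMessages(library(sva))\n'
            'a <- commandArgs(trailingOnly=TRUE)\n'
            'x <- as.matrix(read.table(a[1], sep="\\t", header=TRUE, '
            'row.names=1, check.names=FALSE))\n'
            'b <- read.table(a[2], sep="\\t", row.names=1)[,1]\n'
            'out <- ComBat(dat=x, batch=b, par.prior=TRUE)\n'
            'write.table(out, a[3], sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "expr.tsv"),
             str(tmp_path / "batch.tsv"), str(tmp_path / "out.tsv")],
            check=True, capture_output=True,
        )
        theirs = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(mine.to_numpy(), theirs.to_numpy(), atol=1e-8)

    def test_near_identity_without_batch_effects(self, rng):
        G, n = 200, 40
        Y = rng.normal(6, 1, size=(G, 1)) + rng.normal(0, 0.5, size=(G, 2 * n))
        mat = pd.DataFrame(Y, index=[f"g{i}" for i in range(G)],
                           columns=[f"s{j}" for j in range(2 * n)])
        batch = {s: ("b1" if j < n else "b2")
                 for j, s in enumerate(mat.columns)}
        corrected = combat_correct(mat, batch)
        rms = np.sqrt(((corrected - mat) ** 2).mean(axis=1))
        assert rms.mean() < 0.05

    def test_shape_gene_order_and_grand_mean_preserved(self, planted_batch_cohort):
        expression, metadata, _ = planted_batch_cohort
        corrected = combat_correct(expression, metadata["batch"])
        assert corrected.shape == expression.shape
        assert corrected.index.tolist() == expression.index.tolist()
        # weighted grand mean per gene is a ComBat invariant
        np.testing.assert_allclose(
            corrected.mean(axis=1), expression.mean(axis=1), atol=5e-2
        )

    def test_single_batch_with_check_disabled_is_identity(self, rng):
        mat = _df(rng.normal(size=(20, 6)))
        batch = {s: "only" for s in mat.columns}
        out = combat_correct(mat, batch, check_batches=False)
        pd.testing.assert_frame_equal(out, mat)

    def test_singleton_batch_rejected_by_name(self):
        mat = _df(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="lonely"):
            combat_correct(mat, {"s0": "a", "s1": "a", "s2": "lonely"})


class TestPCADiagnostics:
    def test_constructed_separation_gives_full_batch_r2(self):
        left = np.zeros((30, 10))
        right = np.full((30, 10), 5.0)
        mat = _df(np.hstack([left, right]) + 0.01 * np.arange(30)[:, None])
        batch = {f"s{j}": ("a" if j < 10 else "b") for j in range(20)}
        d = pca_batch_diagnostics(mat, batch)
        assert d["batch_assoc"] > 0.99

    def test_isotropic_noise_has_no_batch_signal(self, rng):
        mat = _df(rng.normal(size=(400, 40)))
        batch = {f"s{j}": ("a" if j < 20 else "b") for j in range(40)}
        d = pca_batch_diagnostics(mat, batch)
        assert d["pc1_variance"] < 0.15
        assert d["batch_assoc"] < 0.25

    def test_correction_reduces_pc1_share_and_batch_assoc(self, planted_batch_cohort):
        expression, metadata, _ = planted_batch_cohort
        before = pca_batch_diagnostics(expression, metadata["batch"])
        corrected = combat_correct(expression, metadata["batch"])
        after = pca_batch_diagnostics(corrected, metadata["batch"])
        assert before["pc1_variance"] > 0.5  # batch dominates pre-correction
        assert after["pc1_variance"] < before["pc1_variance"]
        assert after["batch_assoc"] < before["batch_assoc"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_batch_diagnostics(_df(np.zeros((5, 2))), {"s0": "a", "s1": "b"})
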