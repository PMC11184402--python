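import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, ttest_ind

import cellprior as cp
from cellprior.specificity import (
    EPS,
    METRICS,
    OrthologMapError,
    esw_from_metric,
    group_means,
    validate_ortholog_map,
)


def _matrix(counts, labels):
    counts = np.asarray(counts)
    return cp.ExpressionMatrix(
        counts=counts,
        gene_ids=np.array([f"g{i}" for i in range(counts.shape[0])], dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(counts.shape[1])], dtype=object),
        cell_type=np.asarray(labels, dtype=object),
    )


class TestNormalize:
    def test_scaling_and_log(self):
        x = _matrix([[1, 5], [0, 5], [3, 5]], ["a", "b"])
        out = cp.normalize(x, scale=10_000)
        np.testing.assert_allclose(
            out[:, 0], [np.log(2501), 0.0, np.log(7501)], rtol=1e-12
        )

    def test_all_zero_cell_stays_zero(self):
        x = _matrix([[1, 0], [2, 0]], ["a", "b"])
        with pytest.warns(UserWarning, match="all-zero"):
            out = cp.normalize(x)
        np.testing.assert_array_equal(out[:, 1], 0.0)

    def test_cell_already_at_scale(self):
        x = _matrix([[4000, 1], [6000, 1]], ["a", "b"])
        out = cp.normalize(x, scale=10_000)
        np.testing.assert_allclose(out[:, 0], np.log1p([4000, 6000]))


class TestOrthologs:
    def test_subset_and_rename(self):
        x = _matrix([[1, 2], [3, 4], [5, 6]], ["a", "b"])
        mapped = cp.map_orthologs(x, {"g0": "H0", "g2": "H2"})
        assert list(mapped.gene_ids) == ["H0", "H2"]
        np.testing.assert_array_equal(mapped.counts, [[1, 2], [5, 6]])

    def test_identity_map(self):
        x = _matrix([[1, 2], [3, 4]], ["a", "b"])
        mapped = cp.map_orthologs(x, {"g0": "g0", "g1": "g1"})
        np.testing.assert_array_equal(mapped.counts, x.counts)

    def test_collision_rejected(self):
        with pytest.raises(OrthologMapError, match="injective"):
            validate_ortholog_map({"g0": "H", "g1": "H"})


class TestMetricEP:
    def test_proportions(self):
        out = cp.metric_ep(np.array([[2.0, 1.0, 1.0]]))
        np.testing.assert_allclose(out, [[0.5, 0.25, 0.25]])

    def test_single_type_expression(self):
        out = cp.metric_ep(np.array([[0.0, 3.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.0, 1.0, 0.0]])

    def test_zero_row_stays_zero(self):
        out = cp.metric_ep(np.zeros((1, 3)))
        np.testing.assert_array_equal(out, 0.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = rng.random((20, 5)) * (rng.random((20, 5)) < 0.7)
        m[0] = 0
        out = cp.metric_ep(m)
        nonzero = m.sum(axis=1) > 0
        np.testing.assert_allclose(out[nonzero].sum(axis=1), 1.0)
        np.testing.assert_array_equal(out[~nonzero], 0.0)


class TestMetricGES:
    def test_uniform_gene_is_one(self):
        xnorm = np.full((1, 6), 2.0)
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        out = cp.metric_ges(xnorm, labels)
        np.testing.assert_allclose(out, 1.0, rtol=1e-6)

    def test_exclusive_gene_is_inverse_fraction(self):
        # 6 cells, 2 in type a (f = 1/3): mean in a = 3, global mean = 1
        xnorm = np.array([[3.0, 3.0, 0, 0, 0, 0]])
        labels = np.array(["a"] * 2 + ["b"] * 4, dtype=object)
        out = cp.metric_ges(xnorm, labels)
        assert out[0, 0] == pytest.approx(3.0, rel=1e-6)  # 1/f
        assert out[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_gene(self):
        xnorm = np.zeros((1, 4))
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        np.testing.assert_array_equal(cp.metric_ges(xnorm, labels), 0.0)


class TestMetricNSI:
    def test_top_gene_scores_one(self):
        m = np.array([[10.0, 0.1], [1.0, 1.0], [0.1, 10.0]])
        out = cp.metric_nsi(m)
        assert out[0, 0] == pytest.approx(1.0)
        assert out[2, 0] == pytest.approx(0.0)

    def test_matches_bruteforce_ranks(self):
        rng = np.random.default_rng(3)
        m = rng.random((6, 3))
        out = cp.metric_nsi(m)
        # exhaustive oracle: loop over target types and competitors
        for c in range(3):
            for g in range(6):
                ranks = []
                for cp_ in range(3):
                    if cp_ == c:
                        continue
                    ratios = m[:, c] / (m[:, cp_] + EPS)
                    ranks.append(rankdata(-ratios)[g])
                si = np.mean(ranks)
                expected = 1 - (si - 1) / (6 - 1)
                assert out[g, c] == pytest.approx(expected)


class TestMetricDET:
    def test_identical_groups_give_zero(self):
        xnorm = np.array([[1.0, 1.0, 1.0, 1.0]])
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        np.testing.assert_allclose(cp.metric_det(xnorm, labels), 0.0)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(5)
        xnorm = rng.random((4, 10))
        labels = np.array(["a"] * 4 + ["b"] * 6, dtype=object)
        out = cp.metric_det(xnorm, labels)
        for g in range(4):
            t_ref = ttest_ind(xnorm[g, :4], xnorm[g, 4:], equal_var=False).statistic
            assert out[g, 0] == pytest.approx(t_ref, rel=1e-10)
            assert out[g, 1] == pytest.approx(-t_ref, rel=1e-10)

    def test_small_group_column_zeroed(self):
        xnorm = np.array([[1.0, 2.0, 3.0, 4.0]])
        labels = np.array(["a", "b", "b", "b"], dtype=object)
        with pytest.warns(UserWarning, match="<2 cells"):
            out = cp.metric_det(xnorm, labels)
        assert out[0, 0] == 0.0


class TestESW:
    def test_rank_scaling(self):
        """Retained genes get rank/#retained, the largest metric value -> 1."""
        labels = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        base = np.arange(1.0, 7.0)  # six genes with distinct metric values

        def fake_metric(xnorm, lab, types):
            # signal only under the original labelling; nulls score 0
            signal = float(np.array_equal(lab, labels))
            return np.outer(base * signal, np.ones(len(types)))

        esw = esw_from_metric(fake_metric, np.zeros((6, 10)), labels, n_perms=100, seed=1)
        np.testing.assert_allclose(np.sort(esw[:, 0]), np.arange(1, 7) / 6)

    def test_tied_metric_values_share_average_rank_weight(self, planted_expression):
        """Markers silent off-type all hit EP = 1 and share one tied weight."""
        x, markers = planted_expression
        xnorm = cp.normalize(x)
        esw = esw_from_metric(METRICS["ep"], xnorm, x.cell_type, n_perms=200, seed=1)
        col = esw[:, 0]
        retained = col[col > 0]
        assert len(retained) >= len(markers)
        # the five tied EP=1 markers all receive the mean of ranks 1..5 over 5
        assert np.unique(col[markers]).size == 1

    def test_no_signal_mostly_gated(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(2.0, size=(40, 60))
        labels = np.array(["a", "b", "c"] * 20, dtype=object)
        x = cp.ExpressionMatrix(
            counts, np.array([f"g{i}" for i in range(40)], dtype=object),
            np.array([f"c{i}" for i in range(60)], dtype=object), labels,
        )
        xnorm = cp.normalize(x)
        frac_nonzero = []
        for seed in range(10):
            esw = esw_from_metric(METRICS["ep"], xnorm, x.cell_type, n_perms=150, seed=seed)
            frac_nonzero.append((esw > 0).mean())
        assert np.mean(frac_nonzero) <= 0.075

    def test_perms_below_minimum_rejected(self, planted_expression):
        x, _ = planted_expression
        with pytest.raises(ValueError, match="at least 100"):
            esw_from_metric(METRICS["ep"], cp.normalize(x), x.cell_type, n_perms=10)


class TestCombine:
    def test_mean_of_identical_inputs(self):
        m = np.array([[0.5, 1.0]])
        es = cp.combine_es_mu({k: m for k in "abcd"}, ["g0"], ["t0", "t1"])
        np.testing.assert_allclose(es.es_mu.to_numpy(), m)

    def test_mean_arithmetic(self):
        mats = {"a": np.array([[1.0]]), "b": np.array([[1.0]]),
                "c": np.array([[0.0]]), "d": np.array([[0.0]])}
        es = cp.combine_es_mu(mats, ["g0"], ["t0"])
        assert es.es_mu.iloc[0, 0] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        mats = {"a": np.array([[1.5]]), "b": np.array([[0.0]])}
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cp.combine_es_mu(mats, ["g0"], ["t0"])

    def test_shape_mismatch_rejected(self):
        mats = {"a": np.zeros((2, 2)), "b": np.zeros((3, 2))}
        with pytest.raises(ValueError, match="shape"):
            cp.combine_es_mu(mats, ["g0", "g1"], ["t0", "t1"])


class TestPlantedRecovery:
    def test_every_metric_ranks_planted_markers_top(self, planted_expression):
        """Genes expressed only in one type outrank all others on each metric."""
        x, markers = planted_expression
        xnorm = cp.normalize(x)
        types = x.cell_types
        non_markers = np.setdiff1d(np.arange(len(x.gene_ids)), markers)
        for name, metric in METRICS.items():
            vals = metric(xnorm, x.cell_type, types)
            assert vals[markers, 0].min() > vals[non_markers, 0].max(), name

    def test_es_mu_in_unit_interval_and_markers_win(self, planted_expression):
        x, markers = planted_expression
        es = cp.compute_es(x, n_perms=150, seed=3)
        v = es.es_mu.to_numpy()
        assert v.min() >= 0 and v.max() <= 1
        non_markers = np.setdiff1d(np.arange(len(x.gene_ids)), markers)
        assert v[markers, 0].min() > v[non_markers, 0].max()
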