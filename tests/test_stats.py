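"""t-tests, q-values, Fisher enrichment, overlap and permutation tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import pancanproteo as pp
from pancanproteo.stats import (
    ConfusionOverlap,
    assignment_strength,
    enrichment_table,
    estimate_pi0,
    fisher_enrichment,
    overlap_significance,
    permutation_association_test,
    qvalues,
    ttest_groups,
    two_sample_t,
)

from conftest import make_annotation, make_matrix


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_pooled_example(self):
        # x̄=3, ȳ=0, s_p²=1, t=3, df=2 → p ≈ 0.0955
        t, p = two_sample_t([2, 4], [0, 0])
        assert t == pytest.approx(3.0, abs=1e-12)
        assert p == pytest.approx(0.09547, abs=1e-4)

    def test_antisymmetry(self):
        t1, p1 = two_sample_t([1, 5, 2], [4, 8, 9, 7])
        t2, p2 = two_sample_t([4, 8, 9, 7], [1, 5, 2])
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_closed_form_and_scipy_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.normal(size=rng.integers(3, 20))
            y = rng.normal(loc=rng.normal(), size=rng.integers(3, 20))
            t, p = two_sample_t(x, y)
            # closed-form pooled formula
            n1, n2 = len(x), len(y)
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
            expected = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert t == pytest.approx(expected, abs=1e-12)
            # independent library implementation
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(scale=4, size=5)
        t, p = two_sample_t(x, y, welch=True)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_conventions(self):
        res = ttest_groups(np.array([[1.0, 1.0, 1.0, 1.0]]), np.array([True, True, False, False]))
        assert res["t"][0] == 0.0 and res["p"][0] == 1.0
        res = ttest_groups(np.array([[2.0, 2.0, 0.0, 0.0]]), np.array([True, True, False, False]))
        assert np.isposinf(res["t"][0]) and res["p"][0] == 0.0

    def test_missing_values_dropped(self):
        t, p = two_sample_t([2, 4, np.nan], [0, 0, np.nan])
        assert t == pytest.approx(3.0, abs=1e-12)

    def test_tiny_group_is_error(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestQvalues:
    def test_hand_computed_storey_example(self):
        # fixed λ=0.5: π̂0 = #{p>0.5}/(4·0.5) = 0.5
        q = qvalues([0.01, 0.02, 0.03, 0.9], pi0_method="fixed", fixed_lambda=0.5)
        np.testing.assert_allclose(q, [0.02, 0.02, 0.02, 0.45], atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(qvalues([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_empty(self):
        assert qvalues([]).size == 0

    def test_equals_benjamini_hochberg_when_pi0_forced_to_one(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=200) ** 2
        q = qvalues(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        pi0 = estimate_pi0(p)
        assert (q >= p * pi0 - 1e-15).all()
        assert (q <= 1).all()

    def test_pi0_recovers_null_proportion_on_uniform_p(self):
        """π̂0 lands in [0.9, 1.0] for pure-null p-values (m = 10000)."""
        hits = 0
        for seed in range(10):
            p = pp.generate_pvalue_mixture(10000, pi0=1.0, seed=seed)
            if 0.9 <= estimate_pi0(p) <= 1.0:
                hits += 1
        assert hits >= 9

    def test_pi0_detects_signal(self):
        p = pp.generate_pvalue_mixture(10000, pi0=0.5, alt_beta_shape=0.05, seed=4)
        assert estimate_pi0(p) < 0.7

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.2])


class TestFisherEnrichment:
    def test_zero_overlap_gives_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        counts, p = fisher_enrichment(bg[:3], bg[5:8], bg)
        assert counts["n_list_in_cat"] == 0
        assert p == 1.0

    def test_hand_computed_tail(self):
        # bg 10, category 4, list 4, overlap 3 → (C(4,3)C(6,1)+C(4,4))/C(10,4)
        bg = [f"g{i}" for i in range(10)]
        cat = bg[:4]
        lst = bg[:3] + [bg[5]]
        counts, p = fisher_enrichment(lst, cat, bg)
        assert counts["n_list_in_cat"] == 3
        assert p == pytest.approx(25 / 210, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            N = int(rng.integers(5, 60))
            bg = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            cat = list(rng.choice(bg, size=K, replace=False))
            lst = list(rng.choice(bg, size=n, replace=False))
            counts, p = fisher_enrichment(lst, cat, bg)
            x = counts["n_list_in_cat"]
            expected = sum(
                math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(x, min(K, n) + 1)
                if n - i <= N - K
            ) / math.comb(N, n)
            assert p == pytest.approx(expected, rel=1e-10)

    def test_list_gene_outside_background_named(self):
        with pytest.raises(ValueError, match="rogue"):
            fisher_enrichment(["rogue"], ["a"], ["a", "b"])

    def test_enrichment_table_sorted_by_p(self):
        bg = [f"g{i}" for i in range(20)]
        coll = pp.GeneSetCollection(
            {
                "hit": pp.GeneSet("hit", bg[:5]),
                "miss": pp.GeneSet("miss", bg[15:]),
            }
        )
        table = enrichment_table(bg[:5], coll, bg)
        assert list(table["category"]) == ["hit", "miss"]
        assert table.loc[0, "p"] < table.loc[1, "p"]


class TestOverlapSignificance:
    def test_perfectly_matched_two_class_labeling(self):
        ids = [f"s{i}" for i in range(10)]
        a = pd.Series(["x"] * 5 + ["y"] * 5, index=ids)
        result = overlap_significance(a, a.copy())
        # diagonal: P(overlap ≥ 5 | 5 of 10 in each) = 1/C(10,5)
        assert result.p.loc["x", "x"] == pytest.approx(1 / 252, rel=1e-9)
        assert result.counts.loc["x", "y"] == 0
        assert result.counts.loc["y", "x"] == 0

    def test_counts_margins_match_cohorts(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(40)]
        a = pd.Series(rng.choice(["p", "q", "r"], size=40), index=ids)
        b = pd.Series(rng.choice(["u", "v"], size=40), index=ids)
        result = overlap_significance(a, b)
        assert result.counts.to_numpy().sum() == 40
        assert (result.counts.sum(axis=1) == a.value_counts().loc[result.counts.index]).all()

    def test_null_labelings_have_calibrated_diagonal_p(self):
        rng = np.random.default_rng(7)
        ids = [f"s{i}" for i in range(60)]
        ps = []
        for _ in range(300):
            a = pd.Series(rng.choice(["x", "y"], size=60), index=ids)
            b = pd.Series(rng.choice(["x", "y"], size=60), index=ids)
            result = overlap_significance(a, b)
            if "x" in result.p.index and "x" in result.p.columns:
                ps.append(result.p.loc["x", "x"])
        ps = np.array(ps)
        # one-sided null p-values are super-uniform at worst
        assert (ps <= 0.05).mean() <= 0.08
        assert 0.4 <= ps.mean() <= 0.7

    def test_disjoint_ids_error(self):
        a = pd.Series(["x"], index=["s1"])
        b = pd.Series(["x"], index=["s2"])
        with pytest.raises(ValueError):
            overlap_significance(a, b)


class TestPermutationTest:
    @pytest.fixture()
    def tiny_model(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(40)]
        centroids = pd.DataFrame(
            rng.normal(size=(40, 3)), index=genes, columns=["k1", "k2", "k3"]
        )
        features = pd.DataFrame(
            {"gene_id": genes, "subtype": ["k1"] * 14 + ["k2"] * 13 + ["k3"] * 13,
             "t": 1.0, "q": 0.01}
        )
        clf = pp.SubtypeClassifier(
            subtype_names=["k1", "k2", "k3"], features=features,
            centroids=centroids, markers_per_subtype=14,
        )
        cols = {}
        for j in range(12):
            c = centroids.iloc[:, j % 3]
            cols[f"s{j}"] = c + rng.normal(scale=0.3, size=40)
        target = pp.ExpressionMatrix(pd.DataFrame(cols), norm_state="fully_normalized")
        ann = make_annotation(list(cols), ["t1"] * 6 + ["t2"] * 6)
        return clf, target, ann

    def test_strong_signal_hits_add_one_floor(self, tiny_model):
        clf, target, ann = tiny_model
        stat, p = permutation_association_test(clf, target, ann, n_perm=99, seed=1)
        assert stat > 0.8
        assert p == pytest.approx(1 / 100)

    def test_p_matches_replay_of_recorded_nulls(self, tiny_model):
        clf, target, ann = tiny_model
        stat, p, nulls = permutation_association_test(
            clf, target, ann, n_perm=3, seed=2, return_null=True
        )
        assert len(nulls) == 3
        expected = (1 + sum(s >= stat for s in nulls)) / 4
        assert p == expected

    def test_preshuffled_target_is_non_significant(self, tiny_model):
        clf, target, ann = tiny_model
        rng = np.random.default_rng(9)
        shuffled = target.values.to_numpy()[rng.permutation(40)]
        null_target = pp.ExpressionMatrix(
            pd.DataFrame(shuffled, index=target.gene_ids, columns=target.sample_ids),
            norm_state="fully_normalized",
        )
        ps = [
            permutation_association_test(clf, null_target, ann, n_perm=19, seed=s)[1]
            for s in range(8)
        ]
        assert np.mean(ps) > 0.2

    def test_sample_scheme_runs(self, tiny_model):
        clf, target, ann = tiny_model
        stat, p = permutation_association_test(
            clf, target, ann, n_perm=9, seed=3, scheme="sample"
        )
        assert 0 < p <= 1


class TestDiffexpAndPrevalence:
    def test_type_one_error_calibrated_on_null_cohort(self):
        """Random labels on an effect-free cohort: ~5% of genes at p < 0.05."""
        cfg = pp.CohortConfig(
            type_sizes={"a": 60, "b": 60}, n_genes=10000, n_subtypes=2,
            markers_per_subtype=10, effect_size=0.0,
            type_restricted_subtypes={}, missing_type_prob=0.0, seed=10,
        )
        matrix, ann, _ = pp.generate_cohort(cfg)
        _, stage2, _ = pp.normalize_two_stage(matrix, ann)
        rng = np.random.default_rng(11)
        mask = rng.random(120) < 0.5
        res = ttest_groups(stage2.values.to_numpy(), mask)
        frac = float((res["p"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_diffexp_table_signs_and_q_ranges(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(30, 20))
        vals[:5, :7] += 3.0  # genes high in subtype A
        m = make_matrix(vals, norm_state="fully_normalized")
        labels = pd.Series(["A"] * 7 + ["B"] * 13, index=m.sample_ids)
        table = pp.diffexp_table(m, labels)
        sub = table[table["subtype"] == "A"].set_index("gene_id")
        assert (sub.loc[[f"g{i}" for i in range(5)], "t"] > 0).all()
        signs = np.sign(table["t"]) == np.sign(table["mean_in"] - table["mean_out"])
        assert signs[table["t"] != 0].all()
        assert table["q"].between(0, 1).all()

    def test_prevalence_percentages(self):
        labels = pd.Series(["k5"] * 113 + ["k1"] * 22 + ["k7"] * 95 + ["kx"] * 302)
        prev = pp.prevalence_percentages(labels)
        assert round(prev["k5"], 1) == 21.2
        assert round(prev["k1"], 1) == 4.1
        assert round(prev["k7"], 1) == 17.9


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
def test_qvalue_order_compatibility_property(p):
    """q-values never reorder the evidence: sorted by p ⇒ sorted by q."""
    q = qvalues(p, pi0=1.0)
    order = np.argsort(np.asarray(p), kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()
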