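import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celldecon import (
    BlackList,
    ExpressionMatrix,
    GeneratorSpec,
    PhenotypeAnnotation,
    apply_blacklists,
    build_signature,
    cancer_blacklist,
    condition_number,
    construct_signature,
    generate_references,
    normal_tissue_blacklist,
    pairwise_deg,
    planted_markers,
    qvalues,
    select_g,
    top_g_union,
    welch_t_test,
)
from celldecon.signature_builder import PairwiseDEGTable
from _oracles import bh_oracle, kappa_oracle, welch_oracle


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestBlacklists:
    def test_normal_tissue_threshold_is_strict(self):
        # 6/100 tissues above zero -> listed; 5/100 -> kept
        es = pd.DataFrame(0.0, index=["hit", "edge", "cold"],
                          columns=[f"t{i}" for i in range(100)])
        es.iloc[0, :6] = 1.0
        es.iloc[1, :5] = 1.0
        es.iloc[2, :] = -1.0
        blacklist = normal_tissue_blacklist(es)
        assert blacklist.gene_ids == {"hit"}

    def test_cancer_threshold_is_strict_any_line(self):
        ccle = pd.DataFrame(
            {"line1": [7.1, 7.0, 1.0], "line2": [0.0, 7.0, 2.0]},
            index=["hot", "edge", "cold"],
        )
        blacklist = cancer_blacklist(ccle)
        assert blacklist.gene_ids == {"hot"}

    def test_empty_table_gives_empty_blacklist(self):
        assert len(cancer_blacklist(pd.DataFrame())) == 0

    def test_apply_removes_only_listed_genes(self):
        matrix = _em(np.ones((10, 2)))
        blacklist = BlackList(frozenset({"g0", "g3", "g7"}), "user")
        out = apply_blacklists(matrix, blacklist)
        assert out.shape == (7, 2)
        assert not {"g0", "g3", "g7"} & set(out.gene_ids)

    def test_apply_disjoint_list_is_identity(self):
        matrix = _em(np.ones((4, 2)))
        out = apply_blacklists(matrix, BlackList(frozenset({"zz"}), "user"))
        assert out.gene_ids == matrix.gene_ids

    def test_all_genes_blacklisted_is_error(self):
        matrix = _em(np.ones((2, 2)))
        with pytest.raises(ValueError, match="black-listed"):
            apply_blacklists(matrix, BlackList(frozenset({"g0", "g1"}), "user"))


class TestWelch:
    def test_identical_groups_t_zero_p_one(self):
        t, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_checkable_instance(self):
        # (1,2) vs (3,5): t = -2/sqrt(0.25+0.5), Welch-Satterthwaite df
        t, p = welch_t_test([1, 2], [3, 5])
        t_ref, df_ref, p_ref = welch_oracle(np.array([1, 2.0]), np.array([3, 5.0]))
        assert abs(t - (-2.23606797749979)) < 1e-12
        assert abs(df_ref - 1.4705882352941178) < 1e-12
        assert abs(t - t_ref) < 1e-12 and abs(p - p_ref) < 1e-12

    def test_swapping_groups_negates_t_preserves_p(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=5), rng.normal(1, 2, size=7)
        t1, p1 = welch_t_test(a, b)
        t2, p2 = welch_t_test(b, a)
        assert abs(t1 + t2) < 1e-12 and abs(p1 - p2) < 1e-12

    def test_constant_unequal_groups_error(self):
        with pytest.raises(ValueError, match="constant"):
            welch_t_test([2, 2], [5, 5])

    def test_matches_oracle_on_many_random_fixtures(self):
        rng = np.random.default_rng(99)
        for _ in range(120):
            na, nb = rng.integers(2, 9, size=2)
            a = rng.normal(rng.uniform(-3, 3), rng.uniform(0.5, 3), size=na)
            b = rng.normal(rng.uniform(-3, 3), rng.uniform(0.5, 3), size=nb)
            t, p = welch_t_test(a, b)
            t_ref, _, p_ref = welch_oracle(a, b)
            assert abs(t - t_ref) < 1e-10
            assert abs(p - p_ref) < 1e-10


class TestQvalues:
    def test_bh_step_up_example(self):
        np.testing.assert_allclose(qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_is_its_own_q(self):
        np.testing.assert_allclose(qvalues([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(qvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_step_up_oracle_exactly(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_array_equal(qvalues(p), bh_oracle(p))

    def test_monotone_in_p(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=50)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(29)
        p = rng.uniform(size=200)
        assert (qvalues(p, method="storey") <= qvalues(p, method="bh") + 1e-15).all()


@pytest.fixture(scope="module")
def marker_fixture():
    """3 classes x 3 replicates, 30 genes; gene 'g0' is a strong class-A
    marker (mean 100 in A, 1 elsewhere), everything else near-constant."""
    rng = np.random.default_rng(314)
    values = rng.normal(50, 0.5, size=(30, 9))
    values[0, 0:3] = [100.0, 100.5, 99.5]
    values[0, 3:] = [1.0, 1.1, 0.9, 1.0, 1.05, 0.95]
    samples = [f"{c}{i}" for c in "ABC" for i in range(3)]
    matrix = _em(values, samples=samples)
    annotation = PhenotypeAnnotation({s: s[0] for s in samples})
    return matrix, annotation


class TestPairwiseDEG:
    def test_three_classes_yield_three_pairs(self, marker_fixture):
        matrix, annotation = marker_fixture
        deg = pairwise_deg(matrix, annotation)
        assert len(deg.pairs) == 3

    def test_planted_marker_ranks_first_in_every_pair_involving_its_class(
        self, marker_fixture
    ):
        matrix, annotation = marker_fixture
        deg = pairwise_deg(matrix, annotation)
        for class_a, class_b in deg.pairs:
            sub = deg.table[
                (deg.table["class_a"] == class_a) & (deg.table["class_b"] == class_b)
            ]
            if "A" in (class_a, class_b):
                assert sub.iloc[0]["gene"] == "g0"
                assert sub.iloc[0]["rank"] == 1

    def test_identical_distributions_excluded_in_noiseless_fixture(self):
        values = np.tile([[3.0], [5.0]], (1, 4))
        matrix = _em(values, samples=["a1", "a2", "b1", "b2"])
        annotation = PhenotypeAnnotation(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        deg = pairwise_deg(matrix, annotation)
        assert deg.table.empty  # t = 0 => p = 1 everywhere

    def test_class_below_two_replicates_is_error(self, marker_fixture):
        matrix, _ = marker_fixture
        annotation = PhenotypeAnnotation(
            {s: ("solo" if s == "A0" else s[0]) for s in matrix.sample_ids}
        )
        with pytest.raises(ValueError, match="solo"):
            pairwise_deg(matrix, annotation)


def _deg_from_records(records):
    table = pd.DataFrame.from_records(
        records,
        columns=["class_a", "class_b", "gene", "t_statistic", "p_value",
                 "q_value", "log2_fold_change", "rank"],
    )
    return PairwiseDEGTable(table)


class TestTopGUnion:
    def test_disjoint_pairs_sum(self):
        records = [
            ("A", "B", f"p1_{i}", 5.0, 0.01, 0.01, 4.0 - i * 0.1, i + 1)
            for i in range(2)
        ] + [
            ("A", "C", f"p2_{i}", 5.0, 0.01, 0.01, 4.0 - i * 0.1, i + 1)
            for i in range(2)
        ] + [
            ("B", "C", f"p3_{i}", 5.0, 0.01, 0.01, 4.0 - i * 0.1, i + 1)
            for i in range(2)
        ]
        assert len(top_g_union(_deg_from_records(records), 2)) == 6

    def test_shared_top_gene_counted_once(self):
        records = [
            ("A", "B", "star", 9.0, 0.001, 0.001, 5.0, 1),
            ("A", "C", "star", 9.0, 0.001, 0.001, 5.0, 1),
        ]
        assert top_g_union(_deg_from_records(records), 1) == ["star"]

    def test_g_beyond_significant_count_saturates(self):
        records = [("A", "B", f"g{i}", 5.0, 0.01, 0.01, 3.0, i + 1) for i in range(4)]
        assert len(top_g_union(_deg_from_records(records), 50)) == 4

    def test_union_size_non_decreasing_in_g(self, marker_fixture):
        matrix, annotation = marker_fixture
        deg = pairwise_deg(matrix, annotation, q_cutoff=0.9)
        sizes = [len(top_g_union(deg, g)) for g in range(1, 15)]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            top_g_union(_deg_from_records([]), 5)


class TestBuildSignature:
    def test_entries_are_class_means(self, tiny_matrix, tiny_annotation):
        sig = build_signature(tiny_matrix, tiny_annotation, ["g1", "g2", "g3"])
        np.testing.assert_allclose(sig.data.loc["g1"].to_numpy(), [11.0, 1.05])

    def test_replicate_order_irrelevant(self, tiny_matrix, tiny_annotation):
        shuffled = ExpressionMatrix(tiny_matrix.data[["b2", "a1", "b1", "a2"]])
        sig1 = build_signature(tiny_matrix, tiny_annotation, ["g1", "g2"])
        sig2 = build_signature(shuffled, tiny_annotation, ["g1", "g2"])
        np.testing.assert_allclose(sig1.values, sig2.values)

    def test_absent_gene_is_error(self, tiny_matrix, tiny_annotation):
        with pytest.raises(KeyError):
            build_signature(tiny_matrix, tiny_annotation, ["g1", "ghost"])


class TestConditionNumber:
    def test_orthonormal_columns_give_one(self):
        q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(6, 3)))
        assert abs(condition_number(q) - 1.0) < 1e-12

    def test_diagonal_closed_form(self):
        assert abs(condition_number(np.diag([10.0, 1.0])) - 10.0) < 1e-12

    def test_matches_svd_oracle_on_random_matrices(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            m = rng.normal(size=(6, 3))
            assert abs(condition_number(m) - kappa_oracle(m)) <= 1e-10 * kappa_oracle(m)

    def test_rank_deficient_reports_infinity(self):
        column = np.arange(4.0)[:, None]
        with pytest.warns(UserWarning, match="rank-deficient"):
            assert condition_number(np.hstack([column, column])) == np.inf

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_kappa_at_least_one_and_scale_invariant(self, seed, scale):
        m = np.random.default_rng(seed).normal(size=(5, 3))
        kappa = condition_number(m)
        assert kappa >= 1.0
        assert abs(condition_number(scale * m) - kappa) < 1e-8 * kappa


class TestSelectG:
    def test_interior_minimum_chosen(self, marker_fixture):
        matrix, annotation = marker_fixture
        deg = pairwise_deg(matrix, annotation, q_cutoff=0.9)
        trace = select_g(deg, matrix, annotation, g_min=1, g_max=8)
        kappas = trace.trace.set_index("G")["condition_number"]
        assert trace.chosen_condition_number == kappas.min()
        assert trace.chosen_g == kappas.idxmin()

    def test_tie_prefers_smaller_g(self):
        records = [
            ("A", "B", g, 5.0, 0.01, 0.01, 3.0, i + 1)
            for i, g in enumerate(["g0", "g1", "g2"])
        ]
        deg = _deg_from_records(records)
        matrix = _em(
            np.array([[4.0, 4.0, 1.0, 1.0],
                      [1.0, 1.0, 4.0, 4.0],
                      [2.0, 2.0, 2.0, 2.0]]),
            genes=["g0", "g1", "g2"],
            samples=["a1", "a2", "b1", "b2"],
        )
        annotation = PhenotypeAnnotation({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        trace = select_g(deg, matrix, annotation, g_min=2, g_max=3)
        # G=2 and G=3 both reach the minimum only if kappa ties; assert rule
        kappas = trace.trace.set_index("G")["condition_number"]
        expected = kappas[kappas == kappas.min()].index.min()
        assert trace.chosen_g == expected

    def test_orthogonal_marker_blocks_reach_low_kappa_at_g_min(self):
        spec = GeneratorSpec(n_classes=3, n_genes=60, markers_per_class=5,
                             replicates_per_class=3, marker_effect=100.0,
                             noise_sd=0.0, seed=5)
        refs, annotation = generate_references(spec)
        sig, selection, _ = construct_signature(refs, annotation, g_min=1, g_max=10,
                                                normalize=False)
        assert selection.chosen_condition_number < 50
        assert selection.chosen_g == selection.trace["G"].iloc[
            int(np.argmin(selection.trace["condition_number"].to_numpy()))
        ]


class TestEndToEndConstruction:
    def test_final_list_never_contains_blacklisted_gene(self):
        spec = GeneratorSpec(n_classes=4, n_genes=200, markers_per_class=4,
                             replicates_per_class=3, seed=3)
        refs, annotation = generate_references(spec)
        markers = planted_markers(spec)
        banned = frozenset(markers["class_01"][:2] + markers["class_03"][:1])
        blacklist = BlackList(banned, "user")
        sig, _, _ = construct_signature(refs, annotation, (blacklist,),
                                        g_min=2, g_max=20)
        assert not banned & set(sig.gene_ids)

    def test_chosen_list_recovers_planted_markers(self):
        # markers_per_class below the scan floor: every pair can carry all
        # of its markers, so at most the globally weakest marker is shadowed
        spec = GeneratorSpec(n_classes=6, n_genes=600, markers_per_class=3,
                             replicates_per_class=3, noise_sd=0.01, seed=42)
        refs, annotation = generate_references(spec)
        sig, selection, _ = construct_signature(refs, annotation)
        planted = {g for gl in planted_markers(spec).values() for g in gl}
        recovered = planted & set(sig.gene_ids)
        assert len(recovered) / len(planted) >= 0.95
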