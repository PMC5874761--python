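"""Laplace fold changes, the two-proportion test, FDR, and DAG trimming."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportions_ztest

from peptigo import (
    GoCountTable,
    adjust_pvalues,
    compare_experiments,
    laplace_proportion,
    log2_fold_change,
    proportion_test,
    trim_dag,
)
from peptigo.go_quant import UnknownNodeConfig


class TestLaplace:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(0, 99, 0.01), (99, 99, 1.0), (9, 99, 0.1)],
    )
    def test_values(self, count, total, expected):
        assert laplace_proportion(count, total) == pytest.approx(expected)

    def test_strictly_positive(self):
        assert laplace_proportion(0, 10**9) > 0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            laplace_proportion(0, 0)

    def test_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            laplace_proportion(5, 4)


class TestLog2FoldChange:
    def test_motivating_zero_count_case(self):
        assert log2_fold_change(0, 99, 3, 99) == pytest.approx(2.0)

    def test_identity(self):
        assert log2_fold_change(17, 100, 17, 100) == 0.0

    def test_antisymmetry(self):
        a = log2_fold_change(5, 200, 33, 150)
        b = log2_fold_change(33, 150, 5, 200)
        assert a == pytest.approx(-b)

    def test_always_finite(self):
        values = log2_fold_change(
            np.array([0, 0, 100]), 100, np.array([100, 0, 0]), 100
        )
        assert np.all(np.isfinite(values))


class TestProportionTest:
    def test_matches_reference_two_proportion_ztest(self):
        """Pooled z-test agrees with the statsmodels implementation."""
        cases = [(10, 100, 20, 100), (1, 50, 4, 60), (250, 5000, 300, 5100),
                 (0, 100, 5, 100), (99, 100, 90, 100)]
        for c1, n1, c2, n2 in cases:
            _, expected = proportions_ztest([c1, c2], [n1, n2])
            assert proportion_test(c1, n1, c2, n2) == pytest.approx(expected, abs=1e-10)

    def test_equal_proportions_give_p_one(self):
        assert proportion_test(17, 100, 17, 100) == 1.0

    def test_degenerate_pooled_proportion(self):
        assert proportion_test(0, 100, 0, 100) == 1.0
        assert proportion_test(100, 100, 50, 50) == 1.0

    def test_vectorized_matches_scalar(self):
        c1 = np.array([10, 1, 0])
        c2 = np.array([20, 4, 0])
        vector = proportion_test(c1, 100, c2, 100)
        scalars = [proportion_test(a, 100, b, 100) for a, b in zip(c1, c2)]
        assert np.allclose(vector, scalars)


def brute_force_bh(p):
    """Step-up BH by its definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i, idx in enumerate(order):
        q[idx] = min(
            min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0
        )
    return q


class TestAdjust:
    def test_bonferroni_caps_at_one(self):
        assert list(adjust_pvalues([0.3], "bonferroni")) == [0.3]
        assert list(adjust_pvalues([0.3] * 4, "bonferroni")) == [1.0] * 4

    def test_bh_spec_example(self):
        assert np.allclose(adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04] * 4)

    def test_bh_constant_vector_unchanged(self):
        assert np.allclose(adjust_pvalues([0.2] * 7, "bh"), [0.2] * 7)

    def test_bh_matches_brute_force_definition(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(adjust_pvalues(p, "bh"), brute_force_bh(p))

    def test_bh_monotone_in_p_rank(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        q = adjust_pvalues(p, "bh")
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh")


def make_table(counts: dict[str, int], total: int, **kwargs) -> GoCountTable:
    info = {acc: ("molecular_function", acc.lower()) for acc in counts}
    return GoCountTable(counts=counts, total_psms=total, term_info=info, **kwargs)


class TestCompareExperiments:
    def test_union_includes_single_experiment_terms(self):
        t1 = make_table({"GO:0000001": 10}, 100)
        t2 = make_table({"GO:0000001": 10, "GO:0000002": 9}, 100)
        frame = compare_experiments(t1, t2)
        row = frame[frame.go_accession == "GO:0000002"].iloc[0]
        assert row.count_1 == 0
        assert np.isfinite(row.log2_fold_change) and row.log2_fold_change > 0
        assert 0 <= row.p_value <= 1

    def test_self_comparison_is_null(self):
        t = make_table({"GO:0000001": 10, "GO:0000002": 55}, 100)
        frame = compare_experiments(t, t)
        assert (frame.log2_fold_change == 0).all()
        assert (frame.p_value == 1).all()
        assert (frame.q_value == 1).all()

    def test_swap_negates_fold_changes_and_preserves_p_q(self):
        t1 = make_table({"GO:0000001": 10, "GO:0000002": 50, "GO:0000003": 0}, 120)
        t2 = make_table({"GO:0000001": 44, "GO:0000002": 50}, 150)
        ab = compare_experiments(t1, t2).set_index("go_accession")
        ba = compare_experiments(t2, t1).set_index("go_accession")
        assert np.allclose(ab.log2_fold_change, -ba.log2_fold_change.loc[ab.index])
        assert np.allclose(ab.p_value, ba.p_value.loc[ab.index])
        assert np.allclose(ab.q_value, ba.q_value.loc[ab.index])

    def test_mismatched_unknown_configs_rejected(self):
        t1 = make_table({"GO:0000001": 10}, 100)
        t2 = make_table(
            {"GO:0000001": 10}, 100,
            unknown_config=UnknownNodeConfig(biological_process="other"),
        )
        with pytest.raises(ValueError, match="unknown-node"):
            compare_experiments(t1, t2)

    def test_mismatched_ontology_fingerprints_rejected(self):
        t1 = make_table({"GO:0000001": 10}, 100, ontology_fingerprint="aaaa")
        t2 = make_table({"GO:0000001": 10}, 100, ontology_fingerprint="bbbb")
        with pytest.raises(ValueError, match="different ontologies"):
            compare_experiments(t1, t2)

    def test_terms_laplace_denominator_mode(self):
        t1 = make_table({"GO:0000001": 0, "GO:0000002": 9}, 99)
        t2 = make_table({"GO:0000001": 3, "GO:0000002": 9}, 99)
        frame = compare_experiments(t1, t2, laplace_denominator="terms")
        row = frame.set_index("go_accession").loc["GO:0000001"]
        # (3+1)/(99+2) over (0+1)/(99+2) = 4
        assert row.log2_fold_change == pytest.approx(2.0)

    def test_planted_enrichment_ranks_first(self):
        """Terms with a planted 4-fold proportion shift attain the smallest
        q-values among 50 terms."""
        rng = np.random.default_rng(20251001)
        planted = {f"GO:{i:07d}" for i in range(5)}
        counts_1, counts_2 = {}, {}
        for i in range(50):
            acc = f"GO:{i:07d}"
            counts_1[acc] = int(rng.poisson(100))
            counts_2[acc] = int(rng.poisson(400 if acc in planted else 100))
        frame = compare_experiments(
            make_table(counts_1, 10_000), make_table(counts_2, 10_000)
        )
        top5 = set(frame.nsmallest(5, "q_value").go_accession)
        assert top5 == planted


def make_rows(q_by_node: dict[str, float], parents: dict[str, list[str]]):
    rows = pd.DataFrame(
        {
            "go_accession": list(q_by_node),
            "go_aspect": "molecular_function",
            "go_name": [f"name {acc}" for acc in q_by_node],
            "log2_fold_change": [1.0 if i % 2 == 0 else -1.0 for i in range(len(q_by_node))],
            "q_value": list(q_by_node.values()),
        }
    )

    class FakeOntology:
        roots = {"molecular_function": "root"}

        def __contains__(self, acc):
            return acc in parents

        def parents(self, acc):
            return frozenset(parents[acc])

    return rows, FakeOntology()


class TestTrimDag:
    def test_nonsignificant_leaf_removed_significant_parent_kept(self):
        rows, onto = make_rows(
            {"root": 0.9, "A": 0.005, "B": 0.5},
            {"root": [], "A": ["root"], "B": ["A"]},
        )
        trimmed = trim_dag(rows, onto, 0.01)
        assert set(trimmed.nodes) == {"root", "A"}

    def test_interior_nonsignificant_node_survives(self):
        rows, onto = make_rows(
            {"root": 0.9, "A": 0.5, "B": 0.005},
            {"root": [], "A": ["root"], "B": ["A"]},
        )
        trimmed = trim_dag(rows, onto, 0.01)
        assert set(trimmed.nodes) == {"root", "A", "B"}
        assert trimmed.nodes["A"][3] == "ns"

    def test_all_nonsignificant_empties_the_dag(self):
        rows, onto = make_rows(
            {"root": 0.9, "A": 0.5, "B": 0.6},
            {"root": [], "A": ["root"], "B": ["A"]},
        )
        assert trim_dag(rows, onto, 0.01).nodes == {}

    def test_fixed_point_and_leaf_significance(self):
        """Every leaf of the trimmed DAG is significant, and trimming the
        retained row set again changes nothing."""
        rng = np.random.default_rng(8)
        parents = {"root": []}
        q = {"root": float(rng.uniform())}
        for i in range(40):
            acc = f"n{i}"
            pool = list(parents)
            parents[acc] = list(
                rng.choice(pool, size=min(len(pool), int(rng.integers(1, 3))), replace=False)
            )
            q[acc] = float(rng.uniform())
        rows, onto = make_rows(q, parents)
        trimmed = trim_dag(rows, onto, 0.3)
        children = {acc: 0 for acc in trimmed.nodes}
        for child, parent in trimmed.edges:
            children[parent] += 1
        for acc, n in children.items():
            if n == 0:
                assert trimmed.nodes[acc][2] <= 0.3
        retained_rows = rows[rows.go_accession.isin(trimmed.nodes)]
        again = trim_dag(retained_rows, onto, 0.3)
        assert set(again.nodes) == set(trimmed.nodes)
        assert again.edges == trimmed.edges

    def test_dot_output_encodes_significance(self):
        rows, onto = make_rows(
            {"root": 0.9, "A": 0.005, "B": 0.005},
            {"root": [], "A": ["root"], "B": ["root"]},
        )
        rows.loc[rows.go_accession == "B", "log2_fold_change"] = -2.0
        rows.loc[rows.go_accession == "A", "log2_fold_change"] = 2.0
        dot = trim_dag(rows, onto, 0.01).to_dot()
        assert "parallelogram" in dot and "#ffe066" in dot  # up
        assert "#9ecae1" in dot  # down
        assert "#d9d9d9" in dot  # non-significant root
        assert '"A" -> "root"' in dot
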