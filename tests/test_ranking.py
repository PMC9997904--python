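"""Plain and penalized greedy orderings."""

import numpy as np
import pytest

from shapsets import (
    build_family,
    rank,
    rank_penalized,
    rank_sv,
    ranking_table,
    restrict_family,
    select_top,
    shapley_microarray,
)
from shapsets.ranking import resolve_top_n
from shapsets.synthetic import SyntheticSpec, generate_family

ALL_METHODS = ("SV", "PO", "POR", "AO", "AOR")
PENALIZED = ("PO", "POR", "AO", "AOR")


class TestRankSV:
    def test_orders_by_shapley_descending(self, two_set_family):
        assert rank_sv(two_set_family).order == (0, 1)

    def test_ties_broken_by_construction_order(self, disjoint_family):
        assert rank_sv(disjoint_family).order == (0, 1, 2, 3)

    def test_small_rare_set_loses_to_large_set(self):
        fam = build_family([("P1", ["a"]), ("P2", ["a", "b", "c"])])
        # ϕ(P2) = (1/3)(1/2 + 1 + 1) > ϕ(P1) = (1/3)(1/2)
        assert rank_sv(fam).order == (1, 0)

    def test_duplicates_ranked_adjacently(self):
        fam = build_family(
            [("A", ["a", "b"]), ("B", ["c", "d", "e"]), ("A2", ["a", "b"])]
        )
        order = rank_sv(fam).order
        pos = {idx: p for p, idx in enumerate(order)}
        assert abs(pos[0] - pos[2]) == 1


class TestRankPenalized:
    def test_unknown_method_rejected(self, two_set_family):
        with pytest.raises(ValueError, match="unknown method"):
            rank_penalized(two_set_family, "XX")

    def test_po_separates_exact_duplicates(self, duplicate_family):
        # hand-executed: after A is ranked, S_2(A') = ϕ_2(A') − 1 < S_2(C)
        r = rank_penalized(duplicate_family, "PO")
        assert [duplicate_family.names[i] for i in r.order] == ["A", "C", "A2"]

    def test_po_iteration_log_hand_values(self, duplicate_family):
        # iter 1: ϕ = (1/3, 1/3, 1/3), tie -> A.  iter 2: ϕ=(2/3, 1/3)
        # on {A2, C}; penalties (1, 0) -> C wins with score 1/3.
        # iter 3: A2 appended, ϕ=1, accumulated penalty 1 -> score 0.
        log = rank_penalized(duplicate_family, "PO").iteration_log
        np.testing.assert_allclose(log["shapley"], [1 / 3, 1 / 3, 1.0])
        np.testing.assert_allclose(log["penalty"], [0.0, 0.0, 1.0])
        np.testing.assert_allclose(log["score"], [1 / 3, 1 / 3, 0.0])

    @pytest.mark.parametrize("method", PENALIZED)
    def test_duplicate_never_second_under_strong_penalties(self, method,
                                                           duplicate_family):
        if method in ("PO", "AO"):
            r = rank_penalized(duplicate_family, method)
            order = [duplicate_family.names[i] for i in r.order]
            assert order[1] != "A2"
        else:
            # rescaled penalties are softer; just require a valid permutation
            r = rank_penalized(duplicate_family, method)
            assert sorted(r.order) == [0, 1, 2]

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_first_rank_is_argmax_shapley(self, method):
        fam, _ = generate_family(SyntheticSpec(n_sets=30, seed=7))
        phi = shapley_microarray(fam).scores
        assert rank(fam, method).order[0] == int(np.argmax(phi))

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_emits_a_permutation(self, method):
        fam, _ = generate_family(SyntheticSpec(n_sets=25, seed=3))
        order = rank(fam, method).order
        assert sorted(order) == list(range(fam.n_sets))

    @pytest.mark.parametrize("method", PENALIZED)
    def test_disjoint_family_reproduces_sv(self, method, disjoint_family):
        assert rank(disjoint_family, method).order == rank_sv(disjoint_family).order

    @pytest.mark.parametrize("method", PENALIZED)
    def test_per_iteration_efficiency(self, method):
        fam, _ = generate_family(SyntheticSpec(n_sets=20, seed=11))
        r = rank_penalized(fam, method)
        for n in range(fam.n_sets - 1):
            sub = restrict_family(fam, list(r.order[n:]))
            assert abs(shapley_microarray(sub).scores.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("method", ("POR", "AOR"))
    def test_rescaled_penalty_bounded_by_max_shapley(self, method):
        fam, _ = generate_family(SyntheticSpec(n_sets=25, seed=5))
        r = rank_penalized(fam, method)
        log = r.iteration_log
        for n in range(1, fam.n_sets):
            sub = restrict_family(fam, list(r.order[n:]))
            max_phi = shapley_microarray(sub).scores.max()
            penalty = log.loc[log["position"] == n + 1, "penalty"].item()
            assert -1e-15 <= penalty <= max_phi + 1e-12

    def test_po_scores_may_go_negative(self):
        # heavy overlap drives raw accumulated penalties above ϕ
        fam = build_family(
            [(f"S{i}", ["x", "y", f"p{i}"]) for i in range(6)]
        )
        log = rank_penalized(fam, "PO").iteration_log
        assert (log["score"] < 0).any()

    def test_deterministic_across_runs(self):
        fam, _ = generate_family(SyntheticSpec(n_sets=20, seed=2))
        assert rank_penalized(fam, "AOR").order == rank_penalized(fam, "AOR").order


class TestSelectTop:
    def test_top_one_is_argmax(self, two_set_family):
        sub = select_top(two_set_family, rank_sv(two_set_family), 1)
        assert sub.names == ("P1",)

    def test_top_all_preserves_membership(self, triangle_family):
        r = rank_sv(triangle_family)
        sub = select_top(triangle_family, r, 1.0)
        assert set(sub.names) == set(triangle_family.names)
        assert {frozenset(m) for m in sub.members} == {
            frozenset(m) for m in triangle_family.members
        }

    def test_fraction_rounds_half_up(self):
        assert resolve_top_n(0.4, 10) == 4
        assert resolve_top_n(0.25, 10) == 3  # 2.5 rounds up
        with pytest.raises(ValueError):
            resolve_top_n(0.01, 10)  # rounds to zero sets

    def test_out_of_range_rejected(self, two_set_family):
        r = rank_sv(two_set_family)
        with pytest.raises(ValueError):
            select_top(two_set_family, r, 3)


def test_ranking_table_schema_and_monotone_coverage():
    fam, _ = generate_family(SyntheticSpec(n_sets=15, seed=4))
    table = ranking_table(fam, rank_penalized(fam, "PO"))
    assert list(table.columns) == [
        "rank", "set_name", "set_size", "total_score", "shapley_component",
        "penalty_component", "cumulative_coverage_percent",
        "cumulative_jaccard_score",
    ]
    cov = table["cumulative_coverage_percent"].to_numpy()
    assert (np.diff(cov) >= 0).all() and cov[-1] == pytest.approx(100.0)
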