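"""Scoring engine: tier predicates, precedence, ranking and table outputs."""

from __future__ import annotations

import itertools

import pytest

from unired_rank import (AnalysisError, ClusterSet, ComplexTable, ScoreScheme,
                         build_kb, evidence_table, excluded_table, rank,
                         score_lists, score_pair)

from conftest import make_tier_kb
from _oracles import first_true_tier, tier_predicates

Q, R = "Q00001", "Q00002"


class TestTierPrecedence:
    @pytest.mark.parametrize("flags", list(itertools.product([False, True],
                                                             repeat=4)))
    def test_first_true_tier_wins(self, flags):
        """Over all 16 truth combinations the reported association type is
        the first satisfied tier, matching the brute-force evaluator."""
        kb = make_tier_kb(*flags)
        assert tier_predicates(kb, Q, R, "human") == flags
        expected = first_true_tier(flags)
        ev = score_pair(kb, Q, R, "human")
        if expected is None:
            assert ev is None
        else:
            assert ev.association_type == expected

    def test_tier_scores(self):
        scheme = ScoreScheme()
        for flags, score in [((True, False, False, False), 1.0),
                             ((False, True, False, False), 0.5),
                             ((False, False, True, False), 0.5),
                             ((False, False, False, True), 0.5)]:
            ev = score_pair(make_tier_kb(*flags), Q, R, "human", scheme)
            assert ev.score == score

    def test_evidence_pairs(self):
        ev = score_pair(make_tier_kb(True, False, False, False), Q, R, "human")
        assert ev.evidence_pair == (Q, R)
        ev = score_pair(make_tier_kb(False, True, False, False), Q, R, "human")
        assert ev.evidence_pair == ("Q00003", R)  # the paralogue + reference
        ev = score_pair(make_tier_kb(False, False, True, False), Q, R, "human")
        assert ev.evidence_pair == ("Q00004", R)  # the complex partner + reference
        ev = score_pair(make_tier_kb(False, False, False, True), Q, R, "human")
        assert ev.evidence_pair == ("O00001", "O00002")  # the two orthologues

    def test_unclustered_accession_is_a_precondition_violation(self):
        kb = make_tier_kb(True, False, False, False)
        with pytest.raises(AnalysisError):
            score_pair(kb, "P99999", R, "human")


class TestComplexModes:
    def _kb(self):
        """Reference is a member of the query's complex, but no complex
        partner of the query shares a cluster with the reference."""
        return build_kb(
            cluster_sets={"human": ClusterSet(species="human", clusters={
                "KQ": {"Q00001"}, "KR": {"Q00002"}})},
            complex_tables={"human": ComplexTable(species="human", complexes={
                "CPX-1": {"Q00001", "Q00002"}})},
        )

    def test_partner_reading_does_not_fire(self):
        # the only complex partner of the query IS the reference, and it is
        # not co-clustered with itself's cluster... with the reference's own
        # cluster it is, actually — partner == reference shares every cluster
        # with itself, so the partner reading fires here too.
        ev = score_pair(self._kb(), "Q00001", "Q00002", "human",
                        complex_mode="partner")
        assert ev is not None and ev.association_type == "Complex"

    def test_member_reading_fires_without_coclustering(self):
        kb = build_kb(
            cluster_sets={"human": ClusterSet(species="human", clusters={
                "KQ": {"Q00001"}, "KR": {"Q00002"}, "KM": {"Q00003"}})},
            complex_tables={"human": ComplexTable(species="human", complexes={
                "CPX-1": {"Q00001", "Q00002"}, "CPX-2": {"Q00001", "Q00003"}})},
        )
        # partner Q00003 is in its own cluster, away from the reference:
        # partner reading still fires through the reference itself (a complex
        # co-member); member reading fires because the reference is a member.
        member = score_pair(kb, "Q00001", "Q00002", "human",
                            complex_mode="member")
        assert member.association_type == "Complex"
        assert member.evidence_pair == ("Q00001", "Q00002")

    def test_modes_diverge_when_reference_not_in_complex(self):
        kb = make_tier_kb(False, False, True, False)
        partner = score_pair(kb, Q, R, "human", complex_mode="partner")
        member = score_pair(kb, Q, R, "human", complex_mode="member")
        assert partner.association_type == "Complex"
        assert member is None  # reference is not a member of the complex


class TestScoreLists:
    def _toy_kb(self):
        # q1 in-cluster with r1; paralogue of q1 co-clustered with r2
        return build_kb(
            cluster_sets={"human": ClusterSet(species="human", clusters={
                "K1": {"Q00001", "R00001"},
                "K2": {"P00010", "R00002"},
                "K3": {"Q00005"},
            })},
            paralogue_pairs={"human": {frozenset(("Q00001", "P00010"))}},
        )

    def test_overall_is_sum_of_pairwise_scores(self):
        res = score_lists(self._toy_kb(), ["Q00001"], ["R00001", "R00002"],
                          "human")
        assert res.overall["Q00001"] == pytest.approx(1.5)
        assert res.matrix["Q00001"] == {"R00001": 1.0, "R00002": 0.5}

    def test_unclustered_proteins_go_to_excluded(self):
        res = score_lists(self._toy_kb(), ["Q00001", "P99999"],
                          ["R00001", "A00000"], "human")
        assert ("P99999", "query") in res.excluded
        assert ("A00000", "reference") in res.excluded
        assert "P99999" not in res.overall

    def test_all_queries_excluded_is_user_error(self):
        with pytest.raises(AnalysisError, match="no analyzable query"):
            score_lists(self._toy_kb(), ["P99999"], ["R00001"], "human")

    def test_zero_evidence_query_is_ranked_not_excluded(self):
        res = score_lists(self._toy_kb(), ["Q00005"], ["R00001"], "human")
        assert res.overall["Q00005"] == 0.0
        assert res.excluded == []
        assert res.ranking == ["Q00005"]

    def test_invariant_to_order_and_duplicates(self):
        kb = self._toy_kb()
        a = score_lists(kb, ["Q00001", "Q00005"], ["R00001", "R00002"], "human")
        b = score_lists(kb, ["Q00005", "Q00001", "Q00005"],
                        ["R00002", "R00001", "R00001"], "human")
        assert a.matrix == b.matrix and a.ranking == b.ranking

    def test_overall_totals_match_evidence_table(self, planted):
        kb, manifest = planted
        res = score_lists(kb, manifest["query"], manifest["reference"], "human")
        assert sum(res.overall.values()) == pytest.approx(
            sum(ev.score for ev in res.evidence))

    def test_scoring_is_asymmetric(self):
        # paralogue expansion applies to the query side only
        kb = build_kb(
            cluster_sets={"human": ClusterSet(species="human", clusters={
                "K1": {"Q00001"}, "K2": {"P00010", "R00001"}})},
            paralogue_pairs={"human": {frozenset(("Q00001", "P00010"))}},
        )
        forward = score_lists(kb, ["Q00001"], ["R00001"], "human")
        backward = score_lists(kb, ["R00001"], ["Q00001"], "human")
        assert forward.overall["Q00001"] == 0.5
        assert backward.overall["R00001"] == 0.0

    def test_removing_a_reference_never_increases_overalls(self, planted):
        kb, manifest = planted
        refs = manifest["reference"]
        full = score_lists(kb, manifest["query"], refs, "human")
        for drop in refs[:3]:
            reduced = score_lists(kb, manifest["query"],
                                  [r for r in refs if r != drop], "human")
            for q in reduced.overall:
                assert reduced.overall[q] <= full.overall[q] + 1e-12

    def test_self_pairs_skipped_by_default(self):
        kb = build_kb(cluster_sets={"human": ClusterSet(
            species="human", clusters={"K1": {"Q00001", "Q00002"}})})
        skipped = score_lists(kb, ["Q00001"], ["Q00001", "Q00002"], "human")
        assert "Q00001" not in skipped.matrix["Q00001"]
        kept = score_lists(kb, ["Q00001"], ["Q00001", "Q00002"], "human",
                           skip_self_pairs=False)
        assert kept.matrix["Q00001"]["Q00001"] == 1.0


class TestRank:
    def _result(self, overalls):
        kb = build_kb(cluster_sets={"human": ClusterSet(
            species="human",
            clusters={f"K{i}": {acc} for i, acc in enumerate(
                list(overalls) + ["R00001"])})})
        res = score_lists(kb, list(overalls), ["R00001"], "human")
        res.overall.update(overalls)
        res.ranking = sorted(res.overall, key=lambda q: (-res.overall[q], q))
        return res

    def test_ties_break_lexicographically(self):
        res = self._result({"A00001": 1.5, "B00001": 0.5, "C00001": 1.5})
        assert res.ranking == ["A00001", "C00001", "B00001"]
        table = rank(res)
        assert list(table["Overall"]) == [1.5, 1.5, 0.5]

    def test_all_zero_is_lexicographic(self):
        res = self._result({"C00001": 0.0, "A00001": 0.0, "B00001": 0.0})
        assert res.ranking == ["A00001", "B00001", "C00001"]

    def test_label_falls_back_to_bare_accession(self, planted):
        kb, manifest = planted
        res = score_lists(kb, manifest["query"], manifest["reference"], "human")
        table = rank(res)
        for acc in res.ranking:
            rec = kb.records[acc]
            label = f"{acc} ({rec.gene_name})" if rec.gene_name else acc
            assert label in table.index

    def test_evidence_and_excluded_tables_shapes(self, planted):
        kb, manifest = planted
        res = score_lists(kb, manifest["query"] + ["A99999"],
                          manifest["reference"], "human")
        ev = evidence_table(res)
        assert list(ev.columns) == ["query", "reference", "association_type",
                                    "evidence_pair", "score"]
        assert len(ev) == len(res.evidence)
        ex = excluded_table(res)
        assert ("A99999" in set(ex["accession"]))
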