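"""Hypergeometric enrichment, BH-FDR, and the ranking/bubble utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from netpharm.enrich import (AnnotationTerm, bh_fdr, bubble_table, enrich,
                             hypergeometric_upper_tail, top_by_gene_percentage)


class TestHypergeometricTail:
    def test_enumerated_example(self):
        # drawing 4 of 10 with 5 marked: only C(5,4) of C(10,4) draws give k=4
        assert hypergeometric_upper_tail(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_trivial_tails(self):
        assert hypergeometric_upper_tail(0, 5, 4, 10) == 1.0
        assert hypergeometric_upper_tail(3, 3, 3, 3) == 1.0

    def test_matches_one_sided_fisher(self):
        """Independent cross-check: the tail equals the one-sided Fisher
        exact p on the corresponding 2x2 table."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            N = int(rng.integers(10, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            table = [[k, K - k], [n - k, N - K - n + k]]
            _, p_fisher = fisher_exact(table, alternative="greater")
            assert hypergeometric_upper_tail(k, K, n, N) == pytest.approx(p_fisher, rel=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(6, 5, 4, 10)
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(1, 11, 4, 10)


class TestBhFdr:
    def test_hand_computed_examples(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr([0.04, 0.5]) == pytest.approx([0.08, 0.5])
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_input_order_preserved(self):
        q = bh_fdr([0.5, 0.01, 0.04])
        assert q[1] < q[2] < q[0]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0, exclude_min=False), min_size=1, max_size=40))
    def test_q_dominates_p_and_caps_at_one(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)
        # order-preserving: smaller p never gets a larger q
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


def _term(tid, genes, cat="pathway"):
    return AnnotationTerm(tid, tid, cat, frozenset(genes))


class TestEnrich:
    def test_zero_overlap_terms_absent(self):
        res = enrich({"A", "B"}, [_term("T1", {"X", "Y"})], {"A", "B", "X", "Y"})
        assert res == []

    def test_query_equals_universe_saturates(self):
        uni = {f"G{i}" for i in range(20)}
        res = enrich(uni, [_term("T1", set(list(uni)[:5]))], uni)
        assert res[0].p_value == pytest.approx(1.0)

    def test_results_sorted_and_fields_consistent(self):
        uni = {f"G{i}" for i in range(100)}
        query = {f"G{i}" for i in range(10)}
        terms = [_term("T1", {f"G{i}" for i in range(8)}),          # strong overlap
                 _term("T2", {f"G{i}" for i in range(50, 80)})]     # none
        terms.append(_term("T3", {"G0", "G50", "G51", "G52"}))       # weak
        res = enrich(query, terms, uni)
        assert [r.term.term_id for r in res] == ["T1", "T3"]
        for r in res:
            assert r.rich_factor == pytest.approx(r.overlap / r.term_size)
            assert r.gene_percentage == pytest.approx(100 * r.overlap / r.query_size)
            assert r.q_value >= r.p_value - 1e-12

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich({"A", "Z"}, [_term("T1", {"A"})], {"A", "B"})
        with pytest.raises(ValueError):
            enrich({"A"}, [_term("T1", {"A"})], set())

    def test_default_universe_is_collection_plus_query(self):
        res = enrich({"A"}, [_term("T1", {"A", "B", "C"})])
        assert res[0].universe_size == 3


class TestRankingHelpers:
    def _results(self):
        uni = {f"G{i}" for i in range(40)}
        query = {f"G{i}" for i in range(12)}
        terms = [
            _term("BP1", {f"G{i}" for i in range(6)}, "BP"),
            _term("BP2", {f"G{i}" for i in range(3, 12)}, "BP"),
            _term("PW1", {f"G{i}" for i in range(4)}, "pathway"),
        ]
        return enrich(query, terms, uni)

    def test_top_by_gene_percentage_category_filter(self):
        res = self._results()
        top_bp = top_by_gene_percentage(res, m=10, category="BP")
        assert all(r.term.category == "BP" for r in top_bp)
        pcts = [r.gene_percentage for r in top_bp]
        assert pcts == sorted(pcts, reverse=True)

    def test_top_truncation_and_tie_rule(self):
        res = self._results()
        assert len(top_by_gene_percentage(res, m=1)) == 1
        # equal percentages fall back to ascending p
        tied = top_by_gene_percentage(res, m=len(res))
        for a, b in zip(tied, tied[1:]):
            if a.gene_percentage == b.gene_percentage:
                assert a.p_value <= b.p_value

    def test_bubble_table_projection(self):
        res = self._results()
        tbl = bubble_table(res, categories=("pathway",))
        sig_pw = [r for r in res if r.significant and r.term.category == "pathway"]
        assert len(tbl) == len(sig_pw)
        for row, r in zip(tbl.itertuples(index=False), sig_pw):
            assert row.rich_factor == pytest.approx(r.rich_factor)
            assert row.q_value == pytest.approx(r.q_value)
            assert row.overlap == r.overlap

    def test_bubble_table_empty_when_nothing_significant(self):
        uni = {f"G{i}" for i in range(10)}
        res = enrich(uni, [_term("T1", set(list(uni)[:4]))], uni)  # p == 1
        assert bubble_table(res).empty


def test_planted_term_recovered_in_study(study):
    """The fold-5 planted pathway ranks first against 49 background terms."""
    res = enrich(study.common_targets, study.annotations, study.universe)
    assert res[0].term.term_id == study.config.planted_term_id
    assert res[0].significant
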