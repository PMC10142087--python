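"""Synthetic-input generators: planted structure, cardinalities, determinism."""

import numpy as np
import pandas as pd
import pytest

from netpharm.screen import count_lipinski_violations, is_druglike
from netpharm.synth import (GeneratorConfig, gen_annotations, gen_associations,
                            gen_compounds, gen_disease_sets, gen_gene_universe,
                            gen_ppi, generate_study)


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if a | b else 0.0


class TestGenCompounds:
    def test_no_violators_all_druglike(self):
        df = gen_compounds(27, 0.0, seed=1)
        assert len(df) == 27
        for row in df.itertuples(index=False):
            assert count_lipinski_violations(row.mw, row.hba, row.hbd, row.mlogp) <= 1
            assert is_druglike(row._asdict())

    def test_violator_fraction_exact(self):
        df = gen_compounds(20, 0.5, seed=3)
        n_bad = sum(
            count_lipinski_violations(r.mw, r.hba, r.hbd, r.mlogp) >= 2
            for r in df.itertuples(index=False)
        )
        assert n_bad == 10

    def test_descriptor_ranges_physical(self):
        df = gen_compounds(50, 0.4, seed=9)
        assert df["mw"].between(50, 900).all()
        assert df["hba"].between(0, 15).all()
        assert df["hbd"].between(0, 8).all()
        assert df["mlogp"].between(-3, 7).all()
        assert df["bioavailability"].isin([0.11, 0.17, 0.55, 0.56, 0.85]).all()

    def test_empty_and_determinism(self):
        assert len(gen_compounds(0, 0.5, seed=1)) == 0
        pd.testing.assert_frame_equal(gen_compounds(10, 0.5, seed=7),
                                      gen_compounds(10, 0.5, seed=7))

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gen_compounds(-1, 0.0, seed=1)
        with pytest.raises(ValueError):
            gen_compounds(5, 1.5, seed=1)


class TestGenUniverse:
    def test_cardinality_unique_upper(self):
        u = gen_gene_universe(100, seed=3)
        assert len(u) == 100 == len(set(u))
        assert all(s == s.upper() for s in u)

    def test_empty_and_seed_sensitivity(self):
        assert gen_gene_universe(0, seed=3) == []
        assert gen_gene_universe(100, seed=3) == gen_gene_universe(100, seed=3)
        assert gen_gene_universe(100, seed=3) != gen_gene_universe(100, seed=4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gen_gene_universe(-5)


class TestGenAssociations:
    def setup_method(self):
        self.universe = gen_gene_universe(500, seed=0)
        self.compounds = [f"C{i:03d}" for i in range(20)]

    def _pools(self, df_a, df_b):
        return set(df_a["gene_symbol"]), set(df_b["gene_symbol"])

    def test_overlap_half(self):
        df_a, df_b = gen_associations(self.compounds, self.universe, overlap=0.5, seed=2)
        a, b = self._pools(df_a, df_b)
        assert 0.4 <= _jaccard(a, b) <= 0.6

    def test_overlap_limits(self):
        df_a, df_b = gen_associations(self.compounds, self.universe, overlap=1.0, seed=2)
        a, b = self._pools(df_a, df_b)
        assert a == b
        df_a, df_b = gen_associations(self.compounds, self.universe, overlap=0.0, seed=2)
        a, b = self._pools(df_a, df_b)
        assert not a & b

    def test_genes_within_universe_and_compounds_known(self):
        df_a, df_b = gen_associations(self.compounds, self.universe, overlap=0.3, seed=5)
        uni = set(self.universe)
        for df in (df_a, df_b):
            assert set(df["gene_symbol"]) <= uni
            assert set(df["compound_id"]) <= set(self.compounds)

    def test_bad_overlap_rejected(self):
        with pytest.raises(ValueError):
            gen_associations(self.compounds, self.universe, overlap=1.2)


class TestGenDiseaseSets:
    def setup_method(self):
        self.universe = gen_gene_universe(300, seed=1)
        self.targets = set(self.universe[:80])

    def _union(self, frames):
        return set().union(*(set(f["gene_symbol"]) for f in frames))

    def test_exact_hit_overlap(self):
        frames = gen_disease_sets(self.universe, (60, 30, 50), 42, self.targets, seed=4)
        assert len(self._union(frames) & self.targets) == 42

    def test_zero_overlap_disjoint(self):
        frames = gen_disease_sets(self.universe, (30, 20, 25), 0, self.targets, seed=4)
        assert not self._union(frames) & self.targets

    def test_union_bounded_by_universe(self):
        small = self.universe[:15]
        frames = gen_disease_sets(small, (10, 10, 10), 3, set(small[:5]), seed=4)
        assert len(self._union(frames)) <= 15

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_disease_sets(self.universe, (5, 5, 5), 200, self.targets, seed=1)
        with pytest.raises(ValueError):
            gen_disease_sets(self.universe, (1000, 5, 5), 3, self.targets, seed=1)


class TestGenPpi:
    def test_hub_degree_with_full_coverage(self):
        nodes = [f"N{i}" for i in range(10)]
        df = gen_ppi(nodes, "N0", clique_sizes=[3], background_edge_prob=0.0,
                     seed=6, hub_coverage=1.0)
        deg = ((df["protein1"] == "N0") | (df["protein2"] == "N0")).sum()
        assert deg == 9

    def test_complete_graph_edge_count(self):
        df = gen_ppi([f"N{i}" for i in range(5)], "N0", clique_sizes=[],
                     background_edge_prob=1.0, seed=6)
        assert len(df) == 10

    def test_simple_graph_and_determinism(self):
        nodes = [f"N{i}" for i in range(30)]
        df = gen_ppi(nodes, "N0", seed=8)
        assert (df["protein1"] != df["protein2"]).all()
        pairs = set(map(frozenset, zip(df["protein1"], df["protein2"])))
        assert len(pairs) == len(df)
        pd.testing.assert_frame_equal(df, gen_ppi(nodes, "N0", seed=8))

    def test_planted_edges_survive_medium_confidence(self):
        nodes = [f"N{i}" for i in range(20)]
        df = gen_ppi(nodes, "N0", clique_sizes=[4], background_edge_prob=0.0, seed=3)
        assert (df["combined_score"] >= 700).all()

    def test_hub_not_in_nodes_rejected(self):
        with pytest.raises(ValueError):
            gen_ppi(["A", "B"], "Z", seed=1)


class TestGenAnnotations:
    def test_empty_collection(self):
        assert gen_annotations(gen_gene_universe(50, 1), n_terms=0) == []

    def test_planted_overlap_exceeds_fold_expectation(self):
        universe = gen_gene_universe(2000, seed=2)
        query = set(universe[:42])
        terms = gen_annotations(universe, 20, (30, 80), "PW1", query, fold=5.0, seed=2)
        planted = terms[0]
        assert planted.term_id == "PW1"
        K, N, n = len(planted.genes), 2000, 42
        assert len(planted.genes & query) >= 5.0 * K * n / N

    def test_all_genes_from_universe(self):
        universe = gen_gene_universe(200, seed=3)
        terms = gen_annotations(universe, 10, (10, 30), "PW1",
                                set(universe[:20]), 2.0, seed=3)
        for t in terms:
            assert t.genes <= set(universe)

    def test_oversized_terms_rejected(self):
        with pytest.raises(ValueError):
            gen_annotations(gen_gene_universe(10, 1), 5, (5, 50))


class TestGeneratorConfigAndStudy:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(source_overlap=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(planted_term_fold=0.5)
        with pytest.raises(ValueError):
            GeneratorConfig(clique_sizes=(1,))

    def test_study_plants_recoverable_structure(self, study):
        assert study.config.planted_hub in study.common_targets
        assert len(study.common_targets) == study.config.hit_overlap
        assert len(study.connected_compounds) == 21
        assert len(study.orphan_compounds) == 6
        # orphans never touch the common targets
        common = set(study.common_targets)
        for df in (study.assoc_a, study.assoc_b):
            hits = df[df["gene_symbol"].isin(common)]
            assert not set(hits["compound_id"]) & set(study.orphan_compounds)

    def test_study_byte_identical_under_seed(self, tmp_path, study):
        from netpharm.synth import write_study
        a = write_study(generate_study(GeneratorConfig(seed=11)), tmp_path / "a")
        b = write_study(generate_study(GeneratorConfig(seed=11)), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key
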