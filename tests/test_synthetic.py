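"""Generators must plant exactly what they claim, deterministically."""

from math import comb

import numpy as np
import pytest

from targetnet.disease_genes import filter_source
from targetnet.synthetic import (
    gene_symbols,
    simulate_expression,
    simulate_genesets,
    simulate_ppi,
    simulate_sources,
    simulate_study,
)


class TestSimulateExpression:
    def test_null_case_plants_nothing(self):
        m, truth = simulate_expression(100, 32, 0, 2.0, 1.0, seed=7)
        assert truth.de_genes == frozenset()
        # both groups share the gene-wise means: global mean difference ~ 0
        diff = (
            m.data[m.case_columns].mean(axis=1) - m.data[m.control_columns].mean(axis=1)
        )
        assert abs(diff.mean()) < 0.1

    def test_bookkeeping_and_updown_split(self):
        m, truth = simulate_expression(100, 32, 10, 2.0, 0.5, seed=7)
        assert len(truth.de_genes) == 10
        assert m.data.shape == (100, 64)
        diff = (
            m.data[m.case_columns].mean(axis=1) - m.data[m.control_columns].mean(axis=1)
        )
        up = sum(diff[g] > 1.0 for g in truth.de_genes)
        down = sum(diff[g] < -1.0 for g in truth.de_genes)
        assert (up, down) == (5, 5)

    def test_odd_remainder_goes_up(self):
        m, truth = simulate_expression(50, 8, 7, 3.0, 0.3, seed=1)
        diff = (
            m.data[m.case_columns].mean(axis=1) - m.data[m.control_columns].mean(axis=1)
        )
        up = sum(diff[g] > 1.5 for g in truth.de_genes)
        assert up == 4  # ceil(7/2)

    def test_seed_determinism(self):
        a, _ = simulate_expression(100, 32, 10, 2.0, 0.5, seed=7)
        b, _ = simulate_expression(100, 32, 10, 2.0, 0.5, seed=7)
        c, _ = simulate_expression(100, 32, 10, 2.0, 0.5, seed=8)
        assert a.data.equals(b.data)
        assert not a.data.equals(c.data)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=10, n_per_group=32, n_de=11, effect_log2fc=2.0, noise_sd=1.0),
            dict(n_genes=10, n_per_group=32, n_de=2, effect_log2fc=2.0, noise_sd=0.0),
            dict(n_genes=10, n_per_group=1, n_de=2, effect_log2fc=2.0, noise_sd=1.0),
            dict(n_genes=10, n_per_group=4, n_de=2, effect_log2fc=-1.0, noise_sd=1.0),
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            simulate_expression(seed=0, **kwargs)


class TestSimulatePpi:
    def test_clique_is_pairwise_adjacent(self):
        net, truth = simulate_ppi(30, 0.05, 6, seed=1)
        clique = sorted(truth.clique_genes)
        assert len(clique) == 6
        for i, a in enumerate(clique):
            for b in clique[i + 1 :]:
                assert net.has_edge(a, b)

    def test_vanishing_background_leaves_only_the_clique(self):
        net, _ = simulate_ppi(30, 1e-9, 6, seed=1)
        assert net.n_edges == comb(6, 2)

    def test_clique_edges_score_above_point_nine(self):
        net, truth = simulate_ppi(20, 0.2, 5, seed=3)
        clique = truth.clique_genes
        for a, b, s in net.edge_rows():
            if a in clique and b in clique:
                assert s > 0.9
            assert 0.0 < s <= 1.0

    def test_determinism_and_no_self_loops(self):
        n1, _ = simulate_ppi(30, 0.1, 5, seed=9)
        n2, _ = simulate_ppi(30, 0.1, 5, seed=9)
        assert n1.edge_rows() == n2.edge_rows()
        assert all(a != b for a, b, _ in n1.edge_rows())

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_ppi(30, 1.5, 6, seed=1)
        with pytest.raises(ValueError):
            simulate_ppi(5, 0.1, 6, seed=1)


class TestSimulateGenesets:
    def test_planted_set_covers_members(self):
        universe = gene_symbols(50)
        planted = set(universe[:3])
        coll, truth = simulate_genesets(universe, 5, (5, 10), planted, seed=2)
        _, members = coll.sets[truth.enriched_set_id]
        assert planted <= members

    def test_single_set_collection(self):
        coll, _ = simulate_genesets(gene_symbols(30), 1, (5, 10), set(), seed=2)
        assert len(coll) == 1

    def test_gmt_output_deterministic(self, tmp_path):
        paths = []
        for run in (1, 2):
            coll, _ = simulate_genesets(gene_symbols(40), 6, (5, 10), set(), seed=4)
            p = tmp_path / f"run{run}.gmt"
            coll.to_gmt(p)
            paths.append(p.read_text())
        assert paths[0] == paths[1]

    def test_exclusion_keeps_fill_away(self):
        universe = gene_symbols(60)
        excluded = set(universe[10:30])
        coll, truth = simulate_genesets(
            universe, 3, (15, 15), set(universe[:3]), seed=5,
            exclude_from_fill=excluded,
        )
        _, members = coll.sets[truth.enriched_set_id]
        assert not (members & excluded)

    def test_planted_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            simulate_genesets(gene_symbols(10), 3, (2, 4), {"ZZZ"}, seed=0)


class TestSimulateSources:
    def test_every_filter_boundary_is_straddled(self):
        tables = simulate_sources(gene_symbols(100), seed=6)
        assert {t.source_name for t in tables} == {
            "CTD", "DisGeNET", "GeneCards", "OMIM", "PharmGKB", "TTD",
        }
        for t in tables:
            kept = filter_source(t)
            if t.source_name in {"PharmGKB", "TTD"}:
                assert len(kept) == len(t.records)
            else:
                assert 0 < len(kept) < len(t.records)


class TestSimulateStudy:
    def test_truth_is_internally_consistent(self):
        bundle = simulate_study(seed=11)
        truth = bundle.truth
        assert truth.target_genes <= truth.clique_genes
        _, members = bundle.collection.sets[truth.enriched_set_id]
        assert truth.target_genes <= members
        universe = set(bundle.expression.data.index)
        assert truth.de_genes <= universe
        assert truth.clique_genes <= universe
        # pathway fill avoids the rest of the clique
        assert not (members & (truth.clique_genes - truth.target_genes))

    def test_study_determinism(self):
        a = simulate_study(seed=3)
        b = simulate_study(seed=3)
        assert a.truth == b.truth
        assert a.ppi.edge_rows() == b.ppi.edge_rows()
        assert a.expression.data.equals(b.expression.data)
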