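"""Hypergeometric enrichment, BH, lineage/cluster pruning, enrichment maps."""

import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest

import chemofit as cf
from chemofit.enrichment import (
    EnrichmentRow,
    GeneSetCollection,
    enrich_query,
    propagate_annotations,
    prune,
    rows_to_frame,
)


def exact_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) by counting draws; independent of scipy."""
    total = comb(N, n)
    hits = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(hits, total)


class TestHypergeom:
    def test_two_of_two_in_four(self):
        # all C(4,2)=6 draws: exactly one contains both marked elements
        assert cf.hypergeom_pvalue(2, 2, 2, 4) == pytest.approx(1 / 6, abs=1e-12)

    def test_k_zero_is_one(self):
        assert cf.hypergeom_pvalue(0, 5, 3, 10) == 1.0

    def test_query_equals_universe(self):
        assert cf.hypergeom_pvalue(4, 4, 8, 8) == 1.0

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            cf.hypergeom_pvalue(3, 2, 5, 10)

    def test_small_grid_against_enumeration(self):
        for N in (5, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = float(exact_upper_tail(k, K, n, N))
                        assert cf.hypergeom_pvalue(k, K, n, N) == pytest.approx(
                            expected, abs=1e-12
                        )


class TestBH:
    def test_hand_step_up(self):
        out = cf.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_value_unchanged(self):
        assert cf.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(1e-6, 1, size=50)
        q = cf.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-15).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            cf.bh_adjust([0.0, 0.5])


def toy_collection():
    universe = frozenset(f"g{i}" for i in range(100))
    sets = {
        "T:A": frozenset(f"g{i}" for i in range(20)),
        "T:B": frozenset(f"g{i}" for i in range(10)),
        "T:C": frozenset(f"g{i}" for i in range(50, 70)),
    }
    names = {t: t for t in sets}
    return GeneSetCollection(sets=sets, names=names, universe=universe)


class TestLoadGeneSets:
    def _write_gmt(self, tmp_path, sizes):
        lines = []
        for i, size in enumerate(sizes):
            genes = "\t".join(f"g{j}" for j in range(size))
            lines.append(f"S{i}\tset {i} (n={size})\t{genes}")
        path = tmp_path / "sets.gmt"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_size_filter_boundaries(self, tmp_path):
        path = self._write_gmt(tmp_path, [4, 5, 300, 301])
        collection, dag = cf.load_gene_sets(path)
        assert set(collection.sets) == {"S1", "S2"}  # 5 and 300 kept
        assert dag.number_of_edges() == 0

    def _write_obo_gaf(self, tmp_path, cyclic=False):
        obo = [
            "format-version: 1.2", "",
            "[Term]", "id: T:0001", "name: root", "",
            "[Term]", "id: T:0002", "name: mid", "is_a: T:0001 ! root", "",
            "[Term]", "id: T:0003", "name: leaf",
            "relationship: part_of T:0002 ! mid", "",
        ]
        if cyclic:
            obo += ["[Term]", "id: T:0004", "name: c1", "is_a: T:0005 ! c2", "",
                    "[Term]", "id: T:0005", "name: c2", "is_a: T:0004 ! c1", ""]
        (tmp_path / "toy.obo").write_text("\n".join(obo) + "\n")
        gaf_rows = []
        # leaf gets 5 genes; mid gets 1 direct gene; root gets none directly
        for i in range(5):
            gaf_rows.append(("leafG%d" % i, "T:0003"))
        gaf_rows.append(("midG", "T:0002"))
        lines = ["!gaf-version: 2.2"]
        for gene, term in gaf_rows:
            cols = ["SGD", gene, gene, "", term, "PMID:1", "IDA", "", "P",
                    gene, "", "protein", "taxon:4932", "20200101", "SGD"]
            lines.append("\t".join(cols))
        (tmp_path / "toy.gaf").write_text("\n".join(lines) + "\n")
        return tmp_path / "toy.gaf", tmp_path / "toy.obo"

    def test_propagation_before_filtering(self, tmp_path):
        """The true-path rule runs before the size filter: the 5 leaf genes
        propagate up through part_of and is_a, so mid (6) and root (6) pass
        the >= 5 filter while the leaf itself (5) also passes."""
        gaf, obo = self._write_obo_gaf(tmp_path)
        collection, dag = cf.load_gene_sets(gaf, obo)
        assert set(collection.sets) == {"T:0001", "T:0002", "T:0003"}
        assert collection.sets["T:0002"] == collection.sets["T:0003"] | {"midG"}
        assert collection.sets["T:0001"] == collection.sets["T:0002"]
        assert nx.has_path(dag, "T:0003", "T:0001")

    def test_cycle_detected(self, tmp_path):
        gaf, obo = self._write_obo_gaf(tmp_path, cyclic=True)
        with pytest.raises(ValueError, match="cycle"):
            cf.load_gene_sets(gaf, obo)


class TestEnrichQuery:
    def test_planted_term_has_smallest_p(self):
        """All 20 members of T:A sensitive in a query of 25 from N=100."""
        coll = toy_collection()
        query = set(f"g{i}" for i in range(20)) | {"g90", "g91", "g92", "g93", "g94"}
        rows = enrich_query(query, coll.universe, coll)
        by_term = {r.term_id: r for r in rows}
        assert min(rows, key=lambda r: r.p).term_id == "T:A"
        expected = float(exact_upper_tail(20, 20, 25, 100))
        assert by_term["T:A"].p == pytest.approx(expected, rel=1e-9)
        assert by_term["T:A"].drivers == frozenset(f"g{i}" for i in range(20))

    def test_disjoint_query_all_p_one(self):
        coll = toy_collection()
        rows = enrich_query({"g95", "g96"}, coll.universe, coll)
        assert all(r.p == 1.0 for r in rows if r.term_id != "T:A" or True)

    def test_fdr_threshold_is_strict(self):
        """A term whose FDR equals the threshold exactly is not significant."""
        coll = toy_collection()
        rows = enrich_query({"g95", "g96"}, coll.universe, coll, fdr_threshold=1.0)
        assert rows and all(r.fdr == 1.0 for r in rows)
        assert all(r.status == "not_significant" for r in rows)

    def test_empty_query_gives_empty_result(self, small_catalog):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "gene": ["g0"], "screen_id": ["s"], "fd": [0.0], "raw_lfc": [0.0],
                "se": [0.1], "p": [1.0], "fdr": [1.0], "call": ["neutral"],
            }
        )
        table = cf.FitnessTable(frame=frame)
        assert cf.enrich_screen(table, "s", toy_collection()) == []


def make_rows(spec):
    """spec: list of (term_id, p, drivers, K)."""
    rows = []
    for term_id, p, drivers, K in spec:
        row = EnrichmentRow(term_id, term_id, len(drivers), K, 10, 100, p=p)
        row.drivers = frozenset(drivers)
        row.fdr = p  # convenience
        row.status = "retained"
        rows.append(row)
    return rows


class TestPruneLineage:
    def _dag(self):
        dag = nx.DiGraph()
        dag.add_edge("T:child", "T:parent")
        dag.add_edge("T:parent", "T:root")
        dag.add_node("T:other")
        return dag

    def test_most_significant_in_lineage_survives(self):
        rows = make_rows(
            [("T:parent", 1e-5, {"a"}, 10), ("T:child", 1e-3, {"a"}, 5)]
        )
        out = {r.term_id: r for r in cf.prune_lineage(rows, self._dag())}
        assert out["T:parent"].status == "retained"
        assert out["T:child"].status == "pruned_lineage"

    def test_unrelated_terms_both_retained(self):
        rows = make_rows([("T:parent", 1e-5, {"a"}, 10), ("T:other", 1e-3, {"b"}, 5)])
        out = {r.term_id: r for r in cf.prune_lineage(rows, self._dag())}
        assert out["T:parent"].status == out["T:other"].status == "retained"

    def test_tie_breaks_smaller_term_then_id(self):
        rows = make_rows([("T:parent", 1e-4, {"a"}, 10), ("T:child", 1e-4, {"a"}, 5)])
        out = {r.term_id: r for r in cf.prune_lineage(rows, self._dag())}
        assert out["T:child"].status == "retained"  # smaller K wins the tie
        assert out["T:parent"].status == "pruned_lineage"

    def test_survivors_form_antichain(self):
        dag = nx.DiGraph()
        terms = [f"T:{i}" for i in range(6)]
        for a, b in zip(terms, terms[1:]):
            dag.add_edge(a, b)  # one long chain
        rows = make_rows([(t, 10 ** -(i + 2), {"a"}, 5 + i) for i, t in enumerate(terms)])
        out = cf.prune_lineage(rows, dag)
        retained = [r for r in out if r.status == "retained"]
        assert len(retained) == 1
        # every pruned row can name a retained row with p <= its own
        for r in out:
            if r.status == "pruned_lineage":
                assert any(k.p <= r.p for k in retained)


class TestPruneClusters:
    def test_identical_drivers_merge(self):
        rows = make_rows([("T:a", 1e-5, {"x", "y"}, 5), ("T:b", 1e-3, {"x", "y"}, 5)])
        out = {r.term_id: r for r in cf.prune_clusters(rows)}
        assert out["T:a"].status == "retained"
        assert out["T:b"].status == "pruned_cluster"
        assert out["T:a"].cluster_id == out["T:b"].cluster_id

    def test_disjoint_drivers_stay_separate(self):
        rows = make_rows([("T:a", 1e-5, {"x"}, 5), ("T:b", 1e-3, {"y"}, 5)])
        out = {r.term_id: r for r in cf.prune_clusters(rows)}
        assert out["T:a"].status == out["T:b"].status == "retained"
        assert out["T:a"].cluster_id != out["T:b"].cluster_id

    def test_jaccard_below_threshold_not_merged(self):
        # {a,b} vs {b,c}: J = 1/3 < 0.5
        rows = make_rows([("T:a", 1e-5, {"a", "b"}, 5), ("T:b", 1e-3, {"b", "c"}, 5)])
        out = {r.term_id: r for r in cf.prune_clusters(rows, jaccard_merge=0.5)}
        assert out["T:b"].status == "retained"


class TestEnrichmentMap:
    def test_overlap_coefficient_boundary_inclusive(self):
        coll = GeneSetCollection(
            sets={"T:a": frozenset("ab"), "T:b": frozenset("bc")},
            names={}, universe=frozenset("abc"),
        )
        rows = make_rows([("T:a", 1e-3, {"a"}, 2), ("T:b", 1e-3, {"b"}, 2)])
        emap = cf.build_enrichment_map(rows, coll, overlap_min=0.5)
        assert len(emap.edges) == 1  # coefficient exactly 0.5 kept
        assert emap.edges[0]["overlap_count"] == 1

    def test_low_overlap_dropped(self):
        coll = GeneSetCollection(
            sets={"T:a": frozenset("abcde"), "T:b": frozenset("efghi")},
            names={}, universe=frozenset("abcdefghi"),
        )
        rows = make_rows([("T:a", 1e-3, {"a"}, 5), ("T:b", 1e-3, {"e"}, 5)])
        emap = cf.build_enrichment_map(rows, coll)  # coefficient 1/5
        assert emap.edges == []

    def test_node_size_is_neglog10_fdr(self):
        coll = toy_collection()
        rows = make_rows([("T:A", 0.01, {"g0"}, 20)])
        rows[0].fdr = 0.01
        emap = cf.build_enrichment_map(rows, coll)
        assert emap.nodes[0]["size_value"] == pytest.approx(2.0)
        assert emap.nodes[0]["n_genes"] == 20


def test_results_independent_of_term_order(rng):
    coll = toy_collection()
    query = set(f"g{i}" for i in range(15))
    rows_a = enrich_query(query, coll.universe, coll)
    shuffled = GeneSetCollection(
        sets=dict(reversed(list(coll.sets.items()))), names=coll.names,
        universe=coll.universe,
    )
    rows_b = enrich_query(query, shuffled.universe, shuffled)
    fa = rows_to_frame(prune(rows_a, nx.DiGraph()))
    fb = rows_to_frame(prune(rows_b, nx.DiGraph()))
    assert fa.equals(fb)
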