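"""Feature construction: interaction filtering, GO blocks, dataset variants."""

import numpy as np
import pandas as pd
import pytest

from agerepair.data import (
    CLASS_NEGATIVE,
    CLASS_POSITIVE,
    GeneRecord,
    InteractionRecord,
    PATHWAY_CATEGORIES,
)
from agerepair.features import (
    PARTNERS_ATTR,
    build_dataset,
    build_expression_dataset,
    build_go_block,
    count_partners,
    deduplicate,
    filter_interactions,
    select_top_bpi,
)
from conftest import toy_dataset


def edge(a, b, *tags):
    return InteractionRecord(a, b, frozenset(tags))


class TestFilterInteractions:
    def test_high_throughput_only_removed(self):
        assert filter_interactions([edge("X", "Y", "high_throughput")], {"X"}) == []

    def test_in_vitro_cohort_edge_kept(self):
        edges = filter_interactions([edge("X", "Y", "in_vitro")], {"X"})
        assert len(edges) == 1

    def test_non_cohort_edge_removed(self):
        assert filter_interactions([edge("P", "Q", "in_vivo")], {"X"}) == []

    def test_duplicate_pairs_merged_with_evidence_union(self):
        edges = [
            edge("A", "B", "in_vivo"),
            edge("A", "C", "in_vitro"),
            edge("B", "A", "yeast_2-hybrid"),  # duplicate of A-B, reversed
            edge("A", "D", "in_vivo"),
            edge("A", "E", "in_vitro"),
        ]
        kept = filter_interactions(edges, {"A"})
        assert len(kept) == 4
        ab = next(e for e in kept if e.pair == ("A", "B"))
        assert ab.evidence == {"in_vivo", "yeast_2-hybrid"}

    def test_weak_evidence_rescued_by_merge(self):
        # the pair has strong evidence once listings are merged
        edges = [edge("A", "B", "high_throughput"), edge("B", "A", "in_vivo")]
        assert len(filter_interactions(edges, {"A"})) == 1


class TestCountPartners:
    def test_isolated_symbol(self):
        assert count_partners("P", []) == 0

    def test_distinct_partner_count(self):
        edges = [edge("P", "A", "in_vivo"), edge("P", "B", "in_vivo"),
                 edge("P", "B", "in_vitro")]
        assert count_partners("P", edges) == 2

    def test_self_interaction_counts_once(self):
        edges = [edge("P", "P", "in_vivo"), edge("P", "A", "in_vivo")]
        assert count_partners("P", edges) == 2

    def test_star_hub_exceeds_fifteen_partner_cut(self):
        edges = [edge("H", f"P{i:02d}", "in_vivo") for i in range(16)]
        assert count_partners("H", edges) == 16


class TestSelectTopBpi:
    def test_empty_edges(self):
        assert select_top_bpi([], 5) == []

    def test_lexicographic_tie_break(self):
        edges = []
        for i in range(5):
            edges.append(edge("A", f"x{i}", "in_vivo"))
        for i in range(3):
            edges.append(edge("B", f"y{i}", "in_vivo"))
            edges.append(edge("C", f"y{i}", "in_vivo"))
        top = select_top_bpi(edges, 2)
        assert top == ["A", "B"]

    def test_returns_fewer_when_fewer_exist(self):
        assert len(select_top_bpi([edge("A", "B", "in_vivo")], 30)) == 2


def _records(n_pos=3, n_neg=5, go=None):
    go = go or {}
    recs = []
    for i in range(n_pos + n_neg):
        sym = f"G{i}"
        recs.append(
            GeneRecord(
                symbol=sym,
                class_label=CLASS_POSITIVE if i < n_pos else CLASS_NEGATIVE,
                pathway=PATHWAY_CATEGORIES[i % len(PATHWAY_CATEGORIES)],
                ka_ki=0.1 * i,
                specific_go=frozenset(go.get(sym, set())),
            )
        )
    return recs


class TestGoBlock:
    def test_threshold_boundary_inclusive(self, diamond_graph):
        # leaf term annotated to exactly 2 genes; its 3 ancestors to all
        go = {"G0": {"GO:0000004"}, "G1": {"GO:0000004"}}
        records = _records(go=go)
        attrs, frame = build_go_block(records, diamond_graph, t=2)
        assert "GO:0000004" in [a.name for a in attrs]
        attrs3, _ = build_go_block(records, diamond_graph, t=3)
        assert "GO:0000004" not in [a.name for a in attrs3]

    def test_yes_set_equals_closure_intersect_columns(self, cohort, d5_dataset):
        from agerepair.ontology import close_annotation

        go_cols = {a.name for a in d5_dataset.attributes if a.name.startswith("GO:")}
        by_symbol = {r.symbol: r for r in cohort.records}
        for i in [0, 7, 42]:
            sym = d5_dataset.instance_ids[i]
            closed = close_annotation(cohort.ontology, by_symbol[sym].specific_go)
            yes = {
                c for c in go_cols if d5_dataset.values[c].iloc[i] == "yes"
            }
            assert yes == closed & go_cols

    def test_column_count_monotone_in_threshold(self, cohort):
        counts = []
        for t in (3, 7, 11):
            attrs, _ = build_go_block(cohort.records, cohort.ontology, t)
            counts.append(len(attrs))
        assert counts[0] >= counts[1] >= counts[2]


class TestBuildDataset:
    def test_d1_has_no_ppi_columns(self, d1_dataset):
        names = d1_dataset.attribute_names
        assert PARTNERS_ATTR not in names
        assert not any(n.endswith("_interaction") for n in names)

    def test_d4_has_twenty_interaction_columns(self, cohort):
        d4 = build_dataset(
            cohort.records, cohort.interactions, cohort.ontology, t=3, variant="D4"
        )
        n_bpi = sum(1 for n in d4.attribute_names if n.endswith("_interaction"))
        assert n_bpi == 20
        assert PARTNERS_ATTR in d4.attribute_names

    def test_variant_columns_nested(self, cohort):
        cols = {}
        for v in ("D1", "D2", "D3", "D4", "D5"):
            d = build_dataset(
                cohort.records, cohort.interactions, cohort.ontology, t=3, variant=v
            )
            cols[v] = set(d.attribute_names)
        assert cols["D1"] < cols["D2"] < cols["D3"] < cols["D4"] < cols["D5"]

    def test_single_class_rejected(self, diamond_graph):
        recs = _records(n_pos=0, n_neg=6)
        with pytest.raises(ValueError, match="single-class"):
            build_dataset(recs, [], diamond_graph, t=1, variant="D1")

    def test_duplicate_genes_removed(self, diamond_graph):
        # two attribute-identical genes of the same class collapse to one
        go = {f"G{i}": {"GO:0000004"} for i in range(12)}
        recs = _records(n_pos=4, n_neg=8, go=go)
        twin = recs[5]
        recs[6] = GeneRecord(
            symbol="G6copy",
            class_label=twin.class_label,
            pathway=twin.pathway,
            ka_ki=twin.ka_ki,
            specific_go=twin.specific_go,
        )
        data = build_dataset(recs, [], diamond_graph, t=1, variant="D1")
        assert data.n_instances == 11


class TestDeduplicate:
    def test_no_duplicates_unchanged(self):
        data = toy_dataset(
            [{"a": "yes"}, {"a": "no"}],
            {"a": "binary"},
            [CLASS_POSITIVE, CLASS_NEGATIVE],
        )
        assert deduplicate(data) is data

    def test_three_identical_leave_one(self):
        data = toy_dataset(
            [{"a": "yes"}] * 3 + [{"a": "no"}],
            {"a": "binary"},
            [CLASS_POSITIVE] * 3 + [CLASS_NEGATIVE],
        )
        out = deduplicate(data)
        assert out.n_instances == 2
        assert out.instance_ids[0] == "g0"  # first occurrence survives

    def test_class_conflict_retained_with_warning(self, caplog):
        data = toy_dataset(
            [{"a": "yes"}, {"a": "yes"}],
            {"a": "binary"},
            [CLASS_POSITIVE, CLASS_NEGATIVE],
        )
        with caplog.at_level("WARNING"):
            out = deduplicate(data)
        assert out.n_instances == 2
        assert "conflicting" in caplog.text

    def test_idempotent(self, d5_dataset):
        once = deduplicate(d5_dataset)
        assert deduplicate(once).n_instances == once.n_instances


class TestExpressionDataset:
    def probe_frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "probe", "anatomy", "value"])

    def test_single_probe_passthrough(self):
        table = self.probe_frame([("G1", "p1", "liver", 42.0), ("G2", "p1", "liver", 7.0)])
        data = build_expression_dataset(
            table, {"G1": CLASS_POSITIVE, "G2": CLASS_NEGATIVE}
        )
        assert data.values["liver"].iloc[0] == 42.0

    def test_two_probe_mean(self):
        table = self.probe_frame(
            [("G1", "p1", "liver", 100.0), ("G1", "p2", "liver", 200.0),
             ("G2", "p1", "liver", 7.0)]
        )
        data = build_expression_dataset(
            table, {"G1": CLASS_POSITIVE, "G2": CLASS_NEGATIVE}
        )
        assert data.values["liver"].iloc[0] == 150.0

    def test_unmeasured_category_missing(self):
        table = self.probe_frame(
            [("G1", "p1", "liver", 5.0), ("G2", "p1", "brain", 2.0)]
        )
        data = build_expression_dataset(
            table, {"G1": CLASS_POSITIVE, "G2": CLASS_NEGATIVE}
        )
        assert np.isnan(data.values["brain"].iloc[0])

    def test_cohort_has_108_tissue_columns(self, cohort):
        labels = {r.symbol: r.class_label for r in cohort.records}
        data = build_expression_dataset(cohort.probe_table, labels)
        assert len(data.attributes) == 108
        assert data.n_instances == len(cohort.records)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_expression_dataset(self.probe_frame([]), {})
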