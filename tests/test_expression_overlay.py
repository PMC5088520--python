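"""Barcode-style scoring, ON/OFF/NA state calls and network filtering."""

import numpy as np
import pandas as pd
import pytest

from pathexnet.errors import OverlayError
from pathexnet.expression_overlay import (
    ExpressionResource,
    StateAssignment,
    assign_states,
    barcode_resource_from_samples,
    barcode_scores,
    compare_contexts,
    filter_network,
)
from pathexnet.id_mapping import MappingTable
from pathexnet.network_builder import build_local
from pathexnet.pathway_store import Store

from conftest import random_protein_network, random_scores


def star_network(n_leaves: int = 4):
    store = Store()
    pid = "hsa90001"
    centre = "P10000"
    store.add_protein(centre, pathway_id=pid)
    for i in range(1, n_leaves + 1):
        leaf = f"P1000{i}"
        store.add_protein(leaf, pathway_id=pid)
        store.add_relation(centre, leaf, "other", (), pid)
    return build_local(store, pid)


def resource_for(scores: dict[str, float], context="ctx") -> ExpressionResource:
    return ExpressionResource(
        "barcode_fraction", pd.DataFrame({context: pd.Series(scores, dtype=float)})
    )


class TestBarcodeScores:
    def reference(self, genes):
        return pd.DataFrame(
            {"mu": [100.0] * len(genes), "sigma": [10.0] * len(genes)}, index=genes
        )

    def test_all_samples_at_mu_score_zero(self):
        m = pd.DataFrame(np.full((1, 8), 100.0), index=["g1"])
        scores, missing = barcode_scores(m, self.reference(["g1"]))
        assert scores["g1"] == 0.0 and missing == []

    def test_planted_fraction_recovered(self):
        # expressed at z=8 in 13 of 32 samples, unexpressed at mu elsewhere
        row = np.full(32, 100.0)
        row[:13] = 100.0 + 8 * 10.0
        m = pd.DataFrame([row], index=["g1"])
        scores, _ = barcode_scores(m, self.reference(["g1"]), z_cutoff=5.0)
        assert scores["g1"] == pytest.approx(13 / 32)

    def test_all_samples_expressed_score_one(self):
        m = pd.DataFrame(np.full((1, 8), 500.0), index=["g1"])
        scores, _ = barcode_scores(m, self.reference(["g1"]))
        assert scores["g1"] == 1.0

    def test_gene_missing_from_reference_is_reported(self):
        m = pd.DataFrame(np.full((2, 4), 100.0), index=["g1", "g404"])
        scores, missing = barcode_scores(m, self.reference(["g1"]))
        assert missing == ["g404"]
        assert "g404" not in scores.index

    def test_non_positive_sigma_rejected(self):
        ref = pd.DataFrame({"mu": [100.0], "sigma": [0.0]}, index=["g1"])
        m = pd.DataFrame(np.full((1, 4), 100.0), index=["g1"])
        with pytest.raises(OverlayError, match="sigma"):
            barcode_scores(m, ref)

    def test_scores_bounded_and_monotone_under_unexpressed_samples(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(100, 10, size=(5, 16)),
                         index=[f"g{i}" for i in range(5)])
        ref = self.reference(list(m.index))
        scores, _ = barcode_scores(m, ref)
        assert ((scores >= 0) & (scores <= 1)).all()
        # appending samples exactly at mu can only shrink the fraction
        extra = pd.DataFrame(np.full((5, 8), 100.0), index=m.index,
                             columns=[f"x{i}" for i in range(8)])
        scores2, _ = barcode_scores(pd.concat([m, extra], axis=1), ref)
        assert (scores2 <= scores + 1e-12).all()

    def test_per_context_resource_from_sample_manifest(self):
        genes = ["g1", "g2"]
        ref = self.reference(genes)
        data = pd.DataFrame(
            [[200.0, 200.0, 100.0, 100.0], [200.0, 100.0, 100.0, 100.0]],
            index=genes,
            columns=["s1", "s2", "s3", "s4"],
        )
        manifest = pd.Series(
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        )
        resource = barcode_resource_from_samples(data, manifest, ref)
        assert resource.values.loc["g1", "A"] == 1.0
        assert resource.values.loc["g1", "B"] == 0.0
        assert resource.values.loc["g2", "A"] == 0.5


class TestAssignStates:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.17, "OFF"), (0.40, "OFF"), (0.41, "ON"), (1.00, "ON")],
    )
    def test_strict_threshold_semantics(self, score, expected):
        net = star_network(1)
        res = resource_for({"P10000": score, "P10001": score})
        assignment = assign_states(net, res, "ctx", threshold=0.4)
        assert assignment.states["P10000"] == expected

    def test_absent_accession_is_na(self):
        net = star_network(1)
        res = resource_for({"P10000": 0.9})
        assignment = assign_states(net, res, "ctx")
        assert assignment.states["P10001"] == "NA"
        assert assignment.scores["P10001"] is None

    def test_unknown_context_error_lists_available(self):
        net = star_network(1)
        res = resource_for({"P10000": 0.9}, context="Bcell")
        with pytest.raises(OverlayError, match="Bcell"):
            assign_states(net, res, "Tcell")

    def test_gene_keyed_resource_via_mapping_takes_max(self):
        net = star_network(1)
        mapping = MappingTable("kegg_gene", {
            "hsa:1": {"P10000"}, "hsa:2": {"P10000"}, "hsa:3": {"P10001"},
        })
        res = resource_for({"hsa:1": 0.2, "hsa:2": 0.8, "hsa:3": 0.1})
        assignment = assign_states(net, res, "ctx", mapping=mapping)
        assert assignment.scores["P10000"] == 0.8
        assert assignment.states["P10000"] == "ON"
        assert assignment.states["P10001"] == "OFF"

    def test_mean_aggregation_option(self):
        net = star_network(1)
        mapping = MappingTable("kegg_gene", {
            "hsa:1": {"P10000"}, "hsa:2": {"P10000"}, "hsa:3": {"P10001"},
        })
        res = resource_for({"hsa:1": 0.2, "hsa:2": 0.8, "hsa:3": 0.1})
        assignment = assign_states(net, res, "ctx", mapping=mapping, aggregate="mean")
        assert assignment.scores["P10000"] == pytest.approx(0.5)

    def test_fpkm_resource_needs_absolute_threshold(self):
        net = star_network(1)
        res = ExpressionResource(
            "fpkm", pd.DataFrame({"ctx": pd.Series({"P10000": 5.0, "P10001": 0.5})})
        )
        with pytest.raises(OverlayError, match="absolute"):
            assign_states(net, res, "ctx")
        res.threshold = 1.0
        assignment = assign_states(net, res, "ctx")
        assert assignment.states == {"P10000": "ON", "P10001": "OFF"}

    def test_barcode_values_outside_unit_interval_rejected(self):
        with pytest.raises(OverlayError, match=r"\[0, 1\]"):
            resource_for({"P10000": 1.5})


class TestFilterNetwork:
    def test_all_on_is_identity(self):
        net = star_network(3)
        res = resource_for({a: 0.9 for a in net.nodes()})
        filtered, report = filter_network(net, assign_states(net, res, "ctx"))
        assert filtered.nodes() == net.nodes()
        assert filtered.edges() == net.edges()
        assert report.n_OFF_removed == 0 and report.edges_removed == 0

    def test_star_centre_off_leaves_no_edges(self):
        net = star_network(4)
        scores = {a: 0.9 for a in net.nodes()}
        scores["P10000"] = 0.1
        filtered, report = filter_network(
            net, assign_states(net, resource_for(scores), "ctx")
        )
        assert filtered.n_nodes == 4 and filtered.n_edges == 0
        assert report.edges_removed == 4

    def test_mixed_state_enumeration(self):
        """10 nodes (6 ON, 2 NA, 2 OFF); edges touching OFF nodes go."""
        store = Store()
        pid = "hsa90001"
        accs = [f"P100{i:02d}" for i in range(10)]
        for a in accs:
            store.add_protein(a, pathway_id=pid)
        edges = [
            (0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7),
            (7, 8), (8, 9), (9, 0), (0, 8), (2, 9),
        ]
        for i, j in edges:
            store.add_relation(accs[i], accs[j], "other", (), pid)
        net = build_local(store, pid)
        assert net.n_edges == 12
        # ON: 0..5, NA: 6..7 (absent), OFF: 8..9
        scores = {accs[i]: 0.9 for i in range(6)}
        scores.update({accs[8]: 0.1, accs[9]: 0.1})
        assignment = assign_states(net, resource_for(scores), "ctx")
        filtered, report = filter_network(net, assignment)
        off_touching = {e for e in edges if 8 in e or 9 in e}
        assert len(off_touching) == 5
        assert (report.n_ON, report.n_NA, report.n_OFF_removed) == (6, 2, 2)
        assert filtered.n_nodes == 8 and filtered.n_edges == 7

    def test_node_without_state_raises(self):
        net = star_network(2)
        assignment = StateAssignment("ctx", {"P10000": "ON"}, {"P10000": 0.9})
        with pytest.raises(OverlayError, match="P1000"):
            filter_network(net, assignment)

    def test_conservation_and_monotonicity_on_random_networks(self):
        rng = np.random.default_rng(23)
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 2)
        for _ in range(20):
            net = random_protein_network(rng)
            table = random_scores(rng, net)
            res = ExpressionResource("barcode_fraction", table)
            prev_on = None
            for t in thresholds:
                assignment = assign_states(net, res, "ctx", threshold=float(t))
                filtered, report = filter_network(net, assignment)
                assert (
                    report.n_ON + report.n_OFF_removed + report.n_NA
                    == net.n_nodes
                )
                assert assignment.na_set() <= filtered.nodes()
                on = assignment.on_set()
                if prev_on is not None:
                    assert on <= prev_on
                prev_on = on


class TestCompareContexts:
    def test_self_comparison_has_no_discordance(self):
        net = star_network(2)
        res = resource_for({a: 0.9 for a in net.nodes()})
        a = assign_states(net, res, "ctx")
        b = StateAssignment("ctx2", dict(a.states), dict(a.scores))
        _, discordant = compare_contexts(net, [a, b])
        assert discordant == []

    def test_on_off_split_is_discordant(self):
        net = star_network(1)
        res = pd.DataFrame(
            {"A": {"P10000": 0.9, "P10001": 0.9}, "B": {"P10000": 0.1, "P10001": 0.9}}
        )
        resource = ExpressionResource("barcode_fraction", res)
        a = assign_states(net, resource, "A")
        b = assign_states(net, resource, "B")
        table, discordant = compare_contexts(net, [a, b])
        assert discordant == ["P10000"]
        assert table.loc["P10000", "A"] == "ON" and table.loc["P10000", "B"] == "OFF"

    def test_all_na_gene_never_discordant(self):
        net = star_network(1)
        res = pd.DataFrame({"A": {"P10000": 0.9}, "B": {"P10000": 0.1}})
        resource = ExpressionResource("barcode_fraction", res)
        a = assign_states(net, resource, "A")
        b = assign_states(net, resource, "B")
        _, discordant = compare_contexts(net, [a, b])
        assert "P10001" not in discordant  # NA in both contexts

    def test_mismatched_node_sets_raise(self):
        net = star_network(1)
        res = resource_for({"P10000": 0.9, "P10001": 0.9})
        a = assign_states(net, res, "ctx")
        b = StateAssignment("other", {"P10000": "ON"}, {"P10000": 0.9})
        with pytest.raises(OverlayError, match="cover"):
            compare_contexts(net, [a, b])
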