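"""Expression calls, communication networks, totals and differential attribution."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cardiocomm.catalog import LRCatalog, LRPair
from cardiocomm.network import (
    ExpressionCallTable,
    build_network,
    compute_expression_calls,
    diff_networks,
    network_totals,
)

from conftest import make_matrix


def calls_from_dict(expressed: dict, threshold=0.2) -> ExpressionCallTable:
    """Build a call table from {(condition, group): set of expressed genes}."""
    all_genes = sorted({g for genes in expressed.values() for g in genes}) or ["NOGENE"]
    rows = []
    for (cond, grp), genes in expressed.items():
        for g in all_genes:
            on = g in genes
            rows.append((cond, grp, g, 100, 0.5 if on else 0.0, on))
    return ExpressionCallTable(
        pd.DataFrame(rows, columns=["condition", "group", "gene", "n_cells",
                                    "fraction", "expressed"]),
        threshold,
    )


class TestExpressionCalls:
    def test_twenty_percent_threshold_inclusive(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[:20, 0] = 1   # exactly 20% -> expressed
        counts[:19, 1] = 1   # 19% -> not expressed
        m = make_matrix(counts)
        calls = compute_expression_calls(m)
        assert calls.is_expressed("Normal", "typeA", m.gene_ids[0])
        assert not calls.is_expressed("Normal", "typeA", m.gene_ids[1])

    def test_199_of_1000_is_below_threshold(self):
        counts = np.zeros((1000, 1), dtype=int)
        counts[:199, 0] = 5
        calls = compute_expression_calls(make_matrix(counts))
        assert not calls.is_expressed("Normal", "typeA", "g000")
        assert calls.fraction("Normal", "typeA", "g000") == pytest.approx(0.199)

    def test_zero_detection_never_expressed(self):
        calls = compute_expression_calls(make_matrix(np.zeros((50, 3), dtype=int)))
        assert calls.expressed_genes("Normal", "typeA") == frozenset()

    def test_invalid_threshold_rejected(self):
        m = make_matrix(np.ones((10, 1), dtype=int))
        with pytest.raises(ValueError):
            compute_expression_calls(m, threshold=1.5)

    def test_threshold_monotonicity(self, rng):
        counts = rng.integers(0, 2, size=(60, 10))
        m = make_matrix(counts, cell_types=["A"] * 30 + ["B"] * 30)
        low = compute_expression_calls(m, threshold=0.2)
        high = compute_expression_calls(m, threshold=0.4)
        for grp in ("A", "B"):
            assert high.expressed_genes("Normal", grp) <= low.expressed_genes("Normal", grp)


def brute_force_network(expressed: dict, catalog, condition):
    """Independent enumeration over groups x catalog pairs."""
    groups = sorted({g for (c, g) in expressed if c == condition})
    edges = {}
    for s, t in itertools.product(groups, groups):
        pairs = {
            p for p in catalog.pairs
            if p.ligand in expressed[(condition, s)]
            and p.receptor in expressed[(condition, t)]
        }
        if pairs:
            edges[(s, t)] = frozenset(pairs)
    return edges


class TestBuildNetwork:
    CATALOG = LRCatalog.from_pairs([("L1", "R1"), ("L2", "R2")])

    def test_two_group_toy(self):
        expressed = {
            ("Normal", "A"): {"L1", "R2"},
            ("Normal", "B"): {"R1", "L2"},
        }
        net = build_network(calls_from_dict(expressed), self.CATALOG, "Normal")
        assert net.pairs("A", "B") == frozenset({LRPair("L1", "R1")})
        assert net.pairs("B", "A") == frozenset({LRPair("L2", "R2")})
        assert net.total() == 2
        assert net.edges == brute_force_network(expressed, self.CATALOG, "Normal")

    def test_no_expression_no_edges(self):
        expressed = {("Normal", "A"): set(), ("Normal", "B"): set()}
        net = build_network(calls_from_dict(expressed), self.CATALOG, "Normal")
        assert net.total() == 0

    def test_self_loop_autocrine(self):
        expressed = {("Normal", "A"): {"L1", "R1"}}
        net = build_network(calls_from_dict(expressed), self.CATALOG, "Normal")
        assert net.pairs("A", "A") == frozenset({LRPair("L1", "R1")})

    def test_random_calls_match_brute_force(self, rng):
        catalog = LRCatalog.from_pairs(
            [(f"L{i}", f"R{i}") for i in range(8)] + [("L0", "R3"), ("L5", "R0")]
        )
        genes = sorted(catalog.genes)
        expressed = {
            ("Normal", grp): {g for g in genes if rng.random() < 0.4}
            for grp in ("A", "B", "C")
        }
        net = build_network(calls_from_dict(expressed), catalog, "Normal")
        assert net.edges == brute_force_network(expressed, catalog, "Normal")

    def test_missing_condition_rejected(self):
        calls = calls_from_dict({("Normal", "A"): {"L1"}})
        with pytest.raises(ValueError, match="HCM"):
            build_network(calls, self.CATALOG, "HCM")


class TestNetworkTotals:
    def test_toy_totals(self):
        expressed = {("Normal", "A"): {"L1", "R2"}, ("Normal", "B"): {"R1", "L2"}}
        net = build_network(
            calls_from_dict(expressed), TestBuildNetwork.CATALOG, "Normal"
        )
        totals = network_totals(net)
        assert totals["total"] == 2
        assert totals["broadcast"]["A"] == 1
        assert totals["receive"]["A"] == 1

    def test_self_loop_counts_both_directions(self):
        catalog = LRCatalog.from_pairs([("L1", "R1"), ("L2", "R2"), ("L3", "R3")])
        expressed = {("Normal", "A"): {"L1", "R1", "L2", "R2", "L3", "R3"}}
        totals = network_totals(
            build_network(calls_from_dict(expressed), catalog, "Normal")
        )
        assert totals["broadcast"]["A"] == 3
        assert totals["receive"]["A"] == 3

    def test_conservation(self, rng):
        catalog = LRCatalog.from_pairs([(f"L{i}", f"R{i}") for i in range(6)])
        genes = sorted(catalog.genes)
        expressed = {
            ("Normal", grp): {g for g in genes if rng.random() < 0.5}
            for grp in ("A", "B", "C", "D")
        }
        totals = network_totals(
            build_network(calls_from_dict(expressed), catalog, "Normal")
        )
        assert sum(totals["broadcast"].values()) == totals["total"]
        assert sum(totals["receive"].values()) == totals["total"]


class TestDiffNetworks:
    CATALOG = LRCatalog.from_pairs(
        [("COL1A2", "ITGB1"), ("FN1", "ITGB1"), ("L2", "R2")]
    )

    def _nets(self, expr_a, expr_b):
        calls_a = calls_from_dict(expr_a)
        calls_b = calls_from_dict(expr_b)
        net_a = build_network(calls_a, self.CATALOG, "Normal")
        net_b = build_network(calls_b, self.CATALOG, "HCM")
        return net_a, net_b, calls_a, calls_b

    def test_identical_networks_no_changes(self):
        expr = {("Normal", "A"): {"COL1A2"}, ("Normal", "B"): {"ITGB1"}}
        expr_b = {("HCM", k[1]): v for k, v in expr.items()}
        net_a, net_b, ca, cb = self._nets(expr, expr_b)
        diff = diff_networks(net_a, net_b, ca, cb)
        assert len(diff.table) == 0

    def test_receptor_gain_attributed_to_receptor(self):
        # target gains ITGB1 while the source keeps broadcasting both ligands
        expr_a = {("Normal", "fib"): {"COL1A2", "FN1"}, ("Normal", "dc"): set()}
        expr_b = {("HCM", "fib"): {"COL1A2", "FN1"}, ("HCM", "dc"): {"ITGB1"}}
        net_a, net_b, ca, cb = self._nets(expr_a, expr_b)
        diff = diff_networks(net_a, net_b, ca, cb)
        gained = diff.table[diff.table["change"] == "gained"]
        assert set(gained["attribution"]) == {"receptor-gained"}
        assert len(gained) == 2
        assert diff.gained("fib", "dc") == frozenset(
            {LRPair("COL1A2", "ITGB1"), LRPair("FN1", "ITGB1")}
        )

    def test_ligand_loss_attributed_to_ligand(self):
        expr_a = {("Normal", "A"): {"L2"}, ("Normal", "B"): {"R2"}}
        expr_b = {("HCM", "A"): set(), ("HCM", "B"): {"R2"}}
        net_a, net_b, ca, cb = self._nets(expr_a, expr_b)
        diff = diff_networks(net_a, net_b, ca, cb)
        assert list(diff.table["attribution"]) == ["ligand-lost"]

    def test_both_sides_flipping_tagged_both(self):
        expr_a = {("Normal", "A"): set(), ("Normal", "B"): set()}
        expr_b = {("HCM", "A"): {"L2"}, ("HCM", "B"): {"R2"}}
        net_a, net_b, ca, cb = self._nets(expr_a, expr_b)
        diff = diff_networks(net_a, net_b, ca, cb)
        assert list(diff.table["attribution"]) == ["both-gained"]

    def test_node_mismatch_lists_difference(self):
        expr_a = {("Normal", "A"): {"L2"}, ("Normal", "B"): {"R2"}}
        expr_b = {("HCM", "A"): {"L2"}, ("HCM", "C"): {"R2"}}
        net_a, net_b, ca, cb = self._nets(expr_a, expr_b)
        with pytest.raises(ValueError, match="B"):
            diff_networks(net_a, net_b, ca, cb)
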