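"""Term counting over networks and hypergeometric over-representation."""

import itertools
from math import comb

import numpy as np
import pytest

from cardiocomm.catalog import LRCatalog
from cardiocomm.enrich import (
    AnnotationMap,
    count_term_occurrences,
    hypergeometric_enrich,
    load_gmt,
    term_count_difference,
)
from cardiocomm.network import build_network

from test_network import calls_from_dict


def exhaustive_hypergeom_upper_tail(n_universe, term_size, n_query, k_obs):
    """P(X >= k) by enumerating all C(N, n) draws."""
    hits = 0
    total = 0
    universe = range(n_universe)
    term = set(range(term_size))
    for draw in itertools.combinations(universe, n_query):
        total += 1
        if len(term & set(draw)) >= k_obs:
            hits += 1
    return hits / total


class TestLoadGMT:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "ann.gmt"
        path.write_text("T1\tdesc one\tA\tB\tC\nT2\tdesc two\td\te\n")
        ann = load_gmt(str(path))
        assert ann.terms["T1"] == frozenset({"A", "B", "C"})
        assert ann.terms["T2"] == frozenset({"D", "E"})  # normalized case
        assert ann.labels["T2"] == "desc two"

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("T1\tonly-two-fields\n")
        with pytest.raises(ValueError):
            load_gmt(str(path))

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            AnnotationMap({"T1": set()})


def toy_network():
    catalog = LRCatalog.from_pairs([("L1", "R1"), ("L2", "R2")])
    expressed = {
        ("Normal", "A"): {"L1", "L2", "R1", "R2"},
        ("Normal", "B"): {"R1", "R2"},
    }
    return build_network(calls_from_dict(expressed), catalog, "Normal")


class TestCountTermOccurrences:
    def test_single_term_single_ligand(self):
        net = toy_network()
        ann = AnnotationMap({"T": {"L1"}})
        tab = count_term_occurrences(net, ann, role="ligand")
        # L1 broadcast on edges A->A and A->B: 2 pair instances
        assert tab["count"].item() == 2

    def test_matches_brute_force_triple_enumeration(self):
        net = toy_network()
        ann = AnnotationMap({"T1": {"L1", "R2"}, "T2": {"L2"}})
        for role in ("ligand", "receptor"):
            tab = count_term_occurrences(net, ann, role=role).set_index("term")
            for term, members in ann.terms.items():
                expected = sum(
                    1
                    for (s, t), pairs in net.edges.items()
                    for p in pairs
                    if getattr(p, role) in members
                )
                got = int(tab.loc[term, "count"]) if term in tab.index else 0
                assert got == expected

    def test_empty_annotation_empty_table(self):
        tab = count_term_occurrences(toy_network(), AnnotationMap({"T": {"ZZZ"}}))
        assert len(tab) == 0

    def test_term_covering_all_ligands_counts_every_instance(self):
        net = toy_network()
        ann = AnnotationMap({"ALL": {"L1", "L2"}})
        tab = count_term_occurrences(net, ann, role="ligand")
        assert tab["count"].item() == net.total()

    def test_by_group_splits_by_broadcaster(self):
        net = toy_network()
        ann = AnnotationMap({"ALL": {"L1", "L2"}})
        tab = count_term_occurrences(net, ann, role="ligand", by_group=True)
        assert set(tab["group"]) == {"A"}  # only A broadcasts

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            count_term_occurrences(toy_network(), AnnotationMap({"T": {"L1"}}), role="x")

    def test_condition_difference_antisymmetric(self):
        net = toy_network()
        ann = AnnotationMap({"T1": {"L1"}, "T2": {"L2"}})
        counts = count_term_occurrences(net, ann)
        d_ab = term_count_difference(counts, counts.assign(count=0))
        d_ba = term_count_difference(counts.assign(count=0), counts)
        assert (d_ab["difference"].to_numpy() == -d_ba["difference"].to_numpy()).all()


class TestHypergeometricEnrich:
    def test_printed_fixture(self):
        # N=10, K=4, n=5, k=4 -> C(4,4)C(6,1)/C(10,5) = 6/252
        universe = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(4)}
        query = {f"g{i}" for i in range(4)} | {"g9"}
        tab = hypergeometric_enrich(query, universe, AnnotationMap({"T": term}))
        assert tab["p"].item() == pytest.approx(6 / 252, abs=1e-12)
        assert tab["k"].item() == 4 and tab["K"].item() == 4

    def test_whole_universe_term_certain(self):
        universe = {f"g{i}" for i in range(8)}
        tab = hypergeometric_enrich(
            {"g0", "g1"}, universe, AnnotationMap({"ALL": universe})
        )
        assert tab["p"].item() == pytest.approx(1.0)

    def test_zero_hits_tail_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        tab = hypergeometric_enrich(
            {"g8", "g9"}, universe, AnnotationMap({"T": {"g0", "g1"}})
        )
        assert tab["p"].item() == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="GX"):
            hypergeometric_enrich({"gX"}, {"g0"}, AnnotationMap({"T": {"g0"}}))

    @pytest.mark.parametrize("n_universe,term_size,n_query", [(6, 3, 3), (8, 4, 3), (10, 5, 4), (12, 4, 6)])
    def test_matches_exhaustive_enumeration(self, n_universe, term_size, n_query):
        universe = {f"g{i}" for i in range(n_universe)}
        term = {f"g{i}" for i in range(term_size)}
        ann = AnnotationMap({"T": term})
        rng = np.random.default_rng(n_universe * 100 + n_query)
        query = set(rng.choice(sorted(universe), size=n_query, replace=False))
        k_obs = len(term & query)
        expected = exhaustive_hypergeom_upper_tail(n_universe, term_size, n_query, k_obs)
        tab = hypergeometric_enrich(query, universe, ann)
        assert tab["p"].item() == pytest.approx(expected, abs=1e-12)
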