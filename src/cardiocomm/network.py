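"""Threshold-based cell-cell communication networks.

A gene is *expressed* in a cell group when it has a nonzero count in at
least a fraction ``threshold`` (default 20%) of the group's cells — the
detection-rate rule used across L-R communication studies.  For each
condition, a directed multigraph over cell groups is built: the pair
(L, R) sits on edge s→t exactly when the catalog contains (L, R), L is
expressed in source group s and R is expressed in target group t.
Self-loops (s = t) encode autocrine signaling.  Edge weight is the
number of *unique* pairs on the edge.

Two conditions are compared edge-by-edge: pairs gained and lost, each
attributed to the side whose expression call flipped (ligand, receptor,
or both).  The attribution is read off the two expression-call tables,
so a statement like "this edge gained pairs because the target gained
receptor X" is a derived, checkable fact rather than a narrative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import LRCatalog, LRPair
from .matrix import CountMatrix

__all__ = [
    "ExpressionCallTable",
    "CommNetwork",
    "DiffNetwork",
    "compute_expression_calls",
    "build_network",
    "network_totals",
    "diff_networks",
]

ATTRIBUTIONS = (
    "ligand-gained", "receptor-gained", "both-gained",
    "ligand-lost", "receptor-lost", "both-lost",
)


@dataclass
class ExpressionCallTable:
    """Per (condition, group, gene): nonzero fraction and expression call."""

    table: pd.DataFrame  # columns: condition, group, gene, n_cells, fraction, expressed
    threshold: float

    def __post_init__(self):
        self._idx = {
            (c, g, gene): (frac, bool(expr))
            for c, g, gene, frac, expr in zip(
                self.table["condition"], self.table["group"], self.table["gene"],
                self.table["fraction"], self.table["expressed"],
            )
        }

    def fraction(self, condition: str, group: str, gene: str) -> float:
        return self._idx[(condition, group, gene)][0]

    def is_expressed(self, condition: str, group: str, gene: str) -> bool:
        entry = self._idx.get((condition, group, gene))
        return entry is not None and entry[1]

    def expressed_genes(self, condition: str, group: str) -> frozenset[str]:
        sub = self.table
        mask = (
            (sub["condition"] == condition) & (sub["group"] == group) & sub["expressed"]
        )
        return frozenset(sub.loc[mask, "gene"])

    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def groups(self, condition: str) -> list[str]:
        return sorted(self.table.loc[self.table["condition"] == condition, "group"].unique())


def compute_expression_calls(
    m: CountMatrix,
    grouping: str = "cell_type",
    threshold: float = 0.20,
    genes: list[str] | None = None,
    condition_key: str = "condition",
) -> ExpressionCallTable:
    """Nonzero-count fractions and ≥ threshold expression calls per (condition, group, gene).

    ``grouping`` may be a single metadata column or ``"a+b"`` to group by
    the combination of two columns.  ``genes`` restricts the call table
    (e.g. to catalog genes); default is every gene in the matrix.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    group_cols = grouping.split("+")
    for col in group_cols + [condition_key]:
        if col not in m.cell_meta.columns:
            raise KeyError(f"metadata column {col!r} not found")
    if genes is None:
        gene_idx = np.arange(m.n_genes)
        gene_names = list(m.gene_ids)
    else:
        gene_idx = m.gene_index(genes)
        gene_names = list(genes)

    nonzero = (m.counts[:, gene_idx] > 0).astype(np.int64)
    if len(group_cols) == 1:
        group_labels = m.cell_meta[group_cols[0]].astype(str)
    else:
        group_labels = m.cell_meta[group_cols].astype(str).agg("+".join, axis=1)
    cond_labels = m.cell_meta[condition_key].astype(str)

    records = []
    for (cond, grp), idx in pd.DataFrame(
        {"c": cond_labels.to_numpy(), "g": group_labels.to_numpy()}
    ).groupby(["c", "g"]).groups.items():
        rows = np.asarray(idx, dtype=int)
        n = rows.size
        frac = np.asarray(nonzero[rows, :].sum(axis=0)).ravel() / n
        for gene, f in zip(gene_names, frac):
            records.append((cond, grp, gene, n, f, f >= threshold))
    table = pd.DataFrame(
        records, columns=["condition", "group", "gene", "n_cells", "fraction", "expressed"]
    ).sort_values(["condition", "group", "gene"], ignore_index=True)
    return ExpressionCallTable(table, threshold)


@dataclass
class CommNetwork:
    """Directed communication network for one condition."""

    condition: str
    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], frozenset[LRPair]] = field(default_factory=dict)

    def pairs(self, source: str, target: str) -> frozenset[LRPair]:
        return self.edges.get((source, target), frozenset())

    def edge_count(self, source: str, target: str) -> int:
        return len(self.pairs(source, target))

    def total(self) -> int:
        return sum(len(p) for p in self.edges.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, t, p.ligand, p.receptor)
            for (s, t) in sorted(self.edges)
            for p in sorted(self.edges[(s, t)])
        ]
        return pd.DataFrame(rows, columns=["source", "target", "ligand", "receptor"])

    def count_matrix(self) -> pd.DataFrame:
        """Square table of per-edge unique-pair counts (rows = source)."""
        mat = pd.DataFrame(0, index=list(self.nodes), columns=list(self.nodes))
        for (s, t), pairs in self.edges.items():
            mat.loc[s, t] = len(pairs)
        return mat

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph(condition=self.condition)
        g.add_nodes_from(self.nodes)
        for (s, t), pairs in self.edges.items():
            for p in sorted(pairs):
                g.add_edge(s, t, ligand=p.ligand, receptor=p.receptor)
        return g


def build_network(
    calls: ExpressionCallTable, catalog: LRCatalog, condition: str
) -> CommNetwork:
    """All (L, R) catalog pairs with L expressed in source and R in target."""
    if condition not in calls.conditions():
        raise ValueError(
            f"condition {condition!r} absent from calls (have {calls.conditions()})"
        )
    if not len(catalog):
        raise ValueError("empty L-R catalog")
    groups = calls.groups(condition)
    expressed = {g: calls.expressed_genes(condition, g) for g in groups}
    edges: dict[tuple[str, str], frozenset[LRPair]] = {}
    for s in groups:
        for t in groups:
            pairs = frozenset(
                p for p in catalog.pairs
                if p.ligand in expressed[s] and p.receptor in expressed[t]
            )
            if pairs:
                edges[(s, t)] = pairs
    return CommNetwork(condition, tuple(groups), edges)


def network_totals(net: CommNetwork) -> dict:
    """Total pair instances plus per-node broadcast (out) and receive (in) totals."""
    broadcast = {n: 0 for n in net.nodes}
    receive = {n: 0 for n in net.nodes}
    for (s, t), pairs in net.edges.items():
        broadcast[s] += len(pairs)
        receive[t] += len(pairs)
    return {"total": net.total(), "broadcast": broadcast, "receive": receive}


@dataclass
class DiffNetwork:
    """Gained/lost pairs per directed edge with per-pair change attribution."""

    condition_a: str
    condition_b: str
    table: pd.DataFrame  # source, target, ligand, receptor, change, attribution

    def gained(self, source: str, target: str) -> frozenset[LRPair]:
        return self._select(source, target, "gained")

    def lost(self, source: str, target: str) -> frozenset[LRPair]:
        return self._select(source, target, "lost")

    def _select(self, source: str, target: str, change: str) -> frozenset[LRPair]:
        sub = self.table
        mask = (
            (sub["source"] == source) & (sub["target"] == target) & (sub["change"] == change)
        )
        return frozenset(
            LRPair(l, r) for l, r in sub.loc[mask, ["ligand", "receptor"]].itertuples(index=False)
        )


def _attribute(
    pair: LRPair,
    source: str,
    target: str,
    change: str,
    calls_before: ExpressionCallTable,
    cond_before: str,
) -> str:
    """Which side's expression flip explains a gained/lost pair.

    For a gain (B vs A), the pair is absent under A because the ligand,
    the receptor, or both were below threshold there; symmetric for loss
    with the roles of A and B swapped.
    """
    lig_before = calls_before.is_expressed(cond_before, source, pair.ligand)
    rec_before = calls_before.is_expressed(cond_before, target, pair.receptor)
    suffix = change  # "gained" or "lost"
    if not lig_before and not rec_before:
        return f"both-{suffix}"
    if not rec_before:
        return f"receptor-{suffix}"
    return f"ligand-{suffix}"


def diff_networks(
    net_a: CommNetwork,
    net_b: CommNetwork,
    calls_a: ExpressionCallTable,
    calls_b: ExpressionCallTable,
) -> DiffNetwork:
    """Edge-wise comparison of condition B against condition A.

    ``gained`` = in B not A; ``lost`` = in A not B.  Each changed pair
    carries exactly one attribution tag derived from the call tables.
    """
    if set(net_a.nodes) != set(net_b.nodes):
        diff = set(net_a.nodes) ^ set(net_b.nodes)
        raise ValueError(f"node sets differ; symmetric difference: {sorted(diff)}")
    rows = []
    edge_keys = set(net_a.edges) | set(net_b.edges)
    for (s, t) in sorted(edge_keys):
        a_pairs = net_a.pairs(s, t)
        b_pairs = net_b.pairs(s, t)
        for p in sorted(b_pairs - a_pairs):
            tag = _attribute(p, s, t, "gained", calls_a, net_a.condition)
            rows.append((s, t, p.ligand, p.receptor, "gained", tag))
        for p in sorted(a_pairs - b_pairs):
            tag = _attribute(p, s, t, "lost", calls_b, net_b.condition)
            rows.append((s, t, p.ligand, p.receptor, "lost", tag))
    table = pd.DataFrame(
        rows, columns=["source", "target", "ligand", "receptor", "change", "attribution"]
    )
    return DiffNetwork(net_a.condition, net_b.condition, table)
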