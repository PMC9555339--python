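"""Term counting and hypergeometric over-representation for L-R genes.

Two complementary summaries of what a communication network "does":

* **Term counts** — for each annotation term (e.g. a molecular-function
  category), count the pair instances (source group, target group, pair)
  whose ligand (or receptor) carries the term.  Comparing the per-term
  counts between conditions shows which functions gained or lost
  potential signaling.  The counting unit is the pair *instance*, so a
  ligand reused on many edges contributes once per edge; set
  ``unique_genes=True`` to count distinct genes instead.

* **Over-representation** — for a query gene set against a stated
  universe, the upper-tail hypergeometric probability
  P(X >= k), X ~ Hypergeom(N, K, n), per term, BH-adjusted across terms.
  The universe is an explicit argument, never defaulted: enrichment
  against "all genes" and against "expressed genes" answer different
  questions.

Annotations come from a GMT file (one term per line:
``term<TAB>description<TAB>gene1<TAB>gene2...``), assumed already
propagated; no ontology-graph closure is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import normalize_symbol
from .de import bh_adjust
from .network import CommNetwork

__all__ = [
    "AnnotationMap",
    "load_gmt",
    "count_term_occurrences",
    "term_count_difference",
    "hypergeometric_enrich",
]


@dataclass
class AnnotationMap:
    """term id -> set of normalized gene symbols, plus display labels."""

    terms: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        cleaned = {}
        for term, genes in self.terms.items():
            norm = frozenset(normalize_symbol(g) for g in genes if str(g).strip())
            if not norm:
                raise ValueError(f"term {term!r} has an empty gene set")
            cleaned[term] = norm
        self.terms = cleaned

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


def load_gmt(path: str) -> AnnotationMap:
    """Read a GMT annotation file (term, description, then member genes)."""
    terms: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (needs >= 3 fields): {line[:80]!r}")
            term, label, genes = fields[0], fields[1], fields[2:]
            terms[term] = frozenset(normalize_symbol(g) for g in genes if g.strip())
            labels[term] = label
    return AnnotationMap(terms, labels)


def count_term_occurrences(
    net: CommNetwork,
    ann: AnnotationMap,
    role: str = "ligand",
    by_group: bool = False,
    unique_genes: bool = False,
) -> pd.DataFrame:
    """Per-term counts of annotated ligands/receptors in the network.

    The unit is the pair instance (source, target, pair); ``by_group``
    additionally splits counts by the broadcasting group (ligand role)
    or receiving group (receptor role).  ``unique_genes`` counts
    distinct annotated genes instead of pair instances.
    """
    if role not in ("ligand", "receptor"):
        raise ValueError(f"role must be 'ligand' or 'receptor', got {role!r}")
    records: list[tuple] = []
    for term, members in sorted(ann.terms.items()):
        if by_group:
            per_group: dict[str, list] = {}
            for (s, t), pairs in net.edges.items():
                group = s if role == "ligand" else t
                hits = [getattr(p, role) for p in pairs if getattr(p, role) in members]
                per_group.setdefault(group, []).extend(hits)
            for group, hits in sorted(per_group.items()):
                count = len(set(hits)) if unique_genes else len(hits)
                if count:
                    records.append((term, net.condition, role, group, count))
        else:
            hits = [
                getattr(p, role)
                for pairs in net.edges.values()
                for p in pairs
                if getattr(p, role) in members
            ]
            count = len(set(hits)) if unique_genes else len(hits)
            if count:
                records.append((term, net.condition, role, "", count))
    return pd.DataFrame(
        records, columns=["term", "condition", "role", "group", "count"]
    )


def term_count_difference(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-term count difference (A minus B), over the union of terms."""
    a = counts_a.groupby("term")["count"].sum()
    b = counts_b.groupby("term")["count"].sum()
    terms = sorted(set(a.index) | set(b.index))
    return pd.DataFrame(
        {
            "term": terms,
            "count_a": [int(a.get(t, 0)) for t in terms],
            "count_b": [int(b.get(t, 0)) for t in terms],
            "difference": [int(a.get(t, 0)) - int(b.get(t, 0)) for t in terms],
        }
    )


def hypergeometric_enrich(
    query: set[str], universe: set[str], ann: AnnotationMap
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each term in the query.

    With N = |universe|, K = |term ∩ universe|, n = |query| and
    k = |term ∩ query|, the p-value is P(X >= k) for
    X ~ Hypergeom(N, K, n); BH adjustment is applied across terms.
    Terms with no member in the universe are skipped.
    """
    query = {normalize_symbol(g) for g in query}
    universe = {normalize_symbol(g) for g in universe}
    if not universe:
        raise ValueError("universe is empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes not in universe: {sorted(stray)}")
    rows = []
    n_query, n_universe = len(query), len(universe)
    for term in sorted(ann.terms):
        members = ann.terms[term] & universe
        if not members:
            continue
        k = len(ann.terms[term] & query)
        K = len(members)
        # P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, n_universe, K, n_query))
        rows.append((term, k, K, n_query, n_universe, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table
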