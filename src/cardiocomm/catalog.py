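"""Ligand-receptor pair catalogs.

A catalog is a deduplicated set of *ordered* (ligand, receptor) gene
symbol pairs — the vocabulary of potential intercellular communication.
Direction matters: (A, B) with A as ligand is a different interaction
than (B, A).  Symbols are normalized (uppercased, whitespace-stripped)
so that case variants collapse to one pair; published catalogs merged
this way (2557- and 3398-pair human lists in the source literature)
union to a few thousand unique pairs.  Multi-subunit receptor complexes
are kept as whatever single symbol the source uses; no expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["LRPair", "LRCatalog", "load_catalog", "merge_catalogs", "normalize_symbol"]

logger = logging.getLogger(__name__)


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True, order=True)
class LRPair:
    ligand: str
    receptor: str

    def __post_init__(self):
        object.__setattr__(self, "ligand", normalize_symbol(self.ligand))
        object.__setattr__(self, "receptor", normalize_symbol(self.receptor))
        if not self.ligand or not self.receptor:
            raise ValueError("empty ligand or receptor symbol")


@dataclass
class LRCatalog:
    """Set of unique ordered L-R pairs with per-pair source provenance."""

    pairs: frozenset[LRPair]
    source_tags: dict[LRPair, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = frozenset(self.pairs)
        self.source_tags = {p: frozenset(self.source_tags.get(p, ())) for p in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return pair in self.pairs

    def __iter__(self):
        return iter(sorted(self.pairs))

    @property
    def ligands(self) -> frozenset[str]:
        return frozenset(p.ligand for p in self.pairs)

    @property
    def receptors(self) -> frozenset[str]:
        return frozenset(p.receptor for p in self.pairs)

    @property
    def genes(self) -> frozenset[str]:
        return self.ligands | self.receptors

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str] | LRPair], source: str | None = None
    ) -> "LRCatalog":
        norm = frozenset(p if isinstance(p, LRPair) else LRPair(*p) for p in pairs)
        tags = {p: frozenset([source] if source else []) for p in norm}
        return cls(norm, tags)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p.ligand, p.receptor, ";".join(sorted(self.source_tags.get(p, ()))))
            for p in sorted(self.pairs)
        ]
        return pd.DataFrame(rows, columns=["ligand", "receptor", "sources"])

    def write_tsv(self, path: str) -> None:
        """Canonical two-column TSV, sorted lexicographically (byte-stable)."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_catalog(
    path: str,
    ligand_col: str = "ligand",
    receptor_col: str = "receptor",
    source: str | None = None,
    sep: str | None = None,
) -> LRCatalog:
    """Load a catalog from CSV/TSV with configurable column names.

    Rows with a missing ligand or receptor are dropped and counted in
    the log.  Raises a format error naming the columns actually present
    when the named columns are absent.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (ligand_col, receptor_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"columns {missing} not found in {path}; available: {list(df.columns)}"
        )
    sub = df[[ligand_col, receptor_col]]
    ok = sub.notna().all(axis=1)
    # whitespace-only fields count as missing too
    ok &= sub.astype(str).apply(lambda s: s.str.strip().astype(bool)).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing ligand/receptor", path, n_dropped)
    pairs = [LRPair(l, r) for l, r in sub[ok].itertuples(index=False)]
    return LRCatalog.from_pairs(pairs, source=source or str(path))


def merge_catalogs(a: LRCatalog, b: LRCatalog) -> LRCatalog:
    """Set-union of two catalogs; source tags record each pair's origin(s)."""
    pairs = a.pairs | b.pairs
    tags: dict[LRPair, frozenset[str]] = {}
    for p in pairs:
        tags[p] = a.source_tags.get(p, frozenset()) | b.source_tags.get(p, frozenset())
    return LRCatalog(pairs, tags)
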