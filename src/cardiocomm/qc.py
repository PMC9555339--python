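"""Gene- and nucleus-level quality-control filters.

Droplet snRNA-seq matrices carry genes detected in almost no nuclei and
droplets that captured either ambient RNA only or two nuclei.  The
standard remedy, applied here, is (i) keep genes detected (count > 0)
in at least ``min_nuclei`` nuclei, and (ii) keep nuclei whose number of
detected genes lies within ``[min_genes, max_genes]`` — too few detected
genes indicates an ambient-RNA droplet, too many a doublet.  Defaults
are 3 nuclei and a 200–2000 gene window; both bounds are inclusive
(nuclei with *fewer than* 200 or *more than* 2000 detected genes are
excluded).

The pipeline order is fixed: genes first, then nuclei (gene removal
lowers per-nucleus detected-gene counts, so the order matters and is
part of the contract).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = ["filter_genes", "filter_nuclei", "qc_pipeline", "QCReport"]


@dataclass
class QCReport:
    n_genes_in: int
    n_genes_kept: int
    n_cells_in: int
    n_cells_kept: int

    @property
    def genes_removed(self) -> int:
        return self.n_genes_in - self.n_genes_kept

    @property
    def cells_removed(self) -> int:
        return self.n_cells_in - self.n_cells_kept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["genes_removed", "genes_kept", "cells_removed", "cells_kept"],
                "value": [self.genes_removed, self.n_genes_kept,
                          self.cells_removed, self.n_cells_kept],
            }
        )


def filter_genes(
    m: CountMatrix, min_nuclei: int = 3, batch_key: str | None = None
) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_nuclei`` nuclei.

    With ``batch_key`` set to a metadata column, the threshold is applied
    within each batch and a gene is kept if it passes in at least one
    batch — equivalent to filtering each dataset separately and taking
    the union of retained genes on integration.
    """
    if min_nuclei < 1:
        raise ValueError("min_nuclei must be >= 1")
    if m.n_genes == 0 or m.n_cells == 0:
        return m.subset_genes(np.zeros(m.n_genes, dtype=bool)) if m.n_genes else m
    if batch_key is None:
        keep = m.cells_per_gene() >= min_nuclei
    else:
        batches = m.cell_meta[batch_key]
        keep = np.zeros(m.n_genes, dtype=bool)
        for batch in batches.unique():
            sub = m.subset_cells((batches == batch).to_numpy())
            keep |= sub.cells_per_gene() >= min_nuclei
    return m.subset_genes(keep)


def filter_nuclei(
    m: CountMatrix, min_genes: int = 200, max_genes: int = 2000
) -> CountMatrix:
    """Keep nuclei whose detected-gene count g satisfies min_genes <= g <= max_genes."""
    if min_genes > max_genes:
        raise ValueError(f"min_genes ({min_genes}) > max_genes ({max_genes})")
    g = m.genes_per_cell()
    return m.subset_cells((g >= min_genes) & (g <= max_genes))


def qc_pipeline(
    m: CountMatrix,
    min_nuclei: int = 3,
    min_genes: int = 200,
    max_genes: int = 2000,
    batch_key: str | None = None,
) -> tuple[CountMatrix, QCReport]:
    """Gene filter then nucleus filter, with a removal report."""
    n_genes_in, n_cells_in = m.n_genes, m.n_cells
    out = filter_genes(m, min_nuclei=min_nuclei, batch_key=batch_key)
    out = filter_nuclei(out, min_genes=min_genes, max_genes=max_genes)
    return out, QCReport(n_genes_in, out.n_genes, n_cells_in, out.n_cells)
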