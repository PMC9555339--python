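"""Moran's I spatial autocorrelation over an embedding kNN graph.

Genes whose expression concentrates in a focal region of a 2D embedding
(UMAP-like coordinates) are detected with Moran's I,

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,

computed on a symmetrized k-nearest-neighbor graph over the embedding
(binary weights, optionally row-standardized).  I ranges from about -1
(perfect dispersion) through -1/(N-1) (the null expectation) to 1
(perfect positive autocorrelation).  Significance comes either from the
analytic normal approximation (normality-assumption moments) or from a
one-sided permutation test for positive autocorrelation.

The screen applied per (condition, cell type) stratum declares a gene
spatially differentially expressed when I > 0, BH-adjusted p <= 0.05
and the gene is detected in at least 1% of the stratum's cells.  A
conservative cross-condition selection then keeps genes that pass in a
single condition only if I > 0.1 there, and genes that pass in both
conditions only if |I_normal - I_hcm| > 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .de import bh_adjust
from .matrix import CountMatrix

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "build_knn_weights",
    "morans_i",
    "morans_test",
    "screen_genes",
    "select_spatial_degs",
    "normalized_expression",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Sparse spatial weight matrix (zero diagonal, nonnegative)."""

    w: sp.csr_matrix

    def __post_init__(self):
        self.w = self.w.tocsr()
        if self.w.shape[0] != self.w.shape[1]:
            raise ValueError("weight matrix must be square")
        if self.w.diagonal().any():
            raise ValueError("self-weights must be zero")
        if self.w.data.size and self.w.data.min() < 0:
            raise ValueError("weights must be nonnegative")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def total(self) -> float:
        """W = sum_ij w_ij."""
        return float(self.w.sum())


def build_knn_weights(
    embedding: np.ndarray, k: int = 15, row_standardize: bool = True
) -> SpatialWeights:
    """Symmetrized (union) k-nearest-neighbor graph on 2D coordinates.

    Each node is linked to its k nearest Euclidean neighbors (ties broken
    by node index); the binary adjacency is symmetrized by union and then
    optionally row-standardized so every non-isolated row sums to 1.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2:
        raise ValueError("embedding must be n x d")
    n = embedding.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    if not np.isfinite(embedding).all():
        raise ValueError("embedding coordinates must be finite")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    adj = nn.kneighbors_graph(embedding, mode="connectivity").tolil()
    adj.setdiag(0)  # kneighbors includes self at distance 0
    adj = adj.tocsr()
    adj = ((adj + adj.T) > 0).astype(float)  # union symmetrization
    adj.setdiag(0)
    adj.eliminate_zeros()
    if row_standardize:
        rowsum = np.asarray(adj.sum(axis=1)).ravel()
        inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
        adj = sp.diags(inv) @ adj
    return SpatialWeights(adj.tocsr())


def morans_i(x: np.ndarray, w: SpatialWeights) -> float:
    """Moran's I; NaN (undefined) for constant x."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != w.n:
        raise ValueError(f"expression vector length {x.shape[0]} != n nodes {w.n}")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return float("nan")
    numer = float(xc @ (w.w @ xc))
    return (w.n / w.total) * numer / denom


def _analytic_moments(w: SpatialWeights) -> tuple[float, float]:
    """E[I] and Var[I] under the normality assumption."""
    n = w.n
    W = w.total
    wm = w.w
    s1 = 0.5 * float(((wm + wm.T).power(2)).sum())
    row = np.asarray(wm.sum(axis=1)).ravel()
    col = np.asarray(wm.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    e_i = -1.0 / (n - 1)
    var = (n * n * s1 - n * s2 + 3.0 * W * W) / (W * W * (n * n - 1)) - e_i * e_i
    return e_i, var


@dataclass
class MoranResult:
    i: float
    p: float
    expected: float
    method: str


def morans_test(
    x: np.ndarray,
    w: SpatialWeights,
    method: str = "analytic_z",
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """One-sided test for positive spatial autocorrelation.

    ``analytic_z`` uses E[I] = -1/(N-1) and the normality-assumption
    variance; ``permutation`` uses p = (1 + #{I_perm >= I_obs}) / (1 + n_perm).
    Constant x yields an undefined statistic (NaN I and p).
    """
    obs = morans_i(x, w)
    e_i = -1.0 / (w.n - 1)
    if np.isnan(obs):
        return MoranResult(float("nan"), float("nan"), e_i, method)
    if method == "analytic_z":
        e, var = _analytic_moments(w)
        z = (obs - e) / np.sqrt(var)
        return MoranResult(obs, float(stats.norm.sf(z)), e, method)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        x = np.asarray(x, dtype=float)
        xc = x - x.mean()
        denom = float(xc @ xc)
        perms = np.stack([rng.permutation(xc) for _ in range(n_perm)], axis=1)
        numer = np.einsum("ij,ij->j", perms, w.w @ perms)
        i_perm = (w.n / w.total) * numer / denom
        exceed = int((i_perm >= obs - 1e-12).sum())
        return MoranResult(obs, (1 + exceed) / (1 + n_perm), e_i, method)
    raise ValueError(f"unknown method {method!r}")


def normalized_expression(m: CountMatrix) -> np.ndarray:
    """log1p of library-size-normalized counts (dense cells x genes).

    Size factor per cell = total counts / median total counts, so raw
    depth differences do not masquerade as spatial structure.
    """
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    sf = np.where(totals > 0, totals / med, 1.0)
    dense = m.counts.toarray().astype(float)
    return np.log1p(dense / sf[:, None])


def screen_genes(
    m: CountMatrix,
    condition: str,
    cell_type: str,
    k: int = 15,
    method: str = "analytic_z",
    n_perm: int = 999,
    seed: int | None = None,
    min_frac: float = 0.01,
    alpha: float = 0.05,
    transform: bool = True,
) -> pd.DataFrame:
    """Per-gene Moran's I screen within one (condition, cell type) stratum.

    Returns a table with I, p, BH-adjusted p (within the stratum),
    detected fraction and a ``passes`` flag:
    (I > 0) & (p_adj <= alpha) & (fraction >= min_frac).  Genes with an
    undefined I (constant expression) have NaN statistics and never pass.

    For the permutation method one permutation index matrix is drawn per
    stratum and shared across genes (each gene's p-value is marginally
    exact; only cross-gene dependence is introduced).
    """
    stratum = m.stratum(condition=condition, cell_type=cell_type)
    if stratum.n_cells < k + 1:
        logger.warning(
            "stratum (%s, %s) has %d cells <= k=%d; skipped",
            condition, cell_type, stratum.n_cells, k,
        )
        return pd.DataFrame(
            columns=["condition", "cell_type", "gene", "I", "p", "p_adj",
                     "frac_expressed", "defined", "passes"]
        )
    emb = stratum.cell_meta[["embedding_x", "embedding_y"]].to_numpy()
    w = build_knn_weights(emb, k=k)
    expr = normalized_expression(stratum) if transform else stratum.counts.toarray().astype(float)
    n = stratum.n_cells
    frac = np.asarray((stratum.counts > 0).sum(axis=0)).ravel() / n

    xc = expr - expr.mean(axis=0, keepdims=True)
    denom = np.einsum("ij,ij->j", xc, xc)
    defined = denom > 0
    i_obs = np.full(stratum.n_genes, np.nan)
    wxc = w.w @ xc
    numer = np.einsum("ij,ij->j", xc, wxc)
    with np.errstate(invalid="ignore", divide="ignore"):
        i_all = (n / w.total) * numer / denom
    i_obs[defined] = i_all[defined]

    p = np.full(stratum.n_genes, np.nan)
    if method == "analytic_z":
        e, var = _analytic_moments(w)
        z = (i_obs[defined] - e) / np.sqrt(var)
        p[defined] = stats.norm.sf(z)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
        exceed = np.zeros(stratum.n_genes, dtype=int)
        for rows in perm_idx:
            xp = xc[rows, :]
            num_p = np.einsum("ij,ij->j", xp, w.w @ xp)
            with np.errstate(invalid="ignore", divide="ignore"):
                i_p = (n / w.total) * num_p / denom
            exceed += (i_p >= i_all - 1e-12) & defined
        p[defined] = (1 + exceed[defined]) / (1 + n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")

    p_adj = bh_adjust(p)
    passes = defined & (i_obs > 0) & (p_adj <= alpha) & (frac >= min_frac)
    return pd.DataFrame(
        {
            "condition": condition,
            "cell_type": cell_type,
            "gene": stratum.gene_ids,
            "I": i_obs,
            "p": p,
            "p_adj": p_adj,
            "frac_expressed": frac,
            "defined": defined,
            "passes": passes,
        }
    )


def select_spatial_degs(
    normal: pd.DataFrame,
    hcm: pd.DataFrame,
    i_threshold: float = 0.1,
    delta_threshold: float = 0.1,
    availability: str = "screen",
) -> pd.DataFrame:
    """Conservative cross-condition selection of spatial genes.

    A gene "available" in exactly one condition is selected when its
    Moran's I there exceeds ``i_threshold``; a gene available in both is
    selected when |I_normal - I_hcm| > ``delta_threshold``.  With
    ``availability="screen"`` (default) availability means passing the
    per-stratum screen; ``"computed"`` means I was defined at all.

    Returns one row per selected gene: gene, cell_type, rule
    ("single" or "both"), condition of origin (single rule), I values
    and |ΔI|.
    """
    if availability not in ("screen", "computed"):
        raise ValueError("availability must be 'screen' or 'computed'")
    flag = "passes" if availability == "screen" else "defined"
    n_idx = normal.set_index("gene")
    h_idx = hcm.set_index("gene")
    genes = sorted(set(n_idx.index) | set(h_idx.index))
    cell_type = None
    for df in (normal, hcm):
        if len(df):
            cell_type = df["cell_type"].iloc[0]
    rows = []
    for gene in genes:
        in_n = gene in n_idx.index and bool(n_idx.loc[gene, flag])
        in_h = gene in h_idx.index and bool(h_idx.loc[gene, flag])
        i_n = float(n_idx.loc[gene, "I"]) if gene in n_idx.index else float("nan")
        i_h = float(h_idx.loc[gene, "I"]) if gene in h_idx.index else float("nan")
        if in_n and in_h:
            delta = abs(i_n - i_h)
            if delta > delta_threshold:
                rows.append((gene, cell_type, "both", "", i_n, i_h, delta))
        elif in_n or in_h:
            cond, i_val = ("Normal", i_n) if in_n else ("HCM", i_h)
            if i_val > i_threshold:
                rows.append((gene, cell_type, "single", cond, i_n, i_h, float("nan")))
    return pd.DataFrame(
        rows,
        columns=["gene", "cell_type", "rule", "condition", "I_normal", "I_hcm", "delta_I"],
    )
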