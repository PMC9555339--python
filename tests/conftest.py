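import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cardiocomm.matrix import CountMatrix


def make_matrix(
    counts,
    conditions=None,
    cell_types=None,
    clusters=None,
    embedding=None,
    batch=None,
) -> CountMatrix:
    """Build a CountMatrix from a dense array with minimal default metadata."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    gene_ids = [f"g{j:03d}" for j in range(n_genes)]
    if embedding is None:
        rng = np.random.default_rng(0)
        embedding = rng.normal(size=(n_cells, 2))
    meta = pd.DataFrame(
        {
            "condition": conditions if conditions is not None else ["Normal"] * n_cells,
            "cell_type": cell_types if cell_types is not None else ["typeA"] * n_cells,
            "cluster": clusters if clusters is not None else ["c0"] * n_cells,
            "embedding_x": np.asarray(embedding)[:, 0],
            "embedding_y": np.asarray(embedding)[:, 1],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    if batch is not None:
        meta["batch"] = batch
    return CountMatrix(sp.csr_matrix(counts), gene_ids, cell_ids, meta)


def moran_double_loop(x, w_dense) -> float:
    """Independent double-loop evaluation of Moran's I."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xbar = x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * (x[i] - xbar) * (x[j] - xbar)
    denom = ((x - xbar) ** 2).sum()
    return (n / w_dense.sum()) * num / denom


def irls_poisson(y, x, n_iter=200, tol=1e-12):
    """Independent IRLS for the log-link Poisson GLM with design [1, x].

    Returns (beta, standard errors, deviance trace).
    """
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones_like(np.asarray(x, float)), np.asarray(x, float)])
    beta = np.array([np.log(max(y.mean(), 1e-8)), 0.0])
    deviances = []
    for _ in range(n_iter):
        eta = design @ beta
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        deviances.append(2.0 * dev_terms.sum())
        z = eta + (y - mu) / mu
        wt = mu
        xtw = design.T * wt
        beta_new = np.linalg.solve(xtw @ design, xtw @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = design @ beta
    mu = np.exp(eta)
    cov = np.linalg.inv((design.T * mu) @ design)
    return beta, np.sqrt(np.diag(cov)), deviances


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
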