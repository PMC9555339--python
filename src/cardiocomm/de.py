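"""Per-gene log-link GLM with Wald tests for condition differences.

Each gene's counts y are modelled as log E[y_i] = beta0 + beta_t * x_i,
where x is the condition indicator (0 = Normal, 1 = HCM) or, optionally,
pseudotime.  beta_t is tested against zero with a Wald test
(z = beta_t / se, two-sided normal reference) and p-values are
BH-adjusted within each stratum (cell type or cluster); a gene is
called differentially expressed at adjusted p <= 0.05.

For the common special case — Poisson family, binary two-level design,
no offset — the MLE has a closed form used directly:

    beta0 = log(mean y | x=0),   beta_t = log(mean y | x=1) - beta0,
    se(beta_t) = sqrt(1/sum(y | x=0) + 1/sum(y | x=1)).

General designs go through iteratively reweighted least squares
(statsmodels GLM).  The default family is negative binomial with a
moment-estimated dispersion, falling back to Poisson when the data show
no overdispersion; snRNA-seq counts are typically overdispersed, so
Poisson standard errors would be anticonservative there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CountMatrix

__all__ = ["GLMFit", "fit_gene_glm", "wald_test", "bh_adjust", "de_scan"]

logger = logging.getLogger(__name__)


@dataclass
class GLMFit:
    beta0: float
    beta_t: float
    se_t: float
    family: str
    degenerate: bool = False


def _binary_poisson_closed_form(y: np.ndarray, x: np.ndarray) -> GLMFit:
    lo, hi = np.unique(x)
    y0, y1 = y[x == lo], y[x == hi]
    s0, s1 = float(y0.sum()), float(y1.sum())
    if s0 == 0.0 or s1 == 0.0:
        # a group with all-zero counts: log-mean diverges
        return GLMFit(float("nan"), float("nan"), float("inf"), "poisson", degenerate=True)
    beta0 = float(np.log(y0.mean()))
    beta_t = float(np.log(y1.mean()) - np.log(y0.mean()))
    se_t = float(np.sqrt(1.0 / s0 + 1.0 / s1))
    return GLMFit(beta0, beta_t, se_t, "poisson")


def _estimate_nb_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion alpha (Var = mu + alpha mu^2); 0 if none."""
    resid = (y - mu) ** 2 - mu
    denom = float((mu**2).sum())
    if denom == 0:
        return 0.0
    return max(0.0, float(resid.sum()) / denom)


def fit_gene_glm(
    y: np.ndarray,
    x: np.ndarray,
    family: str = "poisson",
    offset: np.ndarray | None = None,
) -> GLMFit:
    """Fit log E[y] = beta0 + beta_t x by maximum likelihood.

    Degenerate designs (a group with zero total counts) are flagged with
    infinite standard error rather than raising, so scans can skip them.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("y and x must be equal-length with at least 3 observations")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("y must be nonnegative integer counts")
    if np.unique(x).size < 2:
        raise ValueError("covariate must take at least 2 distinct values")
    if family not in ("poisson", "negative_binomial"):
        raise ValueError(f"unknown family {family!r}")

    binary = np.unique(x).size == 2
    if family == "poisson" and binary and offset is None:
        return _binary_poisson_closed_form(y, x)

    import statsmodels.api as sm

    design = np.column_stack([np.ones_like(x), x])
    if family == "poisson":
        fam = sm.families.Poisson()
    else:
        # moment-estimate alpha from a Poisson pilot fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pilot = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset).fit()
        alpha = _estimate_nb_alpha(y, pilot.mu)
        if alpha <= 1e-8:
            fam = sm.families.Poisson()
            family = "poisson"
        else:
            fam = sm.families.NegativeBinomial(alpha=alpha)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=fam, offset=offset).fit()
    except Exception:  # pragma: no cover - pathological separation
        return GLMFit(float("nan"), float("nan"), float("inf"), family, degenerate=True)
    se_t = float(res.bse[1])
    degenerate = not np.isfinite(se_t) or se_t > 1e6
    return GLMFit(float(res.params[0]), float(res.params[1]), se_t, family, degenerate)


def wald_test(beta_t: float, se_t: float) -> float:
    """Two-sided p-value for beta_t = 0 from the standard normal reference."""
    if not np.isfinite(se_t) or se_t <= 0:
        return float("nan")
    z = beta_t / se_t
    return float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate, excluded from ranking."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def de_scan(
    m: CountMatrix,
    stratify_by: str = "cell_type",
    covariate: str = "condition",
    family: str = "negative_binomial",
    adjust: str = "bh",
    alpha: float = 0.05,
    condition_levels: tuple[str, str] = ("Normal", "HCM"),
    offset_library_size: bool = False,
) -> pd.DataFrame:
    """Per-stratum, per-gene GLM Wald scan with FDR adjustment.

    Strata containing a single condition are skipped with a warning;
    genes with all-zero counts in a stratum are excluded before fitting
    (degenerate likelihood).  Returns one row per (stratum, gene) fitted.
    """
    if stratify_by not in m.cell_meta.columns:
        raise KeyError(f"stratify column {stratify_by!r} not found")
    rows = []
    for stratum_label in sorted(m.cell_meta[stratify_by].astype(str).unique()):
        sub = m.stratum(**{stratify_by: stratum_label})
        if covariate == "condition":
            conds = set(sub.cell_meta["condition"])
            if not set(condition_levels) <= conds:
                logger.warning("stratum %r lacks both conditions; skipped", stratum_label)
                continue
            x = (sub.cell_meta["condition"] == condition_levels[1]).to_numpy(float)
        else:
            x = sub.cell_meta[covariate].to_numpy(float)
            if np.unique(x).size < 2:
                logger.warning("stratum %r has constant covariate; skipped", stratum_label)
                continue
        offset = None
        if offset_library_size:
            totals = np.asarray(sub.counts.sum(axis=1)).ravel().astype(float)
            offset = np.log(np.maximum(totals, 1.0))
        dense = sub.counts.toarray()
        for j, gene in enumerate(sub.gene_ids):
            y = dense[:, j]
            if y.sum() == 0:
                continue
            fit = fit_gene_glm(y, x, family=family, offset=offset)
            p = float("nan") if fit.degenerate else wald_test(fit.beta_t, fit.se_t)
            rows.append(
                (stratum_label, gene, fit.beta0, fit.beta_t, fit.se_t, fit.family, p)
            )
    table = pd.DataFrame(
        rows, columns=["stratum", "gene", "beta0", "beta_t", "se_t", "family", "p"]
    )
    if not len(table):
        table["p_adj"] = []
        table["significant"] = []
        return table
    if adjust == "bh":
        table["p_adj"] = table.groupby("stratum")["p"].transform(
            lambda p: bh_adjust(p.to_numpy())
        )
    elif adjust == "bonferroni":
        table["p_adj"] = table.groupby("stratum")["p"].transform(
            lambda p: np.minimum(p * p.notna().sum(), 1.0)
        )
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    table["significant"] = table["p_adj"] <= alpha
    return table
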