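"""Synthetic snRNA-seq counts with planted, recoverable ground truth.

The generator emulates the statistical structure the pipeline consumes:
several cell types observed under two conditions (Normal / HCM-like),
negative-binomial UMI counts, per-(cell type, condition) *planted*
nonzero-expression fractions for ligand/receptor genes, planted
log-fold-change condition effects for DE genes, and embedding-localized
(Gaussian bump) expression for spatial genes.  Every planted feature is
recorded in a :class:`TruthSet` derived deterministically from the
configuration alone, so pipeline output can be compared against truth
exactly.

Planted detection fractions are hit by inverting the NB zero
probability: with dispersion (size) r and mean mu,
P(count = 0) = (1 + mu/r)^(-r), so the mean that realizes a target
nonzero fraction f is mu = r * ((1 - f)^(-1/r) - 1).  With
``nb_dispersion=None`` counts are Poisson and mu = -log(1 - f).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .catalog import LRCatalog
from .matrix import CountMatrix
from .network import (
    ExpressionCallTable,
    CommNetwork,
    DiffNetwork,
    build_network,
    diff_networks,
)

__all__ = [
    "PlantedFraction",
    "PlantedEffect",
    "PlantedSpatial",
    "SimConfig",
    "TruthSet",
    "generate_dataset",
    "derive_truth",
    "mean_for_fraction",
    "baseline_fraction",
]

DEFAULT_CELL_TYPES = (
    "fibroblast", "dendritic", "smooth_muscle", "pericyte",
    "cardiomyocyte", "endothelial", "leukocyte", "neuronal",
)


@dataclass(frozen=True)
class PlantedFraction:
    """Target nonzero-count fraction for one (gene, group, condition)."""

    gene: str
    group: str
    condition: str
    fraction: float


@dataclass(frozen=True)
class PlantedEffect:
    """Condition log-fold-change for one gene within one stratum."""

    gene: str
    stratum: str
    log_fold_change: float


@dataclass(frozen=True)
class PlantedSpatial:
    """Embedding-localized expression bump for one (gene, group, condition)."""

    gene: str
    group: str
    condition: str
    focus: tuple[float, float]
    decay: float
    amplitude: float


@dataclass
class SimConfig:
    n_cell_types: int = 4
    cells_per_type_per_condition: int = 600
    n_genes: int = 300
    nb_dispersion: float | None = 2.0  # NB size r; None = Poisson
    baseline_mean: float = 0.5
    spatial_background: float = 0.05
    blob_sd: float = 1.0
    conditions: tuple[str, str] = ("Normal", "HCM")
    cell_types: tuple[str, ...] = ()
    gene_names: tuple[str, ...] = ()
    planted_lr: list[PlantedFraction] = field(default_factory=list)
    planted_de: list[PlantedEffect] = field(default_factory=list)
    planted_spatial: list[PlantedSpatial] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not self.cell_types:
            base = list(DEFAULT_CELL_TYPES)
            while len(base) < self.n_cell_types:
                base.append(f"cell_type_{len(base)}")
            self.cell_types = tuple(base[: self.n_cell_types])
        if not self.gene_names:
            self.gene_names = tuple(f"G{i + 1:04d}" for i in range(self.n_genes))
        if len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length must equal n_genes")
        universe = set(self.gene_names)
        types = set(self.cell_types)
        conds = set(self.conditions)
        for p in self.planted_lr:
            if p.gene not in universe:
                raise ValueError(f"planted gene {p.gene!r} not in gene universe")
            if p.group not in types or p.condition not in conds:
                raise ValueError(f"planting references unknown group/condition: {p}")
            if not (0.0 < p.fraction < 1.0):
                raise ValueError(
                    f"target fraction for {p.gene!r} must be in (0, 1), got {p.fraction}"
                )
        for s in self.planted_spatial:
            if s.gene not in universe:
                raise ValueError(f"planted spatial gene {s.gene!r} not in gene universe")
            if s.decay <= 0:
                raise ValueError(f"decay length for {s.gene!r} must be > 0")
        for d in self.planted_de:
            if d.gene not in universe:
                raise ValueError(f"planted DE gene {d.gene!r} not in gene universe")

    # -- serialization -------------------------------------------------
    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_lr"] = [PlantedFraction(**p) for p in raw.get("planted_lr", [])]
        raw["planted_de"] = [PlantedEffect(**p) for p in raw.get("planted_de", [])]
        raw["planted_spatial"] = [
            PlantedSpatial(**{**p, "focus": tuple(p["focus"])})
            for p in raw.get("planted_spatial", [])
        ]
        for key in ("conditions", "cell_types", "gene_names"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def mean_for_fraction(fraction: float, nb_dispersion: float | None, gene: str = "?") -> float:
    """Mean realizing a target nonzero fraction under NB(r) or Poisson."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(
            f"target nonzero fraction for gene {gene!r} must be in (0, 1), got {fraction}"
        )
    if nb_dispersion is None:
        return float(-np.log1p(-fraction))
    r = float(nb_dispersion)
    if r <= 0:
        raise ValueError(f"nb_dispersion must be > 0, got {r}")
    return float(r * ((1.0 - fraction) ** (-1.0 / r) - 1.0))


def baseline_fraction(mean: float, nb_dispersion: float | None) -> float:
    """Nonzero-count probability implied by a mean under NB(r) or Poisson."""
    if nb_dispersion is None:
        return float(1.0 - np.exp(-mean))
    r = float(nb_dispersion)
    return float(1.0 - (1.0 + mean / r) ** (-r))


def _blob_centers(cell_types: tuple[str, ...], radius: float = 10.0) -> dict[str, np.ndarray]:
    angles = np.linspace(0, 2 * np.pi, len(cell_types), endpoint=False)
    return {
        ct: radius * np.array([np.cos(a), np.sin(a)])
        for ct, a in zip(cell_types, angles)
    }


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, r: float | None) -> np.ndarray:
    if r is None:
        return rng.poisson(mu)
    return rng.negative_binomial(r, r / (r + mu))


def generate_dataset(cfg: SimConfig) -> tuple[CountMatrix, "TruthSet"]:
    """Draw a count matrix from the configuration; same seed, same bytes."""
    rng = np.random.default_rng(cfg.seed)
    centers = _blob_centers(cfg.cell_types)

    conditions, types = [], []
    for cond in cfg.conditions:
        for ct in cfg.cell_types:
            conditions += [cond] * cfg.cells_per_type_per_condition
            types += [ct] * cfg.cells_per_type_per_condition
    n_cells = len(conditions)
    cell_ids = [f"{c}_{t}_{i:05d}" for i, (c, t) in enumerate(zip(conditions, types))]
    emb = np.vstack([centers[t] for t in types]) + rng.normal(0, cfg.blob_sd, (n_cells, 2))
    cluster = [f"c{cfg.cell_types.index(t)}" for t in types]
    batch = [f"{c}_s{i % 2}" for i, c in enumerate(conditions)]
    pseudotime = np.linalg.norm(
        emb - np.vstack([centers[t] for t in types]), axis=1
    )
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "cell_type": types,
            "cluster": cluster,
            "embedding_x": emb[:, 0],
            "embedding_y": emb[:, 1],
            "pseudotime": pseudotime,
            "batch": batch,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )

    gene_pos = {g: j for j, g in enumerate(cfg.gene_names)}
    cond_arr = np.asarray(conditions)
    type_arr = np.asarray(types)

    mu = np.full((n_cells, cfg.n_genes), cfg.baseline_mean, dtype=float)
    spatial_genes = {s.gene for s in cfg.planted_spatial}
    for g in spatial_genes:
        mu[:, gene_pos[g]] = cfg.spatial_background
    for p in cfg.planted_lr:
        mask = (cond_arr == p.condition) & (type_arr == p.group)
        mu[mask, gene_pos[p.gene]] = mean_for_fraction(p.fraction, cfg.nb_dispersion, p.gene)
    for d in cfg.planted_de:
        mask = (cond_arr == cfg.conditions[1]) & (type_arr == d.stratum)
        mu[mask, gene_pos[d.gene]] *= np.exp(d.log_fold_change)
    for s in cfg.planted_spatial:
        mask = (cond_arr == s.condition) & (type_arr == s.group)
        d2 = ((emb[mask] - np.asarray(s.focus)) ** 2).sum(axis=1)
        mu[mask, gene_pos[s.gene]] = cfg.spatial_background + s.amplitude * np.exp(
            -d2 / s.decay**2
        )

    counts = _sample_counts(rng, mu, cfg.nb_dispersion)
    matrix = CountMatrix(sp.csr_matrix(counts), list(cfg.gene_names), cell_ids, meta)
    return matrix, derive_truth(cfg)


@dataclass
class TruthSet:
    """Ground truth derived from a SimConfig, no simulation involved."""

    expected_calls: ExpressionCallTable | None
    networks: dict[str, CommNetwork]
    diff: DiffNetwork | None
    spatial_genes: dict[tuple[str, str], frozenset[str]]  # (group, condition) -> genes
    de_genes: dict[str, frozenset[str]]  # stratum -> genes

    def to_json(self, path: str) -> None:
        payload = {
            "spatial_genes": {
                f"{g}|{c}": sorted(genes) for (g, c), genes in self.spatial_genes.items()
            },
            "de_genes": {s: sorted(genes) for s, genes in self.de_genes.items()},
        }
        if self.expected_calls is not None:
            payload["expressed"] = [
                [r.condition, r.group, r.gene]
                for r in self.expected_calls.table.itertuples()
                if r.expressed
            ]
        if self.diff is not None:
            payload["diff"] = self.diff.table.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def derive_truth(
    cfg: SimConfig, catalog: LRCatalog | None = None, threshold: float = 0.20
) -> TruthSet:
    """Expected calls, networks, diff and gene lists implied by the config.

    Expression calls cover the catalog's genes: the expected fraction of
    a (gene, group, condition) is its planted value when planted and the
    baseline-mean-implied value otherwise.  Networks and the diff are
    produced by the same communication rules the pipeline applies, fed
    with the expected (noise-free) calls.
    """
    spatial = {}
    for s in cfg.planted_spatial:
        key = (s.group, s.condition)
        spatial.setdefault(key, set()).add(s.gene)
    spatial_truth = {k: frozenset(v) for k, v in spatial.items()}
    de: dict[str, set[str]] = {}
    for d in cfg.planted_de:
        if d.log_fold_change != 0.0:
            de.setdefault(d.stratum, set()).add(d.gene)
    de_truth = {k: frozenset(v) for k, v in de.items()}

    if catalog is None:
        return TruthSet(None, {}, None, spatial_truth, de_truth)

    planted = {
        (p.condition, p.group, p.gene): p.fraction for p in cfg.planted_lr
    }
    base = baseline_fraction(cfg.baseline_mean, cfg.nb_dispersion)
    genes = sorted(g for g in catalog.genes if g in set(cfg.gene_names))
    rows = []
    for cond in cfg.conditions:
        for group in cfg.cell_types:
            for gene in genes:
                frac = planted.get((cond, group, gene), base)
                rows.append(
                    (cond, group, gene, cfg.cells_per_type_per_condition,
                     frac, frac >= threshold)
                )
    calls = ExpressionCallTable(
        pd.DataFrame(
            rows,
            columns=["condition", "group", "gene", "n_cells", "fraction", "expressed"],
        ),
        threshold,
    )
    networks = {cond: build_network(calls, catalog, cond) for cond in cfg.conditions}
    diff = diff_networks(
        networks[cfg.conditions[0]], networks[cfg.conditions[1]], calls, calls
    )
    return TruthSet(calls, networks, diff, spatial_truth, de_truth)
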