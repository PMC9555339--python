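"""End-to-end orchestration: config, stage sequencing, artifact manifest.

A run is described by a single serializable :class:`PipelineConfig`
(paths, thresholds, seed, stage toggles).  ``run_pipeline`` executes the
enabled stages in the fixed order qc → calls → network → diff → spatial
→ de → enrich, writes every table as a deterministically sorted TSV and
records each output with a SHA-256 content hash in a JSON manifest, so
a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

from . import catalog as cat
from . import enrich as en
from . import network as nw
from . import qc as qcmod
from . import spatial as sa
from . import de as demod
from .matrix import CountMatrix, read_mtx_dir, read_csv

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

logger = logging.getLogger(__name__)

STAGES = ("qc", "calls", "network", "diff", "spatial", "de", "enrich")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    matrix_dir: str = ""
    matrix_csv: str = ""
    meta_tsv: str = ""
    catalog_paths: list[str] = field(default_factory=list)
    annotation_gmt: str = ""
    output_dir: str = "results"
    # thresholds (documented ranges enforced in validate)
    expression_threshold: float = 0.20
    moran_i_threshold: float = 0.1
    delta_i_threshold: float = 0.1
    min_frac: float = 0.01
    alpha: float = 0.05
    qc_min_nuclei: int = 3
    qc_min_genes: int = 200
    qc_max_genes: int = 2000
    knn_k: int = 15
    moran_method: str = "analytic_z"
    n_perm: int = 999
    de_family: str = "negative_binomial"
    group_by: str = "cell_type"
    conditions: tuple[str, str] = ("Normal", "HCM")
    enrich_role: str = "ligand"
    enrich_universe: str = "catalog"  # {catalog, network, custom}
    enrich_universe_path: str = ""
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        if not (0.0 < self.expression_threshold <= 1.0):
            raise ValueError(f"expression threshold {self.expression_threshold} outside (0, 1]")
        if not (0.0 <= self.min_frac <= 1.0):
            raise ValueError("min_frac outside [0, 1]")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha outside (0, 1]")
        if self.qc_min_genes > self.qc_max_genes:
            raise ValueError("qc_min_genes > qc_max_genes")
        if self.qc_min_nuclei < 1:
            raise ValueError("qc_min_nuclei < 1")
        if self.moran_i_threshold < 0 or self.delta_i_threshold < 0:
            raise ValueError("Moran thresholds must be nonnegative")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("conditions", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_matrix(cfg: PipelineConfig) -> CountMatrix:
    if cfg.matrix_dir:
        return read_mtx_dir(cfg.matrix_dir)
    if cfg.matrix_csv:
        return read_csv(cfg.matrix_csv, cfg.meta_tsv)
    raise ValueError("config must set matrix_dir or matrix_csv")


def run_pipeline(cfg: PipelineConfig, matrix: CountMatrix | None = None) -> dict:
    """Run the enabled stages in order; return the artifact manifest.

    On stage failure a :class:`StageError` naming the stage is raised;
    outputs written so far are kept and a ``FAILED`` marker file records
    the failing stage.
    """
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    outputs: list[str] = []
    thresholds_used = {
        "expression_threshold": cfg.expression_threshold,
        "moran_i_threshold": cfg.moran_i_threshold,
        "delta_i_threshold": cfg.delta_i_threshold,
        "min_frac": cfg.min_frac,
        "alpha": cfg.alpha,
        "qc": [cfg.qc_min_nuclei, cfg.qc_min_genes, cfg.qc_max_genes],
    }

    def emit(name: str, frame) -> None:
        path = os.path.join(cfg.output_dir, name)
        frame.to_csv(path, sep="\t", index=False)
        outputs.append(path)

    stage = "load"
    try:
        m = matrix if matrix is not None else _load_matrix(cfg)

        catalog = None
        if cfg.catalog_paths:
            catalog = cat.load_catalog(cfg.catalog_paths[0])
            for extra in cfg.catalog_paths[1:]:
                catalog = cat.merge_catalogs(catalog, cat.load_catalog(extra))

        if "qc" in cfg.stages:
            stage = "qc"
            m, report = qcmod.qc_pipeline(
                m, cfg.qc_min_nuclei, cfg.qc_min_genes, cfg.qc_max_genes
            )
            emit("qc_report.tsv", report.to_frame())

        calls = None
        if "calls" in cfg.stages or "network" in cfg.stages or "diff" in cfg.stages:
            stage = "calls"
            genes = sorted(g for g in (catalog.genes if catalog else set())
                           if g in set(m.gene_ids)) or None
            calls = nw.compute_expression_calls(
                m, grouping=cfg.group_by, threshold=cfg.expression_threshold, genes=genes
            )
            emit("expression_calls.tsv", calls.table)

        nets = {}
        if "network" in cfg.stages or "diff" in cfg.stages:
            stage = "network"
            if catalog is None:
                raise ValueError("network stage needs at least one catalog path")
            for cond in cfg.conditions:
                nets[cond] = nw.build_network(calls, catalog, cond)
                emit(f"network_{cond}_edges.tsv", nets[cond].to_frame())
                emit(
                    f"network_{cond}_counts.tsv",
                    nets[cond].count_matrix().reset_index(names="source"),
                )

        if "diff" in cfg.stages:
            stage = "diff"
            diff = nw.diff_networks(
                nets[cfg.conditions[0]], nets[cfg.conditions[1]], calls, calls
            )
            emit("diff_network.tsv", diff.table)

        if "spatial" in cfg.stages:
            stage = "spatial"
            tables = {}
            for cond in cfg.conditions:
                per_cond = []
                for ct in sorted(m.cell_meta["cell_type"].unique()):
                    per_cond.append(
                        sa.screen_genes(
                            m, cond, ct, k=cfg.knn_k, method=cfg.moran_method,
                            n_perm=cfg.n_perm, seed=cfg.seed, min_frac=cfg.min_frac,
                            alpha=cfg.alpha,
                        )
                    )
                import pandas as pd

                tables[cond] = pd.concat(per_cond, ignore_index=True)
                emit(f"moran_{cond}.tsv", tables[cond])
            selections = []
            for ct in sorted(m.cell_meta["cell_type"].unique()):
                a = tables[cfg.conditions[0]]
                b = tables[cfg.conditions[1]]
                selections.append(
                    sa.select_spatial_degs(
                        a[a["cell_type"] == ct], b[b["cell_type"] == ct],
                        i_threshold=cfg.moran_i_threshold,
                        delta_threshold=cfg.delta_i_threshold,
                    )
                )
            import pandas as pd

            emit("spatial_selection.tsv", pd.concat(selections, ignore_index=True))

        if "de" in cfg.stages:
            stage = "de"
            emit(
                "wald_de.tsv",
                demod.de_scan(
                    m, family=cfg.de_family, alpha=cfg.alpha,
                    condition_levels=cfg.conditions,
                ),
            )

        if "enrich" in cfg.stages:
            stage = "enrich"
            if not cfg.annotation_gmt:
                raise ValueError("enrich stage needs annotation_gmt")
            ann = en.load_gmt(cfg.annotation_gmt)
            for cond, net in nets.items():
                emit(
                    f"term_counts_{cond}.tsv",
                    en.count_term_occurrences(net, ann, role=cfg.enrich_role),
                )
    except Exception as exc:
        marker = os.path.join(cfg.output_dir, "FAILED")
        with open(marker, "w") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "thresholds": thresholds_used,
        "stages": list(cfg.stages),
        "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
    }
    manifest_path = os.path.join(cfg.output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
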