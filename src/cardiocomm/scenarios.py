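"""Canonical simulation scenarios used by the analysis drivers and tests.

Each builder fixes the study conditions for one pipeline stage —
sample sizes, planted effect sizes, catalog composition — and takes only
a seed.  The communication scenario mirrors the biology of interest:
ECM ligands (collagens, fibronectin, laminin...) signaling to the
integrin receptor ITGB1, with dendritic cells gaining ITGB1 expression
in the disease condition, plus generic pairs whose expression is
planted at detection fractions well away from the 20% call threshold
(0.05 vs 0.35) so binomial noise cannot flip a call at 600 cells per
group.
"""

from __future__ import annotations

import numpy as np

from .catalog import LRCatalog
from .simulate import PlantedFraction, PlantedEffect, PlantedSpatial, SimConfig

__all__ = [
    "communication_scenario",
    "spatial_scenario",
    "null_de_scenario",
    "planted_de_scenario",
    "ITGB1_LIGANDS",
]

#: ECM ligands with documented ITGB1 cognate interactions
ITGB1_LIGANDS = (
    "COL1A2", "COL3A1", "COL4A1", "COL6A1", "COL6A2",
    "COL6A3", "FN1", "LAMA2", "LGALS1", "LUM",
)

LOW_FRACTION = 0.05   # safely below the 20% expression-call threshold
HIGH_FRACTION = 0.35  # safely above it


def communication_scenario(seed: int) -> tuple[SimConfig, LRCatalog]:
    """4 cell types x 2 conditions, 600 cells/group, 300 genes, 50-pair catalog.

    Every catalog gene gets a planted detection fraction in
    {0.05, 0.35} per (cell type, condition).  Fixed plantings encode the
    disease narrative: dendritic cells express ITGB1 at 5% in Normal and
    35% in HCM (a receptor gain), while the ECM ligands stay expressed
    in fibroblast/smooth-muscle/pericyte sources under both conditions.
    Generic pairs are assigned expressed/silent states at random, with
    the HCM condition biased toward silent so that overall communication
    drops in HCM, mirroring the reduced-network phenotype.
    """
    rng = np.random.default_rng(seed)
    cell_types = ("fibroblast", "dendritic", "smooth_muscle", "pericyte")
    conditions = ("Normal", "HCM")

    pairs = [(lig, "ITGB1") for lig in ITGB1_LIGANDS]
    generic_ligands = [f"LIG{i:02d}" for i in range(1, 41)]
    generic_receptors = [f"REC{i:02d}" for i in range(1, 41)]
    pairs += list(zip(generic_ligands, generic_receptors))
    catalog = LRCatalog.from_pairs(pairs, source="synthetic-50")

    catalog_genes = sorted(catalog.genes)
    n_genes = 300
    fillers = [f"G{i + 1:04d}" for i in range(n_genes - len(catalog_genes))]
    gene_names = tuple(catalog_genes + fillers)

    planted: list[PlantedFraction] = []
    # ITGB1 receptor: silent in Normal dendritic cells, expressed in HCM ones.
    planted.append(PlantedFraction("ITGB1", "dendritic", "Normal", LOW_FRACTION))
    planted.append(PlantedFraction("ITGB1", "dendritic", "HCM", HIGH_FRACTION))
    for group in ("fibroblast", "smooth_muscle", "pericyte"):
        for cond in conditions:
            planted.append(PlantedFraction("ITGB1", group, cond, HIGH_FRACTION))
            for lig in ITGB1_LIGANDS:
                planted.append(PlantedFraction(lig, group, cond, HIGH_FRACTION))
    for cond in conditions:
        for lig in ITGB1_LIGANDS:
            planted.append(PlantedFraction(lig, "dendritic", cond, LOW_FRACTION))
    # Generic pairs: random expressed/silent states, HCM biased toward silent.
    for gene in generic_ligands + generic_receptors:
        for group in cell_types:
            normal_on = rng.random() < 0.5
            hcm_on = rng.random() < 0.3
            planted.append(
                PlantedFraction(gene, group, "Normal",
                                HIGH_FRACTION if normal_on else LOW_FRACTION)
            )
            planted.append(
                PlantedFraction(gene, group, "HCM",
                                HIGH_FRACTION if hcm_on else LOW_FRACTION)
            )
    cfg = SimConfig(
        n_cell_types=len(cell_types),
        cells_per_type_per_condition=600,
        n_genes=n_genes,
        cell_types=cell_types,
        gene_names=gene_names,
        conditions=conditions,
        planted_lr=planted,
        seed=seed,
    )
    return cfg, catalog


def spatial_scenario(
    seed: int, n_null_genes: int = 1000, n_spatial_genes: int = 10, n_cells: int = 600
) -> SimConfig:
    """One cell type: null genes plus focal (Gaussian-bump) spatial genes.

    Spatial genes are planted in the HCM condition only, centered on the
    cell type's embedding blob with a decay length matching the blob
    spread and a strong amplitude, producing pronounced focal expression
    (Moran's I well above the 0.1 selection threshold); in Normal cells
    they stay flat at background level, so they pass the screen in a
    single condition.
    """
    n_genes = n_null_genes + n_spatial_genes
    gene_names = tuple(
        [f"SPAT{i:02d}" for i in range(1, n_spatial_genes + 1)]
        + [f"NULL{i:04d}" for i in range(1, n_null_genes + 1)]
    )
    cell_types = ("cardiomyocyte",)
    # blob center for a single cell type sits at (radius, 0)
    focus = (10.0, 0.0)
    spatial = [
        PlantedSpatial(f"SPAT{i:02d}", "cardiomyocyte", "HCM",
                       focus=focus, decay=1.0, amplitude=8.0)
        for i in range(1, n_spatial_genes + 1)
    ]
    return SimConfig(
        n_cell_types=1,
        cells_per_type_per_condition=n_cells,
        n_genes=n_genes,
        cell_types=cell_types,
        gene_names=gene_names,
        baseline_mean=1.0,
        planted_spatial=spatial,
        seed=seed,
    )


def null_de_scenario(seed: int, n_genes: int = 10000, n_cells_per_condition: int = 200) -> SimConfig:
    """Poisson counts, one cell type, no condition effect anywhere."""
    return SimConfig(
        n_cell_types=1,
        cells_per_type_per_condition=n_cells_per_condition,
        n_genes=n_genes,
        cell_types=("cardiomyocyte",),
        nb_dispersion=None,  # Poisson
        baseline_mean=2.0,
        seed=seed,
    )


def planted_de_scenario(
    seed: int, n_genes: int = 2000, n_planted: int = 20, log_fold_change: float = np.log(4.0)
) -> SimConfig:
    """Poisson counts with a 4-fold condition effect in a few genes."""
    gene_names = tuple(f"G{i + 1:04d}" for i in range(n_genes))
    planted = [
        PlantedEffect(gene_names[i], "cardiomyocyte", log_fold_change)
        for i in range(n_planted)
    ]
    return SimConfig(
        n_cell_types=1,
        cells_per_type_per_condition=400,
        n_genes=n_genes,
        cell_types=("cardiomyocyte",),
        gene_names=gene_names,
        nb_dispersion=None,
        baseline_mean=1.0,
        planted_de=planted,
        seed=seed,
    )
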