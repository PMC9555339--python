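# cardiocomm

Analysis toolkit for single-nucleus RNA-seq studies of intercellular
communication in heart tissue, built around the comparison of a disease
condition (nonobstructive hypertrophic cardiomyopathy, HCM) with normal
donor tissue. It implements the computational chain from a raw nuclei ×
genes count matrix to condition-resolved cell-cell communication
networks, spatially variable gene screens and differential-expression
scans — with a synthetic-data generator that plants known truth so every
stage can be validated end to end.

## What it computes

Given counts with per-nucleus condition, cell type, cluster and a 2D
embedding:

- **QC filtering** — keep genes detected in ≥ 3 nuclei; keep nuclei with
  200–2000 detected genes (ambient-RNA droplets below, doublets above;
  both bounds inclusive).
- **L-R catalogs** — load, normalize and merge ligand-receptor pair
  lists; deduplication is by the ordered (ligand, receptor) symbol pair.
- **Communication networks** — a gene is *expressed* in a cell group
  when detected (count > 0) in ≥ 20% of the group's cells. For each
  condition, pair (L, R) sits on directed edge s→t iff L is expressed in
  s, R in t and (L, R) is in the catalog; edge weight is the number of
  unique pairs. Conditions are compared edge-by-edge, and every gained or
  lost pair is attributed to the side whose call flipped
  (ligand / receptor / both) — e.g. "dendritic cells gained the ITGB1
  receptor" becomes a derived, testable statement.
- **Spatial screen** — Moran's I,
  `I = (N/W) · Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)²`,
  over a symmetrized kNN graph on the embedding, per (condition, cell
  type); analytic-z or permutation p-values, BH adjustment; a gene passes
  at I > 0, adjusted p ≤ 0.05, detection ≥ 1%. A conservative
  cross-condition selection keeps single-condition genes at I > 0.1 and
  both-condition genes at |ΔI| > 0.1.
- **Differential expression** — per gene, log-link GLM
  `log E[yᵢ] = β₀ + βₜ·xₜ` with xₜ the condition indicator (or
  pseudotime); Wald test on βₜ, BH within stratum, significant at
  adjusted p ≤ 0.05.
- **Enrichment** — per-term ligand/receptor pair-instance counts over a
  network, and upper-tail hypergeometric over-representation against an
  explicit universe (GMT annotations).
- **Simulation** — negative-binomial counts with planted detection
  fractions (hit exactly by inverting the NB zero probability), planted
  fold changes and planted focal spatial patterns, plus the derived
  truth they imply.

## Worked example

The numbered scripts under `analysis/` are the narrative: simulate a
4-cell-type, two-condition cohort (600 nuclei per group, 50-pair
catalog, detection fractions planted at 5% or 35%), then run each stage.

```sh
python analysis/01_simulate_cohort.py
python analysis/03_communication_networks.py
```

prints (abridged):

```
Normal: 232 expressed L-R pair instances
  planted-truth edge sets recovered exactly: True
HCM: 184 expressed L-R pair instances
  planted-truth edge sets recovered exactly: True

differential network: 76 gained, 124 lost pair instances (matches derived truth: True)
30 of the dendritic gains are ITGB1-mediated and all are attributed to the receptor side: True
```

Communication drops overall in the disease condition while dendritic
cells gain ECM-ligand→ITGB1 edges — the recovered attribution matches
the planted receptor gain exactly. `analysis/04_spatial_screen.py`
shows the Moran's I screen finding 0 of 1000 unstructured genes and all
10 planted focal genes; `analysis/05_differential_expression.py` shows
the Wald scan calibrated on a 10,000-gene null (raw p ≤ 0.05 rate
0.0494, 0 BH-significant) with full recovery of 20 planted 4-fold
effects. Small output tables land under `results/`.

A `cardiocomm` CLI mirrors the library
(`simulate`, `qc`, `network`, `diff`, `spatial`, `de`, `enrich`,
`run-all`); see `cardiocomm --help`.

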