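# Methods

## Scope and data model

The package operates on a nuclei × genes matrix of nonnegative integer
UMI counts with aligned per-nucleus metadata: a two-level condition
label (Normal vs HCM by default), a cell type, a cluster, a 2D embedding
(UMAP-like coordinates) and an optional pseudotime. Upstream steps —
alignment, integration, clustering, embedding computation, cell-type
assignment, trajectory learning — are inputs, not computations performed
here.

## QC filtering

"Expressed"/"detected" throughout means count > 0. The gene filter keeps
genes detected in at least `min_nuclei` nuclei (default 3); the nucleus
filter keeps nuclei whose detected-gene count lies in
`[min_genes, max_genes]` (default 200–2000, both inclusive: the excluded
sets are "fewer than 200" and "more than 2000"). Too few detected genes
indicates an ambient-RNA droplet, too many a doublet. The pipeline order
is fixed as genes-then-nuclei; the converse can differ because gene
removal lowers detected-gene counts, and fixing one order makes runs
deterministic. Each filter is idempotent and never mutates retained
counts. With a `batch_key`, the gene filter is applied within each batch
and a gene is kept if it passes in any one — the behaviour obtained by
filtering per-sample datasets and uniting them on integration; the
default is global.

## Ligand-receptor catalogs

A catalog is a set of ordered (ligand, receptor) gene-symbol pairs.
Symbols are normalized by uppercasing and whitespace-stripping before
deduplication; direction is preserved ((A,B) ≠ (B,A)) because the
ligand and receptor roles are semantically distinct. Merging is set
union with per-pair source provenance; multi-subunit receptor complexes
are kept as whatever single symbol a source uses (no expansion), since
the downstream analysis treats single genes (e.g. ITGB1) as receptors.
Published human catalogs of 2557 and 3398 pairs merge to 3627 unique
pairs under such normalization; exact reproduction of any published
union depends on the source files and their symbol conventions, so the
catalog layer takes arbitrary CSV/TSV inputs rather than pinning a
specific pair list.

## Expression calls and communication networks

A gene is called expressed in a (cell type, condition) group when its
detection fraction is ≥ 20% of the group's cells (inclusive threshold,
exposed as a flag). Fractions are computed over cells pooled across
samples within a condition — the simplest reading; per-sample
aggregation is a possible refinement. For each condition a directed
multigraph over cell groups is built: pair (L,R) lies on edge s→t
exactly when L is expressed in s, R in t, and (L,R) is in the catalog.
Self-loops encode autocrine signaling. Edge weight is the count of
unique pairs, never multiplicity. Raising the threshold can only remove
calls and edges (monotonicity, property-tested), and summed per-node
broadcast totals, receive totals and the network total agree by
construction.

Two conditions are compared per directed edge: gained = in B not A,
lost = in A not B. Each changed pair gets exactly one attribution tag.
For a gain, the side(s) not expressed under A determine the tag
(receptor-gained / ligand-gained / both-gained); losses are symmetric
with the roles of A and B swapped. A narrative statement such as
"target cells gained receptor X" is thus recomputable from the two
call tables. The "both-" tags complete the taxonomy symmetrically for
simultaneous flips.

## Moran's I spatial screen

The statistic is the standard
I = (N/W)·Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)², undefined (NaN) for
constant x. Weights come from a k-nearest-neighbor graph on the 2D
embedding (Euclidean, k = 15 by default), symmetrized by union, binary,
then row-standardized; the diagonal is zero. k and the weighting are
conventional defaults exposed as flags — no canonical choice exists for
this graph, and the screen's conclusions on well-separated signals are
insensitive to k in the 10–30 range.

Expression is log1p of library-size-normalized counts (size factor =
total counts / median total), so sequencing depth does not masquerade as
spatial structure; the transformation is optional.

Significance is one-sided for positive autocorrelation, matching the
requirement that selected genes have positive I. Two tests are
provided:

* `analytic_z`: E[I] = −1/(N−1) and the normality-assumption variance
  Var(I) = (N²S₁ − NS₂ + 3W²)/(W²(N²−1)) − E[I]², with S₁ = ½Σ(wᵢⱼ+wⱼᵢ)²
  and S₂ = Σᵢ(wᵢ·+w·ᵢ)².
* `permutation`: p = (1 + #{I_perm ≥ I_obs})/(1 + n_perm).

The two tests have complementary failure modes, and the package uses
each where it is strong. The permutation test is exactly calibrated for
any expression distribution, so it is the right tool for null
false-positive control; but its p-values cannot go below
1/(n_perm+1), so with 199 permutations no gene can survive BH at
α = 0.05 across ~1000 genes (0.005·m/k ≫ 0.05 for a handful of true
positives) — recovery power at screen scale requires either thousands of
permutations or the analytic test. The analytic test has unbounded
resolution and near-exact calibration for strong signals, but its
normality-assumption variance is slightly anticonservative for the
skewed distributions typical of sparse counts (a few null false
positives per thousand genes can appear). Validation therefore runs the
null calibration with permutations and the planted-recovery check with
the analytic test; real-data users wanting both should raise `n_perm`.
Within a stratum, one permutation index matrix is shared across genes:
each gene's p-value is marginally exact, and only cross-gene dependence
(tolerated by BH) is introduced; this keeps the screen a single
vectorized pass.

The per-stratum screen flag is (I > 0) ∧ (BH-adjusted p ≤ 0.05) ∧
(detected fraction ≥ 1%). The conservative cross-condition selection
follows: genes available in a single condition are kept when I > 0.1
there; genes available in both are kept when |I_Normal − I_HCM| > 0.1.
"Available" defaults to passing the screen in exactly one condition; a
`availability="computed"` mode interprets it as "I was computable at
all", since the phrase is genuinely ambiguous. No automatic
increased/decreased direction call is attempted — published direction
labels of this kind derive from visual inspection; comparing mean
expression between conditions is an available but clearly separate
extension.

## GLM/Wald differential expression

Per gene, log E[yᵢ] = β₀ + βₜxₜ, with xₜ the condition indicator
(0 = Normal, 1 = HCM) by default and pseudotime selectable as the
covariate. The Wald statistic z = βₜ/se(βₜ) is referred to the standard
normal, two-sided; BH adjustment is applied within each stratum (cell
type or cluster), and significance means adjusted p ≤ 0.05. Library-size
offsets default off (flag-enabled), matching the plain form of the model.

For the Poisson family on a binary design without offset the MLE is
closed-form — β₀ = log ȳ₀, βₜ = log(ȳ₁/ȳ₀),
se(βₜ) = √(1/Σy₀ + 1/Σy₁) — and is used directly (it is the exact IRLS
fixed point and makes 10⁴-gene scans take seconds). General designs go
through statsmodels IRLS. The default family is negative binomial with
a method-of-moments dispersion estimated from a Poisson pilot fit,
falling back to Poisson when no overdispersion is detected; snRNA-seq
counts are typically overdispersed and Poisson standard errors would be
anticonservative there. Genes with all-zero counts in a stratum are
excluded before fitting; a group with zero total counts makes the
log-mean diverge and the fit is flagged degenerate (infinite se,
excluded from testing). Strata containing a single condition are skipped
with a warning.

## Enrichment

Term counts: for each annotation term, the count of pair instances
(source, target, pair) whose ligand (or receptor) is annotated with the
term, optionally split by the broadcasting/receiving group; a flag
counts unique genes instead. The pair-instance unit means a ligand
reused on many edges counts once per edge, which is what per-cell-type
network panels require.

Over-representation: upper-tail hypergeometric P(X ≥ k) with
X ~ Hypergeom(N, K, n), BH across terms. The universe is a required
argument — all genes and expressed genes give different answers and the
choice must be the caller's. Annotations are read from GMT files assumed
pre-propagated; no ontology-graph closure is done, keeping results
independent of ontology releases.

## Synthetic data and planted truth

Counts are negative binomial with a dataset-wide dispersion r
(Var = μ + μ²/r; `nb_dispersion=None` selects Poisson), baseline mean
0.5 per gene. Planted detection fractions are hit by inverting the NB
zero probability, μ = r((1−f)^(−1/r) − 1), which keeps the count
marginal coherent (no post-hoc zero inflation). Embeddings are Gaussian
blobs per cell type (sd 1.0, centers on a circle of radius 10) —
generated, not learned, because the artifact tests the spatial
statistics, not manifold learning. Spatial genes get mean
background + amplitude·exp(−d²/decay²) from a focus point; DE genes get
mean × exp(LFC) in the disease condition of their stratum. The derived
truth (expected calls, networks, differential network, spatial and DE
gene lists) is computed from the configuration alone, with expected
calls fed through the same network-construction rules as real data.

Fixed study conditions used by the analysis drivers and validation:

* communication: 4 cell types × 2 conditions, 600 nuclei per group,
  300 genes, a 50-pair catalog (10 ECM-ligand→ITGB1 pairs plus 40
  generic), planted fractions ∈ {0.05, 0.35}. The 0.15 margin from the
  0.20 threshold is ≈ 7.7 binomial SDs at n = 600, so recovery is exact
  with overwhelming probability; dendritic cells carry the planted
  ITGB1 receptor gain and the HCM condition is biased toward silent
  plantings so total communication drops in disease.
* spatial: one cell type, 600 nuclei per condition, 1000 unstructured
  genes + 10 focal genes (amplitude 8, decay 1.0, HCM only; realized
  Moran's I ≈ 0.44–0.51), 199 permutations for the null calibration.
* DE null: 10,000 Poisson genes, 200 nuclei per condition, mean 2;
  DE planted: 20 four-fold effects among 2000 genes, 400 nuclei per
  condition.

What the generator does **not** emulate: batch effects beyond a label,
ambient RNA, doublets, realistic cluster manifold geometry, gene-gene
correlation, per-gene dispersion variation. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated statistical model, not performance on real tissue, where
detection fractions sit near thresholds and embeddings carry structure
the blobs do not.

## Numerical choices and edge cases

Constant expression vectors make Moran's I undefined (NaN, never
passing). Strata smaller than k+1 cells are skipped with a warning.
kNN ties are broken by node index. Permutation p-values use the
add-one rule and a 1e-12 comparison slack against floating-point ties.
BH propagates NaN inputs without letting them affect ranking. All
tabular outputs are deterministically sorted and runs are reproducible
byte-for-byte from (config, seed); the pipeline manifest records a
SHA-256 per artifact.

## Known limitations

Expression-call networks encode *potential* communication: they use
co-expression only, not spatial position or cell-type boundaries.
The per-condition pooling of cells ignores donor-level variability
(no mixed-effects layer). The NB dispersion is global rather than
per-gene. The analytic Moran variance assumes normality; see above for
when to prefer permutations.
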