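"""Moran's I spatial screen: null calibration and planted-gene recovery.

One cardiomyocyte-like stratum per condition: 1000 spatially unstructured
genes plus 10 genes planted with a focal (Gaussian-bump) pattern in the
HCM condition only.  The permutation screen (199 permutations) should
find nothing among the nulls after BH; the analytic screen plus the
conservative cross-condition rules (single-condition I > 0.1, or
|dI| > 0.1 when available in both) should select exactly the planted
genes.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from cardiocomm.scenarios import spatial_scenario
from cardiocomm.simulate import generate_dataset
from cardiocomm.spatial import screen_genes, select_spatial_degs

SEED = 20220819
ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

cfg = spatial_scenario(SEED)
matrix, truth = generate_dataset(cfg)
planted = truth.spatial_genes[("cardiomyocyte", "HCM")]

null_tab = screen_genes(
    matrix, "Normal", "cardiomyocyte", method="permutation", n_perm=199, seed=SEED
)
nulls = null_tab[null_tab["gene"].str.startswith("NULL")]
print(f"null calibration (permutation, 199 perms): "
      f"{int(nulls['passes'].sum())} of {len(nulls)} unstructured genes "
      f"BH-significant")

tab_n = screen_genes(matrix, "Normal", "cardiomyocyte", method="analytic_z")
tab_h = screen_genes(matrix, "HCM", "cardiomyocyte", method="analytic_z")
sel = select_spatial_degs(tab_n, tab_h)
sel.to_csv(RESULTS / "spatial_selection.tsv", sep="\t", index=False)

hits = tab_h[tab_h["gene"].isin(planted)]
print(f"planted focal genes: Moran's I in "
      f"[{hits['I'].min():.3f}, {hits['I'].max():.3f}], all pass screen: "
      f"{bool(hits['passes'].all())}")
print(f"cross-condition selection: {sorted(sel['gene'])}")
print(f"exactly the 10 planted genes selected: {set(sel['gene']) == set(planted)}")
print("(all by the single-condition rule — the genes are flat in Normal cells)")
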