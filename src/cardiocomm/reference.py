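"""Packaged reference tables.

``hcm_spatial_reference_genes.tsv`` lists the 41 genes reported to show
pronounced spatial-expression differences between Normal and
nonobstructive-HCM heart tissue, with the affected cell group(s) and
the direction of the change in disease.  It is shipped as a small
fixture for demonstrations and as a ready-made query set for the
enrichment machinery.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_spatial_reference_genes"]


def load_spatial_reference_genes() -> pd.DataFrame:
    """Reference spatially differential genes (gene, cell group(s), direction)."""
    ref = resources.files("cardiocomm.data") / "hcm_spatial_reference_genes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
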