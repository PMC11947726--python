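"""Wilcoxon rank-sum differential expression and hypergeometric enrichment.

DEGs between plasma and T/ILC/NK cells at the study thresholds (BH-adjusted
p < 0.05, |log2FC| > 1.5), then over-representation of marker panels among
the plasma-side DEGs.
"""

import scanpy as sc

from jejumap import gene_sets
from jejumap.differential import hypergeom_enrich, wilcoxon_deg
from jejumap.pipeline import scaled_default_spec
from jejumap.synth_atlas import simulate_atlas

adata, truth = simulate_atlas(scaled_default_spec(2000, seed=5,
                                                  doublet_rate=0.0))
sc.pp.normalize_total(adata, target_sum=1e4)
sc.pp.log1p(adata)

mask_plasma = (truth["lineage"] == "plasma").to_numpy()
mask_t = (truth["lineage"] == "T/ILC/NK").to_numpy()
table = wilcoxon_deg(adata, mask_plasma, mask_t)
up = table[table["is_deg"] & (table["direction"] == "up")]
print(f"plasma vs T/ILC/NK: {int(table['is_deg'].sum())} DEGs, "
      f"{len(up)} up in plasma")
print("\ntop plasma-side DEGs by log2FC:")
print(up.nlargest(8, "log2fc")[["log2fc", "adj_p_value"]].round(3).to_string())

sets = {name: genes for name, genes in gene_sets.LINEAGE_MARKERS.items()}
enr = hypergeom_enrich(list(up.index), sets, list(adata.var_names))
print("\nmarker-panel enrichment among plasma-up DEGs:")
print(enr[["gene_set", "overlap", "set_size", "p_value", "adj_p_value",
           "significant"]].round(4).to_string(index=False))
# The plasma panel (JCHAIN, MZB1) is significantly enriched — the planted
# 8-fold marker boost drives both the DEG calls and the enrichment. The B
# panel can co-enrich because plasma Type 2 cells carry the B-receptor
# components CD79A/CD79B, as real plasma compartments do.
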