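"""Normalization, dimensionality reduction, Leiden clustering, marker-panel
annotation, cell-cycle phasing and the cross-breed cell-type dendrogram.

Annotation is two-tier: major lineages on all cells first, then the
T/ILC/NK subtype panel within the T/ILC/NK compartment only. Each cluster
receives the label whose marker panel has the highest mean z-scored
log-normalized expression over the cluster; cells inherit their cluster's
label.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist
from skbio import TreeNode

from . import gene_sets
from .scoring import GeneSet, module_score

TARGET_SUM = 1e4  # depth-normalization target counts per cell


@dataclass
class ClusteringResult:
    labels: pd.Series            # per-cell cluster id (categorical codes as str)
    resolution: float
    n_neighbors: int

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()


def preprocess(adata: AnnData, n_hvg: int = 2000, n_pcs: int = 50,
               center_by: str | None = None, seed: int = 0) -> AnnData:
    """Depth-normalize, log1p, select HVGs, scale, PCA.

    Returns a new AnnData whose ``X`` holds log-normalized expression for
    all genes (for scoring and DE) and whose ``obsm["X_pca"]`` holds the
    HVG-based embedding. ``center_by`` optionally mean-centers the embedding
    per batch column (a light substitute for cross-library integration on
    single-batch data).
    """
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=TARGET_SUM)
    sc.pp.log1p(out)
    n_hvg_eff = min(n_hvg, out.n_vars)
    if n_hvg_eff < n_hvg:
        warnings.warn(f"n_hvg clamped to gene count ({out.n_vars})")
    sc.pp.highly_variable_genes(out, n_top_genes=n_hvg_eff, flavor="seurat")
    hvg = out[:, out.var["highly_variable"]].copy()
    sc.pp.scale(hvg, max_value=10)
    n_comp = min(n_pcs, hvg.n_vars - 1, hvg.n_obs - 1)
    sc.tl.pca(hvg, n_comps=n_comp, svd_solver="arpack", random_state=seed)
    emb = hvg.obsm["X_pca"]
    if center_by is not None:
        emb = emb.copy()
        for batch in out.obs[center_by].unique():
            mask = (out.obs[center_by] == batch).to_numpy()
            emb[mask] -= emb[mask].mean(axis=0)
    out.obsm["X_pca"] = emb
    return out


def cluster_cells(adata: AnnData, k: int = 15, resolution: float = 1.0,
                  seed: int = 0) -> ClusteringResult:
    """Leiden community detection on a nearest-neighbor graph of the embedding."""
    if k >= adata.n_obs:
        raise ValueError(f"k={k} must be smaller than cell count {adata.n_obs}")
    sc.pp.neighbors(adata, n_neighbors=k, use_rep="X_pca", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     key_added="cluster")
    labels = adata.obs["cluster"].astype(str)
    return ClusteringResult(labels=labels, resolution=resolution, n_neighbors=k)


def _zscore_genes(adata: AnnData, genes: list[str]) -> pd.DataFrame:
    """Dense z-scored log-normalized expression for the requested genes."""
    present = [g for g in genes if g in adata.var_names]
    sub = adata[:, present].X
    dense = sub.toarray() if sp.issparse(sub) else np.asarray(sub)
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((dense - mu) / sd, index=adata.obs_names, columns=present)


def annotate_clusters(adata: AnnData, clusters: pd.Series,
                      panel: dict[str, list[str]]) -> pd.Series:
    """Assign each cluster the panel label with the highest mean marker z-score.

    Missing panel genes are warned and skipped; a label whose genes are all
    absent is dropped. Ties break by panel order. Raises if no panel gene is
    present at all.
    """
    universe = set(adata.var_names)
    resolved: dict[str, list[str]] = {}
    for label, genes in panel.items():
        present = [g2 for g in genes
                   if (g2 := gene_sets.resolve_symbol(g, universe)) in universe]
        missing = len(genes) - len(present)
        if missing:
            warnings.warn(f"{missing} marker(s) for {label!r} absent; skipped")
        if present:
            resolved[label] = present
    if not resolved:
        raise ValueError("no panel gene present in the expression matrix")

    all_genes = sorted({g for gs in resolved.values() for g in gs})
    z = _zscore_genes(adata, all_genes)
    labels_in_order = list(resolved)
    cluster_ids = pd.Index(clusters.unique())
    cluster_scores = pd.DataFrame(index=cluster_ids, columns=labels_in_order,
                                  dtype=float)
    for cid in cluster_ids:
        mask = (clusters == cid).to_numpy()
        for label in labels_in_order:
            cluster_scores.loc[cid, label] = \
                z.loc[mask, resolved[label]].to_numpy().mean()
    # argmax with first-in-panel tie-break
    best = cluster_scores.to_numpy().argmax(axis=1)
    mapping = {cid: labels_in_order[j] for cid, j in zip(cluster_ids, best)}
    return clusters.map(mapping).rename("label")


def annotate_two_tier(adata: AnnData, clusters: pd.Series,
                      lineage_panel: dict[str, list[str]] | None = None,
                      subtype_panel: dict[str, list[str]] | None = None,
                      subtype_parent: str = "T/ILC/NK",
                      k: int = 15, resolution: float = 1.0,
                      seed: int = 0) -> pd.DataFrame:
    """Major-lineage annotation on all cells, then subtype annotation by
    re-clustering within the parent compartment.

    Returns a frame with ``lineage`` and ``subtype`` columns (subtype is NA
    outside the parent compartment).
    """
    lineage_panel = lineage_panel or gene_sets.LINEAGE_MARKERS
    subtype_panel = subtype_panel or gene_sets.T_SUBTYPE_MARKERS
    lineage = annotate_clusters(adata, clusters, lineage_panel)
    subtype = pd.Series(pd.NA, index=adata.obs_names, dtype=object,
                        name="subtype")
    mask = (lineage == subtype_parent).to_numpy()
    if mask.sum() > 2 * k:
        sub = adata[mask].copy()
        # re-embed the compartment on its own most variable genes: subtype
        # structure rides on far fewer genes than the whole-atlas HVG set
        X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X)
        n_hvg = min(500, sub.n_vars)
        top = np.argsort(X.var(axis=0))[-n_hvg:]
        Z = X[:, top]
        Z = (Z - Z.mean(axis=0)) / np.maximum(Z.std(axis=0), 1e-12)
        from sklearn.decomposition import PCA
        n_comp = min(50, Z.shape[1] - 1, Z.shape[0] - 1)
        sub.obsm["X_pca"] = PCA(n_components=n_comp,
                                random_state=seed).fit_transform(Z)
        sub_res = cluster_cells(sub, k=k, resolution=resolution, seed=seed)
        subtype.loc[sub.obs_names] = annotate_clusters(
            sub, sub_res.labels, subtype_panel).to_numpy()
    return pd.DataFrame({"lineage": lineage, "subtype": subtype})


# ---------------------------------------------------------------------------
# Cell cycle
# ---------------------------------------------------------------------------

def cell_cycle_phase(adata: AnnData,
                     s_genes: list[str] | None = None,
                     g2m_genes: list[str] | None = None,
                     seed: int = 0,
                     regress: bool = False,
                     n_bins: int = 25,
                     n_ctrl: int = 100
                     ) -> tuple[pd.DataFrame, AnnData | None]:
    """Score S and G2M gene sets and call the phase per cell.

    Phase is G1 iff both scores are <= 0, otherwise the argmax of (S, G2M) —
    cells lacking phase-marker signal are treated as resting. With
    ``regress=True`` also returns a copy of the expression with both scores
    residualized out of every gene by least squares.
    """
    s_genes = s_genes if s_genes is not None else gene_sets.S_PHASE_GENES
    g2m_genes = g2m_genes if g2m_genes is not None else gene_sets.G2M_PHASE_GENES
    universe = set(adata.var_names)
    if not (set(s_genes) & universe) and not (set(g2m_genes) & universe):
        raise ValueError("neither S nor G2M genes present")
    n_bins = min(n_bins, adata.n_vars)
    s_score = module_score(adata, GeneSet("S", s_genes), n_bins=n_bins,
                           n_ctrl=n_ctrl, seed=seed).scores
    g2m_score = module_score(adata, GeneSet("G2M", g2m_genes), n_bins=n_bins,
                             n_ctrl=n_ctrl, seed=seed + 1).scores
    phase = np.where((s_score <= 0) & (g2m_score <= 0), "G1",
                     np.where(s_score >= g2m_score, "S", "G2M"))
    result = pd.DataFrame({"s_score": s_score, "g2m_score": g2m_score,
                           "phase": phase}, index=adata.obs_names)
    residual = None
    if regress:
        residual = adata.copy()
        X = residual.X.toarray() if sp.issparse(residual.X) else \
            np.asarray(residual.X, dtype=float)
        design = np.column_stack([np.ones(adata.n_obs), s_score, g2m_score])
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        residual.X = X - design @ beta
    return result, residual


# ---------------------------------------------------------------------------
# Cross-group dendrogram
# ---------------------------------------------------------------------------

def celltype_dendrogram(adata: AnnData, groups: pd.Series,
                        use_hvg: bool = True) -> str:
    """Average-linkage dendrogram of (breed x cell type) mean profiles.

    Distance is correlation distance (1 - Pearson) between mean
    log-normalized HVG profiles; the tree is returned as a Newick string.
    """
    if use_hvg and "highly_variable" in adata.var.columns:
        sub = adata[:, adata.var["highly_variable"]]
    else:
        sub = adata
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X)
    names, profiles = [], []
    for name, idx in groups.groupby(groups).groups.items():
        rows = groups.index.get_indexer(idx)
        if len(rows) == 0:
            warnings.warn(f"group {name!r} has zero cells; dropped")
            continue
        names.append(str(name))
        profiles.append(X[rows].mean(axis=0))
    if len(names) < 2:
        raise ValueError("need at least 2 non-empty groups")
    P = np.vstack(profiles)
    dist = pdist(P, metric="correlation")
    Z = average(np.clip(dist, 0, None))
    tree = TreeNode.from_linkage_matrix(Z, names)
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
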