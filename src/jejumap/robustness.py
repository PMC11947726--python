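"""Cell-number and sequencing-depth downsampling with pseudobulk Pearson
agreement.

Validates that a dataset's expression structure survives reducing either
the number of cells per group (default 2,000) or the counts per cell
(defaults 8,172 and 6,300), by correlating log-CPM pseudobulk profiles of
the downsampled and original matrices per group, over replicates (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

DEPTH_TARGETS = (8172, 6300)  # average / median per-cell counts convention
N_REPLICATES = 5


@dataclass
class DownsampleReport:
    mode: str                       # "cells" or "depth"
    target: int
    correlations: pd.DataFrame      # columns: group, replicate, pearson_r, raw_r
    replicates: int = N_REPLICATES

    @property
    def min_r(self) -> float:
        return float(self.correlations["pearson_r"].min())


def subsample_cells(adata: AnnData, groups: pd.Series, n: int = 2000,
                    seed: int = 0) -> AnnData:
    """Uniform without-replacement sample of ``n`` cells per group."""
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for g in pd.unique(groups):
        idx = np.flatnonzero((groups == g).to_numpy())
        if idx.size < n:
            raise ValueError(f"group {g!r} has {idx.size} cells < n={n}")
        keep.append(rng.choice(idx, size=n, replace=False))
    order = np.sort(np.concatenate(keep))
    return adata[order].copy()


def downsample_counts(adata: AnnData, counts_per_cell: int,
                      seed: int = 0) -> AnnData:
    """Thin each cell to exactly ``counts_per_cell`` total counts.

    Cells above the target lose reads by a multivariate hypergeometric
    (without-replacement) draw over their gene counts, preserving per-gene
    expectations proportional to the originals; cells at or below the
    target are untouched.
    """
    if counts_per_cell < 1:
        raise ValueError("counts_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(adata.X).astype(np.int64)
    out = X.copy()
    totals = np.asarray(X.sum(axis=1)).ravel()
    for i in np.flatnonzero(totals > counts_per_cell):
        row = X.getrow(i)
        sampled = rng.multivariate_hypergeometric(row.data, counts_per_cell)
        out.data[out.indptr[i]:out.indptr[i + 1]] = sampled
    out.eliminate_zeros()
    result = adata.copy()
    result.X = sp.csr_matrix(out.astype(np.int32))
    return result


def _pseudobulk(adata: AnnData, groups: pd.Series) -> pd.DataFrame:
    X = sp.csr_matrix(adata.X)
    rows = {}
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        rows[g] = np.asarray(X[mask].sum(axis=0)).ravel()
    return pd.DataFrame(rows, index=adata.var_names).T


def _log_cpm(v: np.ndarray) -> np.ndarray:
    return np.log1p(v / v.sum() * 1e6)


def pseudobulk_correlation(original: AnnData, downsampled: AnnData,
                           groups_original: pd.Series,
                           groups_downsampled: pd.Series,
                           replicate: int = 0) -> pd.DataFrame:
    """Per-group Pearson r between log-CPM pseudobulk vectors.

    Also reports the correlation of the raw pseudobulk sums. Both matrices
    must share the gene universe; each group must be present in both.
    """
    if not original.var_names.equals(downsampled.var_names):
        raise ValueError("gene universes differ")
    pb_orig = _pseudobulk(original, groups_original)
    pb_down = _pseudobulk(downsampled, groups_downsampled)
    rows = []
    for g in pb_orig.index:
        if g not in pb_down.index:
            raise ValueError(f"group {g!r} absent from downsampled matrix")
        a, b = pb_orig.loc[g].to_numpy(), pb_down.loc[g].to_numpy()
        r_log = float(np.corrcoef(_log_cpm(a), _log_cpm(b))[0, 1])
        r_raw = float(np.corrcoef(a, b)[0, 1])
        rows.append((g, replicate, r_log, r_raw))
    return pd.DataFrame(rows, columns=["group", "replicate", "pearson_r",
                                       "raw_r"])


def downsampling_report(adata: AnnData, groups: pd.Series, mode: str = "cells",
                        target: int = 2000, replicates: int = N_REPLICATES,
                        seed: int = 0) -> DownsampleReport:
    """Run the full downsampling validation: ``replicates`` independent
    downsampled matrices, each correlated with the original per group."""
    if mode not in ("cells", "depth"):
        raise ValueError("mode must be 'cells' or 'depth'")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    frames = []
    for rep in range(replicates):
        rep_seed = seed + rep
        if mode == "cells":
            down = subsample_cells(adata, groups, n=target, seed=rep_seed)
            down_groups = groups.loc[down.obs_names]
        else:
            down = downsample_counts(adata, counts_per_cell=target,
                                     seed=rep_seed)
            down_groups = groups
        frames.append(pseudobulk_correlation(adata, down, groups, down_groups,
                                             replicate=rep))
    return DownsampleReport(mode=mode, target=target,
                            correlations=pd.concat(frames, ignore_index=True),
                            replicates=replicates)
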