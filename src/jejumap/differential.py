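"""Wilcoxon rank-sum differential expression, Benjamini–Hochberg adjustment
and hypergeometric over-representation testing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

LOG2FC_EPS = 1e-9


@dataclass
class DEGThresholds:
    max_adj_p: float = 0.05
    min_log2fc: float = 1.5
    #: apply the fold-change threshold on |log2FC| (two-sided) or signed.
    absolute: bool = True


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def wilcoxon_deg(adata: AnnData, group_a: np.ndarray, group_b: np.ndarray,
                 thresholds: DEGThresholds | None = None,
                 method: str = "auto") -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test of group A vs group B.

    Uses the tie-corrected normal approximation on log-normalized expression,
    vectorized over genes; with ``method="auto"`` tiny groups (both of at
    most 8 cells) switch to the exact rank-sum null. log2FC compares mean
    expm1-scale expression (A over B) with a small epsilon guarding empty
    genes. Returns a frame indexed by gene with the statistic, raw and
    BH-adjusted p-values, log2FC and a DEG flag at the given thresholds.

    ``group_a`` / ``group_b`` are boolean masks or integer indices over cells.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError("method must be 'auto', 'exact' or 'asymptotic'")
    thr = thresholds if thresholds is not None else DEGThresholds()
    A = _dense(adata[group_a].X)
    B = _dense(adata[group_b].X)
    n1, n2 = A.shape[0], B.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 cells")
    exact = method == "exact" or (method == "auto" and max(n1, n2) <= 8)

    combined = np.vstack([A, B])
    ranks = stats.rankdata(combined, axis=0)
    R1 = ranks[:n1].sum(axis=0)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction per gene
    tie_term = np.zeros(combined.shape[1])
    for j in range(combined.shape[1]):
        _, counts = np.unique(combined[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (U - mu) / sigma
    z[sigma == 0] = 0.0
    if exact:
        p = np.array([
            stats.mannwhitneyu(A[:, j], B[:, j], alternative="two-sided",
                               method="exact" if tie_term[j] == 0 else "asymptotic"
                               ).pvalue
            for j in range(combined.shape[1])
        ])
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)

    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + LOG2FC_EPS) / (mean_b + LOG2FC_EPS))
    adj = bh_adjust(p)
    fc_pass = (np.abs(log2fc) > thr.min_log2fc if thr.absolute
               else log2fc > thr.min_log2fc)
    table = pd.DataFrame({
        "statistic": U,
        "z": z,
        "p_value": p,
        "adj_p_value": adj,
        "log2fc": log2fc,
        "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "flat")),
        "is_deg": (adj < thr.max_adj_p) & fc_pass,
    }, index=adata.var_names)
    table.attrs["thresholds"] = thr
    return table


def hypergeom_enrich(gene_list: list[str],
                     gene_sets: dict[str, list[str]],
                     universe: list[str],
                     max_adj_p: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    ``gene_list`` must be a subset of ``universe``; sets are intersected with
    the universe before testing. BH adjustment across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hits = set(gene_list)
    if not hits:
        raise ValueError("empty gene list")
    if not hits <= uni:
        raise ValueError("gene_list must be a subset of universe")
    M, N = len(uni), len(hits)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & uni)
        k = len(set(members) & hits)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K > 0 else 1.0
        rows.append((name, k, K, N, M, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                        "list_size", "universe_size", "p_value"])
    table["adj_p_value"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["adj_p_value"] < max_adj_p
    return table
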