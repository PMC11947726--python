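"""10x-style MatrixMarket I/O and cell-level quality control.

Filters follow the atlas convention: remove doublet-like cells (simulated-
doublet kNN score at or above 0.25 by default), cells with mitochondrial
read fraction above 50%, and cells detecting fewer than 200 or more than
7,500 genes. Boundary semantics are strict: exactly 200 or 7,500 detected
genes and exactly 50% mito survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

MITO_PREFIX = "MT-"


@dataclass
class QCThresholds:
    doublet_cutoff: float = 0.25
    mito_max: float = 0.50
    min_genes: int = 200
    max_genes: int = 7500
    #: remove cells with score >= cutoff ("high") or <= cutoff ("low").
    doublet_direction: str = "high"

    def validate(self) -> None:
        if not (self.min_genes < self.max_genes):
            raise ValueError("min_genes must be < max_genes")
        if not (0 <= self.mito_max <= 1):
            raise ValueError("mito_max must be in [0, 1]")
        if not (0 <= self.doublet_cutoff <= 1):
            raise ValueError("doublet_cutoff must be in [0, 1]")
        if self.doublet_direction not in ("high", "low"):
            raise ValueError("doublet_direction must be 'high' or 'low'")


@dataclass
class QCReport:
    """Per-filter accounting; a cell failing several filters is attributed to
    the first failing filter in the order doublet -> mito -> min/max genes."""
    n_input: int
    removed: dict[str, int]
    n_survivors: int
    metrics: pd.DataFrame = field(repr=False)

    def balances(self) -> bool:
        return self.n_input == self.n_survivors + sum(self.removed.values())


# ---------------------------------------------------------------------------
# MTX triplet I/O
# ---------------------------------------------------------------------------

def write_10x_mtx(adata: AnnData, path: str | Path) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv (genes x cells on disk)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    if (X.data != np.round(X.data)).any():
        raise ValueError("counts must be integers")
    mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(X.T), field="integer")
    feats = pd.DataFrame({
        "gene_id": adata.var.get("gene_id", adata.var_names),
        "symbol": adata.var.get("symbol", adata.var_names),
    })
    feats.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    obs_cols = [c for c in ("library",) if c in adata.obs.columns]
    barcodes = pd.DataFrame({"barcode": adata.obs_names})
    for c in obs_cols:
        barcodes[c] = adata.obs[c].to_numpy()
    barcodes.to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def read_10x_mtx(path: str | Path, mito_prefix: str = MITO_PREFIX) -> AnnData:
    """Read an MTX triplet into cells x genes AnnData with a mito flag.

    Raises on dimension mismatch between the matrix and the feature/barcode
    tables, and on non-integer matrix entries.
    """
    path = Path(path)
    M = sp.csr_matrix(mmread(str(path / "matrix.mtx")))  # genes x cells
    if (M.data != np.round(M.data)).any():
        raise ValueError("matrix contains non-integer counts")
    feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
    if len(feats) != M.shape[0]:
        raise ValueError(
            f"features.tsv has {len(feats)} rows but matrix has {M.shape[0]} genes")
    if len(barcodes) != M.shape[1]:
        raise ValueError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix has {M.shape[1]} cells")
    symbols = feats.iloc[:, 1 if feats.shape[1] > 1 else 0].astype(str)
    var = pd.DataFrame({
        "gene_id": feats.iloc[:, 0].astype(str).to_numpy(),
        "symbol": symbols.to_numpy(),
        "mito": symbols.str.startswith(mito_prefix).to_numpy(),
    }, index=symbols.to_numpy())
    var.index = pd.Index(np.where(var.index.duplicated(keep=False),
                                  var["gene_id"], var.index))
    obs = pd.DataFrame(index=barcodes.iloc[:, 0].astype(str).to_numpy())
    if barcodes.shape[1] > 1:
        obs["library"] = barcodes.iloc[:, 1].to_numpy()
    return AnnData(X=sp.csr_matrix(M.T.astype(np.int32)), obs=obs, var=var)


# ---------------------------------------------------------------------------
# QC metrics and doublet score
# ---------------------------------------------------------------------------

def qc_metrics(adata: AnnData) -> pd.DataFrame:
    """Per-cell totals, detected genes and mitochondrial read fraction."""
    X = sp.csr_matrix(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    if "mito" in adata.var.columns:
        mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    else:
        mito_mask = adata.var_names.str.startswith(MITO_PREFIX).to_numpy()
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    return pd.DataFrame({"total_counts": total, "n_genes": n_genes,
                         "mito_frac": mito_frac}, index=adata.obs_names)


def doublet_score(adata: AnnData, k: int | None = None,
                  n_sim: int | None = None, n_pcs: int = 30,
                  expected_rate: float = 0.1, seed: int = 0) -> np.ndarray:
    """Simulated-doublet kNN score in [0, 1] per observed cell.

    Simulates ``n_sim`` artificial doublets by summing random cell pairs,
    co-embeds observed and simulated cells in PCA space of log-normalized
    counts, and converts each observed cell's simulated-neighbor fraction
    into a posterior doublet probability given the expected doublet rate,
    correcting for the simulated/observed ratio. A homogeneous population
    with no doublets therefore scores near ``expected_rate``.
    """
    n = adata.n_obs
    if n_sim is None:
        n_sim = n
    if k is None:
        k = max(5, int(round(0.5 * np.sqrt(n))))
    if n < 2 * k:
        raise ValueError(f"need at least 2*k={2 * k} cells, got {n}")
    X = sp.csr_matrix(adata.X).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("matrix contains all-zero cells")

    rng = np.random.default_rng(seed)
    pairs = np.stack([rng.integers(0, n, size=n_sim),
                      rng.integers(0, n, size=n_sim)], axis=1)
    same = pairs[:, 0] == pairs[:, 1]
    pairs[same, 1] = (pairs[same, 1] + 1) % n
    sim = X[pairs[:, 0]] + X[pairs[:, 1]]

    both = sp.vstack([X, sim], format="csr")
    depth = np.asarray(both.sum(axis=1)).ravel()
    norm = sp.diags(1e4 / depth) @ both
    norm.data = np.log1p(norm.data)
    pca = PCA(n_components=min(n_pcs, both.shape[1] - 1, both.shape[0] - 1),
              random_state=seed)
    emb = pca.fit_transform(norm.toarray())

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, nbr = nn.kneighbors(emb[:n])
    nbr = nbr[:, 1:]  # drop self
    frac_sim = (nbr >= n).mean(axis=1)

    r = n_sim / n
    rho = expected_rate
    # posterior P(doublet | neighborhood), Scrublet-style likelihood ratio
    lik = frac_sim / r
    score = lik * rho / (lik * rho + (1.0 - frac_sim) * (1.0 - rho))
    return np.clip(np.nan_to_num(score), 0.0, 1.0)


def qc_filter(adata: AnnData, thresholds: QCThresholds | None = None,
              scores: np.ndarray | None = None) -> tuple[AnnData, QCReport]:
    """Apply the doublet / mito / gene-count filters in the stated order.

    Returns the surviving cells with untouched counts and an accounting
    report. ``scores`` (per-cell doublet scores) may be omitted, in which
    case the doublet filter is skipped.
    """
    thr = thresholds if thresholds is not None else QCThresholds()
    thr.validate()
    metrics = qc_metrics(adata)
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape[0] != adata.n_obs:
            raise ValueError("scores not aligned to cells")
        metrics["doublet_score"] = scores

    n = adata.n_obs
    removed = {"doublet": 0, "mito": 0, "min_genes": 0, "max_genes": 0}
    assigned = np.zeros(n, dtype=bool)

    def _apply(name: str, fail: np.ndarray) -> None:
        new = fail & ~assigned
        removed[name] = int(new.sum())
        assigned[new] = True

    if scores is not None:
        if thr.doublet_direction == "high":
            _apply("doublet", scores >= thr.doublet_cutoff)
        else:
            _apply("doublet", scores <= thr.doublet_cutoff)
    _apply("mito", metrics["mito_frac"].to_numpy() > thr.mito_max)
    _apply("min_genes", metrics["n_genes"].to_numpy() < thr.min_genes)
    _apply("max_genes", metrics["n_genes"].to_numpy() > thr.max_genes)

    keep = ~assigned
    out = adata[keep].copy()
    report = QCReport(n_input=n, removed=removed,
                      n_survivors=int(keep.sum()), metrics=metrics)
    if not report.balances():
        warnings.warn("QC accounting does not balance")  # pragma: no cover
    return out, report
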