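"""Ordered-breed expression-pattern classification via fuzzy c-means.

Genes are summarized as standardized mean expression along the fixed
domestication order AWB -> JH -> DU, soft-clustered with Bezdek fuzzy
c-means (fuzzifier from the Schwämmle–Jensen estimate, cluster number
default 9, advisory Dmin table for choosing it), and classified into four
patterns by centroid shape intersected with DEG evidence:

    type1  increasing along AWB < JH < DU
    type2  JH-high (up-DEG in both JH vs AWB and JH vs DU)
    type3  JH-low  (down-DEG in both)
    type4  decreasing along AWB > JH > DU
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

BREED_ORDER = ("AWB", "JH", "DU")
MEMBERSHIP_MIN = 0.5


@dataclass
class FuzzyClustering:
    centroids: np.ndarray          # c x D
    membership: np.ndarray         # genes x c
    fuzzifier: float
    objective: float
    converged: bool
    genes: list[str]

    @property
    def hard_labels(self) -> np.ndarray:
        return self.membership.argmax(axis=1)


def breed_profile(adata: AnnData, breeds: pd.Series,
                  cell_subset: np.ndarray | None = None,
                  order: tuple[str, ...] = BREED_ORDER
                  ) -> pd.DataFrame:
    """Per-gene standardized mean log-normalized expression per breed.

    Rows are z-scored across the ordered conditions; zero-variance rows are
    dropped (their shape carries no information). Raises if a breed of the
    fixed order is missing from the subset.
    """
    if cell_subset is not None:
        adata = adata[cell_subset]
        breeds = breeds[adata.obs_names]
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    cols = []
    for b in order:
        mask = (breeds == b).to_numpy()
        if not mask.any():
            raise ValueError(f"breed {b!r} missing from the cell subset")
        cols.append(X[mask].mean(axis=0))
    M = np.column_stack(cols)
    sd = M.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} zero-variance gene(s) dropped")
    M = M[keep]
    Z = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
    return pd.DataFrame(Z, index=np.asarray(adata.var_names)[keep],
                        columns=list(order))


def estimate_fuzzifier(n_genes: int, n_conditions: int) -> float:
    """Empirical fuzzifier estimate m(N, D) for expression soft clustering.

    m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)
    """
    if n_genes < 2 or n_conditions < 2:
        raise ValueError("need n_genes >= 2 and n_conditions >= 2")
    N, D = float(n_genes), float(n_conditions)
    return (1.0
            + (1418.0 / N + 22.05) * D**-2
            + (12.33 / N + 0.243) * D**(-0.0406 * np.log(N) - 0.1134))


def fuzzy_cmeans(profiles: pd.DataFrame | np.ndarray, c: int = 9,
                 m: float | None = None, tol: float = 1e-6,
                 max_iter: int = 1000, seed: int = 0) -> FuzzyClustering:
    """Bezdek alternating-optimization fuzzy c-means with random membership
    initialization.

    Memberships: u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)) with Euclidean d;
    centroids: weighted means with weights u^m. Initial centroids are
    ``c`` distinct data points sampled at random (seeded). Iterates until
    the maximum membership change falls below ``tol``. The objective
    sum_ij u_ij^m d_ij^2 is non-increasing across iterations.
    """
    if isinstance(profiles, pd.DataFrame):
        genes = list(profiles.index)
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        genes = [str(i) for i in range(X.shape[0])]
    n = X.shape[0]
    if not (1 < c < n):
        raise ValueError(f"c={c} must be in (1, n_genes)")
    if m is None:
        m = estimate_fuzzifier(n, X.shape[1])
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")

    rng = np.random.default_rng(seed)
    # random membership init with tilt scaled so the centroid weights U^m
    # keep an O(1) spread at any fuzzifier: at small m this is the classic
    # random init and clusters separate; at large m memberships start and
    # stay near-flat, as the fuzzifier limit demands. (Centroid-on-data-point
    # inits instead create singular fixed points at large m.)
    U = rng.random((n, c)) ** (1.0 / m)
    U /= U.sum(axis=1, keepdims=True)
    exponent = 2.0 / (m - 1.0)

    def _memberships(cents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d2 = ((X[:, None, :] - cents[None, :, :])**2).sum(axis=2)
        zero_rows = (d2 < 1e-30).any(axis=1)
        with np.errstate(divide="ignore"):
            inv = np.where(d2 > 0, d2, 1.0) ** (-exponent / 2.0)
        U = inv / inv.sum(axis=1, keepdims=True)
        if zero_rows.any():
            # a point sitting on a centroid belongs to the coincident
            # cluster(s) outright (standard singularity convention)
            hit = d2[zero_rows] < 1e-30
            U[zero_rows] = hit / hit.sum(axis=1, keepdims=True)
        return U, d2

    converged = False
    objective = np.inf
    centroids = None
    for _ in range(max_iter):
        W = U**m
        centroids = (W.T @ X) / np.maximum(W.sum(axis=0)[:, None], 1e-300)
        U_new, d2 = _memberships(centroids)
        prev_objective = objective
        objective = float((U_new**m * d2).sum())
        delta = np.abs(U_new - U).max()
        U = U_new
        # stop on membership stability or objective stability (the latter is
        # what terminates in the large-m regime, where the objective is flat)
        if delta < tol or abs(prev_objective - objective) < tol * max(1.0, objective):
            converged = True
            break
    if not converged:
        warnings.warn("fuzzy c-means did not converge within max_iter")
    return FuzzyClustering(centroids=centroids, membership=U, fuzzifier=m,
                           objective=objective, converged=converged,
                           genes=genes)


def min_centroid_distance(profiles: pd.DataFrame | np.ndarray,
                          m: float | None = None,
                          c_range: range | list[int] = range(2, 13),
                          seed: int = 0) -> pd.DataFrame:
    """Dmin table: minimum pairwise centroid distance for each cluster number.

    Advisory diagnostic for choosing c (a plateau near zero signals
    redundant clusters); the pipeline default stays c = 9.
    """
    n = profiles.shape[0]
    rows = []
    for c in c_range:
        if not (1 < c < n):
            raise ValueError(f"c={c} outside valid range (1, {n})")
        fit = fuzzy_cmeans(profiles, c=c, m=m, seed=seed)
        diff = fit.centroids[:, None, :] - fit.centroids[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        rows.append((c, float(d[np.triu_indices(c, k=1)].min())))
    return pd.DataFrame(rows, columns=["c", "dmin"]).set_index("c")


# ---------------------------------------------------------------------------
# Pattern classification
# ---------------------------------------------------------------------------

def _centroid_shape(centroid: np.ndarray) -> str:
    a, b, c = centroid
    if a < b < c:
        return "increasing"
    if a > b > c:
        return "decreasing"
    if b > max(a, c):
        return "jh_high"
    if b < min(a, c):
        return "jh_low"
    return "unclassified"  # exact ties land here


def classify_patterns(clustering: FuzzyClustering,
                      deg_jh_vs_awb: pd.DataFrame,
                      deg_jh_vs_du: pd.DataFrame,
                      membership_min: float = MEMBERSHIP_MIN) -> pd.DataFrame:
    """Assign each gene one of the four domestication patterns or ``none``.

    A gene qualifies only if its best cluster's membership reaches
    ``membership_min`` and the DEG evidence matches the shape:
    type2/type3 (JH-high/JH-low) need an up-/down-DEG call in *both* JH
    comparisons; type1/type4 (monotone) need a DEG call in at least one JH
    comparison with sign consistent with the slope (DU > AWB for type1
    means JH vs AWB up or JH vs DU down, and conversely for type4).

    DEG tables are ``wilcoxon_deg`` outputs indexed by gene with ``is_deg``
    and ``direction`` columns.
    """
    shapes = [_centroid_shape(c) for c in clustering.centroids]
    best = clustering.hard_labels
    best_membership = clustering.membership.max(axis=1)

    def _deg_dir(table: pd.DataFrame, gene: str) -> str | None:
        if gene not in table.index or not bool(table.loc[gene, "is_deg"]):
            return None
        return str(table.loc[gene, "direction"])

    rows = []
    for i, gene in enumerate(clustering.genes):
        shape = shapes[best[i]]
        d_awb = _deg_dir(deg_jh_vs_awb, gene)   # JH vs AWB
        d_du = _deg_dir(deg_jh_vs_du, gene)     # JH vs DU
        pattern = "none"
        if best_membership[i] >= membership_min and shape != "unclassified":
            if shape == "jh_high" and d_awb == "up" and d_du == "up":
                pattern = "type2"
            elif shape == "jh_low" and d_awb == "down" and d_du == "down":
                pattern = "type3"
            elif shape == "increasing" and (d_awb == "up" or d_du == "down"):
                # rising AWB -> JH -> DU: JH above AWB and/or DU above JH
                pattern = "type1"
            elif shape == "decreasing" and (d_awb == "down" or d_du == "up"):
                pattern = "type4"
        rows.append((gene, pattern, int(best[i]), float(best_membership[i]),
                     d_awb or "", d_du or ""))
    return pd.DataFrame(rows, columns=["gene", "pattern", "cluster",
                                       "membership", "deg_jh_vs_awb",
                                       "deg_jh_vs_du"]).set_index("gene")
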