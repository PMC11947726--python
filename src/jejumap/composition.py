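"""Bootstrapped permutation test for breed differences in per-cluster cell
proportions.

For each cluster c the observed statistic is
log2FD_c = log2(p_c^A / p_c^B), the log2 ratio of the cluster's proportion
between the two groups (0.5-cell pseudocounts guard empty cells of the
contingency table). The null distribution comes from shuffling group labels
across cells; confidence intervals from resampling cells with replacement
within each group; BH adjustment across clusters. A cluster is called
significant at FDR < 0.05 and |log2FD| > 1.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import bh_adjust

PSEUDOCOUNT = 0.5
FDR_MAX = 0.05
LOG2FD_MIN = 1.5


def _log2fd(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    # pseudocount only for empty cluster x group cells (guards infinite ratios
    # without perturbing observed proportions)
    ca = counts_a + PSEUDOCOUNT * (counts_a == 0)
    cb = counts_b + PSEUDOCOUNT * (counts_b == 0)
    return np.log2((ca / ca.sum()) / (cb / cb.sum()))


def proportion_permutation_test(clusters: pd.Series, groups: pd.Series,
                                pair: tuple[str, str], n_perm: int = 1000,
                                n_boot: int = 1000, seed: int = 0,
                                fdr_max: float = FDR_MAX,
                                log2fd_min: float = LOG2FD_MIN) -> pd.DataFrame:
    """Permutation test of composition differences between two groups.

    Returns one row per cluster with the observed log2 fold difference, its
    bootstrap mean and 2.5–97.5% CI, the add-one permutation p-value, the BH
    FDR and the significance call.
    """
    group_a, group_b = pair
    groups = groups.astype(str)
    in_pair = groups.isin([group_a, group_b]).to_numpy()
    if not (groups == group_a).any() or not (groups == group_b).any():
        raise ValueError(f"both groups of {pair} must be non-empty")
    cl = pd.Categorical(clusters[in_pair].astype(str))
    is_a = (groups[in_pair] == group_a).to_numpy()
    codes = cl.codes
    k = len(cl.categories)
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())

    def _counts(mask_a: np.ndarray, code_vec: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
        ca = np.bincount(code_vec[mask_a], minlength=k)
        cb = np.bincount(code_vec[~mask_a], minlength=k)
        return ca, cb

    obs_a, obs_b = _counts(is_a, codes)
    observed = _log2fd(obs_a, obs_b)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(k, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(is_a)
        pa, pb = _counts(perm, codes)
        exceed += np.abs(_log2fd(pa, pb)) >= np.abs(observed)
    p = (1.0 + exceed) / (n_perm + 1.0)

    idx_a = np.flatnonzero(is_a)
    idx_b = np.flatnonzero(~is_a)
    boot = np.empty((n_boot, k))
    for i in range(n_boot):
        ra = codes[rng.choice(idx_a, size=n_a, replace=True)]
        rb = codes[rng.choice(idx_b, size=n_b, replace=True)]
        boot[i] = _log2fd(np.bincount(ra, minlength=k),
                          np.bincount(rb, minlength=k))
    ci_lo, ci_hi = np.percentile(boot, [2.5, 97.5], axis=0)

    fdr = bh_adjust(p)
    table = pd.DataFrame({
        "cluster": list(cl.categories),
        "n_a": obs_a, "n_b": obs_b,
        "log2fd": observed,
        "boot_mean": boot.mean(axis=0),
        "ci_low": ci_lo, "ci_high": ci_hi,
        "p_value": p,
        "fdr": fdr,
        "significant": (fdr < fdr_max) & (np.abs(observed) > log2fd_min),
    }).set_index("cluster")
    return table
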