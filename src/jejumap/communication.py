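"""Ligand–receptor interaction scoring between annotated cell types with a
cluster-label permutation null.

For each (source type, target type, ligand-receptor pair), the interaction
mean is the average of the ligand entity's mean log-normalized expression
in the source cluster and the receptor entity's in the target cluster;
complexes (e.g. CD8A_CD8B) take the minimum over subunit means. An
interaction is gated out (undefined, reported NaN) unless both entities
are expressed in more than ``min_frac`` of their cluster's cells. The
permutation p-value shuffles cluster labels and counts null interaction
means at or above the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .gene_sets import LR_PAIRS, resolve_symbol

MIN_FRAC = 0.1


@dataclass
class LRPair:
    ligand: str
    receptor: str

    @property
    def name(self) -> str:
        return f"{self.ligand}->{self.receptor}"


def default_pairs() -> list[LRPair]:
    return [LRPair(l, r) for l, r in LR_PAIRS]


def _resolve_entities(pairs: list[LRPair], universe: set[str]
                      ) -> tuple[list[LRPair], dict[str, list[str]]]:
    """Keep pairs whose subunits all resolve; return entity -> subunit genes."""
    kept, entities = [], {}
    for pair in pairs:
        ok = True
        for entity in (pair.ligand, pair.receptor):
            subunits = [resolve_symbol(s, universe) for s in entity.split("_")]
            if all(s in universe for s in subunits):
                entities[entity] = subunits
            else:
                ok = False
        if ok:
            kept.append(pair)
        else:
            warnings.warn(f"pair {pair.name} has unresolvable genes; skipped")
    if not kept:
        raise ValueError("no ligand-receptor pair resolvable in this matrix")
    return kept, entities


def _cluster_stats(X: np.ndarray, onehot: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster mean expression and expressed fraction (clusters x genes)."""
    sizes = onehot.sum(axis=0)[:, None]
    means = (onehot.T @ X) / sizes
    fracs = (onehot.T @ (X > 0)) / sizes
    return means, fracs


def _entity_values(means: np.ndarray, fracs: np.ndarray,
                   entities: dict[str, list[str]],
                   gene_pos: dict[str, int]
                   ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-entity cluster values: min over subunit means; min expressed frac."""
    vals, vfrac = {}, {}
    for entity, subunits in entities.items():
        cols = [gene_pos[s] for s in subunits]
        vals[entity] = means[:, cols].min(axis=1)
        vfrac[entity] = fracs[:, cols].min(axis=1)
    return vals, vfrac


def interaction_means(adata: AnnData, labels: pd.Series,
                      pairs: list[LRPair] | None = None,
                      min_frac: float = MIN_FRAC) -> pd.DataFrame:
    """Observed interaction means for every (source, target, pair) triple.

    Gated triples carry NaN means (not 0: the interaction is undefined, not
    absent). Autocrine (source == target) interactions are computed like any
    other.
    """
    pairs = pairs if pairs is not None else default_pairs()
    universe = set(adata.var_names)
    pairs, entities = _resolve_entities(pairs, universe)
    genes = sorted({s for subs in entities.values() for s in subs})
    gene_pos = {g: j for j, g in enumerate(genes)}
    sub = adata[:, genes].X
    X = sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)

    cats = pd.Categorical(labels.astype(str))
    onehot = np.eye(len(cats.categories))[cats.codes]
    means, fracs = _cluster_stats(X, onehot)
    vals, vfrac = _entity_values(means, fracs, entities, gene_pos)

    clusters = list(cats.categories)
    rows = []
    for si, source in enumerate(clusters):
        for ti, target in enumerate(clusters):
            for pair in pairs:
                lig_v, rec_v = vals[pair.ligand][si], vals[pair.receptor][ti]
                gated = (vfrac[pair.ligand][si] <= min_frac
                         or vfrac[pair.receptor][ti] <= min_frac)
                mean = np.nan if gated else 0.5 * (lig_v + rec_v)
                rows.append((source, target, pair.name, mean, gated))
    return pd.DataFrame(rows, columns=["source", "target", "pair",
                                       "interaction_mean", "gated"])


def lr_permutation_test(adata: AnnData, labels: pd.Series,
                        pairs: list[LRPair] | None = None,
                        n_perm: int = 1000, min_frac: float = MIN_FRAC,
                        seed: int = 0) -> pd.DataFrame:
    """Permutation p-values for all (source, target, pair) interaction means.

    p = (1 + #{null mean >= observed}) / (n_perm + 1) under cluster-label
    shuffling; gated triples keep NaN means and NaN p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pairs = pairs if pairs is not None else default_pairs()
    universe = set(adata.var_names)
    pairs, entities = _resolve_entities(pairs, universe)
    genes = sorted({s for subs in entities.values() for s in subs})
    gene_pos = {g: j for j, g in enumerate(genes)}
    sub = adata[:, genes].X
    X = sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)

    cats = pd.Categorical(labels.astype(str))
    if len(cats.categories) < 2:
        raise ValueError("need at least 2 clusters")
    k = len(cats.categories)
    eye = np.eye(k)
    onehot = eye[cats.codes]
    means, fracs = _cluster_stats(X, onehot)
    vals, vfrac = _entity_values(means, fracs, entities, gene_pos)

    # observed statistic per (source, target, pair): (k, k, P)
    P = len(pairs)
    lig_obs = np.stack([vals[p.ligand] for p in pairs], axis=1)       # k x P
    rec_obs = np.stack([vals[p.receptor] for p in pairs], axis=1)     # k x P
    observed = 0.5 * (lig_obs[:, None, :] + rec_obs[None, :, :])      # k x k x P
    lig_frac = np.stack([vfrac[p.ligand] for p in pairs], axis=1)
    rec_frac = np.stack([vfrac[p.receptor] for p in pairs], axis=1)
    gated = (lig_frac[:, None, :] <= min_frac) | (rec_frac[None, :, :] <= min_frac)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed, dtype=int)
    codes = cats.codes.copy()
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        pm, _pf = _cluster_stats(X, eye[perm_codes])
        pvals, _ = _entity_values(pm, np.ones_like(pm), entities, gene_pos)
        lig_p = np.stack([pvals[p.ligand] for p in pairs], axis=1)
        rec_p = np.stack([pvals[p.receptor] for p in pairs], axis=1)
        null = 0.5 * (lig_p[:, None, :] + rec_p[None, :, :])
        exceed += null >= observed
    pval = (1.0 + exceed) / (n_perm + 1.0)

    clusters = list(cats.categories)
    rows = []
    for si, source in enumerate(clusters):
        for ti, target in enumerate(clusters):
            for pi, pair in enumerate(pairs):
                if gated[si, ti, pi]:
                    rows.append((source, target, pair.name, np.nan, np.nan, True))
                else:
                    rows.append((source, target, pair.name,
                                 float(observed[si, ti, pi]),
                                 float(pval[si, ti, pi]), False))
    return pd.DataFrame(rows, columns=["source", "target", "pair",
                                       "interaction_mean", "p_value", "gated"])


def top_interactions(result: pd.DataFrame, k: int = 20,
                     p_max: float = 0.01) -> pd.DataFrame:
    """Top-k interactions with p < p_max, ranked by interaction mean
    (descending); ties break by pair name lexicographically."""
    if result.empty:
        raise ValueError("empty communication result")
    passing = result[(result["p_value"] < p_max) & ~result["gated"]]
    ranked = passing.sort_values(["interaction_mean", "pair"],
                                 ascending=[False, True], kind="stable")
    return ranked.head(k).reset_index(drop=True)
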