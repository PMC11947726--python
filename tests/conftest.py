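"""Shared fixtures: small synthetic atlases and AnnData builders."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from jejumap.synth_atlas import LIBRARY_SIZES, SyntheticSpec, default_spec


def scaled_spec(total_cells: int, seed: int = 0, **overrides) -> SyntheticSpec:
    """Default spec with library sizes scaled down proportionally."""
    scale = total_cells / sum(LIBRARY_SIZES.values())
    sizes = {b: max(1, round(n * scale)) for b, n in LIBRARY_SIZES.items()}
    return replace(default_spec(), library_sizes=sizes, seed=seed, **overrides)


def make_adata(X, genes: list[str] | None = None,
               obs: pd.DataFrame | None = None) -> AnnData:
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    genes = genes if genes is not None else [f"G{j}" for j in range(g)]
    var = pd.DataFrame({"gene_id": genes, "symbol": genes,
                        "mito": [s.startswith("MT-") for s in genes]},
                       index=genes)
    if obs is None:
        obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    return AnnData(X=sp.csr_matrix(X), obs=obs, var=var)


@pytest.fixture(scope="session")
def small_atlas():
    """~1,500-cell three-breed atlas with default composition and doublets."""
    from jejumap.synth_atlas import simulate_atlas
    spec = scaled_spec(1500, seed=42)
    return simulate_atlas(spec)
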