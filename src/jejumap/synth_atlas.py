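"""Synthetic multi-breed jejunum scRNA-seq atlas generator with ground truth.

Emulates the structure of a three-breed pig jejunum single-cell atlas —
Asian wild boar (AWB), Jinhua (JH) and Duroc (DU) libraries of 11,929 /
2,645 / 11,672 cells — with six major cell lineages, five T/ILC/NK
subtypes and three plasma-cell subtypes at the published compositions.

Counts follow a gamma–Poisson (negative binomial) law around per-gene
lognormal baseline means. Each lineage/subtype multiplicatively boosts its
marker panel and a private block of unnamed "program" genes, so that
clustering and marker annotation can recover the planted labels without
the task being trivial. Mitochondrial genes are scaled per cell so the
expected mitochondrial read fraction matches a configurable condition
(a small "damaged" sub-population carries a high fraction, exercising the
mito QC filter). Doublets are appended by summing random cell pairs.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .gene_sets import (
    LINEAGE_MARKERS,
    PLASMA_SUBTYPE_MARKERS,
    T_SUBTYPE_MARKERS,
    all_named_genes,
    resolve_symbol,
)

LINEAGES = list(LINEAGE_MARKERS)  # epithelial, plasma, B, T/ILC/NK, myeloid, mesenchymal
T_SUBTYPES = list(T_SUBTYPE_MARKERS)
PLASMA_SUBTYPES = list(PLASMA_SUBTYPE_MARKERS)
BREEDS = ["AWB", "JH", "DU"]

#: Published per-library cell counts (26,246 total).
LIBRARY_SIZES: dict[str, int] = {"AWB": 11_929, "JH": 2_645, "DU": 11_672}

#: Published pooled major-lineage composition of the atlas.
POOLED_LINEAGE_WEIGHTS: dict[str, float] = {
    "T/ILC/NK": 0.654,
    "epithelial": 0.251,
    "plasma": 0.073,
    "myeloid": 0.014,
    "B": 0.006,
    "mesenchymal": 0.002,
}

# Per-breed lineage weights. Printed values: AWB T/ILC/NK = 83.0%,
# JH plasma = 32.0%. All other entries of AWB/JH are FIXED FILLERS (the
# per-breed breakdown is not published); DU is derived at import time so the
# size-weighted pooled composition reproduces POOLED_LINEAGE_WEIGHTS exactly.
AWB_LINEAGE_WEIGHTS: dict[str, float] = {
    "T/ILC/NK": 0.830,  # published
    "epithelial": 0.120,
    "plasma": 0.030,
    "myeloid": 0.012,
    "B": 0.005,
    "mesenchymal": 0.003,
}
JH_LINEAGE_WEIGHTS: dict[str, float] = {
    "plasma": 0.320,  # published
    "T/ILC/NK": 0.500,
    "epithelial": 0.150,
    "myeloid": 0.020,
    "B": 0.007,
    "mesenchymal": 0.003,
}


def _derive_du_lineage_weights() -> dict[str, float]:
    total = sum(LIBRARY_SIZES.values())
    f_awb = LIBRARY_SIZES["AWB"] / total
    f_jh = LIBRARY_SIZES["JH"] / total
    f_du = LIBRARY_SIZES["DU"] / total
    out = {}
    for lin in LINEAGES:
        w = (POOLED_LINEAGE_WEIGHTS[lin]
             - f_awb * AWB_LINEAGE_WEIGHTS[lin]
             - f_jh * JH_LINEAGE_WEIGHTS[lin]) / f_du
        if w < 0:
            raise ValueError(f"derived DU weight for {lin!r} is negative")
        out[lin] = w
    return out


DU_LINEAGE_WEIGHTS: dict[str, float] = _derive_du_lineage_weights()

# T/ILC/NK subtype weights. Printed: CD4 ab T and CD8 ab T percentages for
# all three breeds; ILC/NK/gd T split the remainder with fixed fillers.
T_SUBTYPE_WEIGHTS: dict[str, dict[str, float]] = {
    "AWB": {"ILC": 0.050, "NK": 0.040, "CD4 ab T": 0.036, "CD8 ab T": 0.834,
            "gd T": 0.040},
    "JH": {"ILC": 0.200, "NK": 0.130, "CD4 ab T": 0.142, "CD8 ab T": 0.328,
           "gd T": 0.200},
    "DU": {"ILC": 0.050, "NK": 0.035, "CD4 ab T": 0.035, "CD8 ab T": 0.843,
           "gd T": 0.037},
}

# Plasma subtype weights. Printed: JH Type 3 = 13.1%; Type 3 absent outside
# JH; remaining splits are fixed fillers.
PLASMA_SUBTYPE_WEIGHTS: dict[str, dict[str, float]] = {
    "AWB": {"Plasma Type1": 0.600, "Plasma Type2": 0.400, "Plasma Type3": 0.0},
    "JH": {"Plasma Type1": 0.500, "Plasma Type2": 0.369, "Plasma Type3": 0.131},
    "DU": {"Plasma Type1": 0.600, "Plasma Type2": 0.400, "Plasma Type3": 0.0},
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic atlas generator.

    ``baseline_mean_distribution`` is the (mu, sigma) of the lognormal law of
    per-gene relative baseline means (heavy right tail, as in depth-normalized
    real data). ``dispersion`` is the gamma–Poisson overdispersion phi with
    Var = mu + phi * mu^2. ``libsize_lognormal`` is the (mu, sigma) of the
    per-cell total-count law on the natural-log scale.
    """

    n_genes: int = 2000
    library_sizes: dict[str, int] = field(
        default_factory=lambda: dict(LIBRARY_SIZES))
    lineage_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"AWB": dict(AWB_LINEAGE_WEIGHTS),
                                 "JH": dict(JH_LINEAGE_WEIGHTS),
                                 "DU": dict(DU_LINEAGE_WEIGHTS)})
    t_subtype_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {b: dict(w) for b, w in T_SUBTYPE_WEIGHTS.items()})
    plasma_subtype_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {b: dict(w)
                                 for b, w in PLASMA_SUBTYPE_WEIGHTS.items()})
    marker_fold: float = 8.0
    program_fold: float = 4.0
    n_program_genes: int = 20
    baseline_mean_distribution: tuple[float, float] = (0.0, 1.5)
    dispersion: float = 0.4
    libsize_lognormal: tuple[float, float] = (np.log(2500.0), 0.35)
    mito_gene_fraction: float = 0.005
    mito_expr_fraction: dict[str, float] = field(
        default_factory=lambda: {"normal": 0.05, "damaged": 0.65})
    damaged_rate: float = 0.02
    doublet_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for breed, n in self.library_sizes.items():
            if n <= 0:
                raise ValueError(f"library size for {breed!r} must be > 0")
        for name, table in (("lineage_weights", self.lineage_weights),
                            ("t_subtype_weights", self.t_subtype_weights),
                            ("plasma_subtype_weights",
                             self.plasma_subtype_weights)):
            for breed in self.library_sizes:
                weights = table.get(breed)
                if weights is None:
                    raise ValueError(f"{name} missing breed {breed!r}")
                vals = np.asarray(list(weights.values()), dtype=float)
                if (vals < 0).any():
                    raise ValueError(f"{name}[{breed!r}] has negative weights")
                if abs(vals.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{name}[{breed!r}] does not sum to 1")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if not (0 <= self.doublet_rate < 1):
            raise ValueError("doublet_rate must be in [0, 1)")
        if not (0 <= self.damaged_rate < 1):
            raise ValueError("damaged_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def default_spec() -> SyntheticSpec:
    """Spec reproducing the published atlas structure (26,246 cells)."""
    return SyntheticSpec()


# ---------------------------------------------------------------------------
# Gene universe
# ---------------------------------------------------------------------------

def _build_gene_universe(spec: SyntheticSpec) -> tuple[list[str], dict[str, np.ndarray]]:
    """Gene name list plus label -> boosted-gene-index map.

    Universe = named panel/set genes, mitochondrial genes, per-label program
    blocks, then anonymous filler genes up to ``n_genes``.
    """
    named = all_named_genes()
    n_mito = max(1, round(spec.mito_gene_fraction * spec.n_genes))
    mito = [f"MT-G{i + 1}" for i in range(n_mito)]
    labels = LINEAGES + T_SUBTYPES + PLASMA_SUBTYPES
    programs: dict[str, list[str]] = {
        lab: [f"PRG{j:02d}-{i:02d}" for i in range(spec.n_program_genes)]
        for j, lab in enumerate(labels)
    }
    program_flat = [g for lab in labels for g in programs[lab]]
    n_core = len(named) + len(mito) + len(program_flat)
    if spec.n_genes < n_core:
        raise ValueError(
            f"n_genes={spec.n_genes} too small; need >= {n_core} for named, "
            "mitochondrial and program genes")
    filler = [f"GENE{i:05d}" for i in range(spec.n_genes - n_core)]
    genes = named + mito + program_flat + filler
    index = {g: i for i, g in enumerate(genes)}

    effects: dict[str, np.ndarray] = {}
    marker_tables = [(LINEAGES, LINEAGE_MARKERS), (T_SUBTYPES, T_SUBTYPE_MARKERS),
                     (PLASMA_SUBTYPES, PLASMA_SUBTYPE_MARKERS)]
    universe = set(genes)
    for labs, table in marker_tables:
        for lab in labs:
            marker_idx = [index[resolve_symbol(g, universe)]
                          for g in table[lab]
                          if resolve_symbol(g, universe) in index]
            effects[lab + "|markers"] = np.asarray(marker_idx, dtype=int)
            effects[lab + "|program"] = np.asarray(
                [index[g] for g in programs[lab]], dtype=int)
    effects["|mito"] = np.asarray([index[g] for g in mito], dtype=int)
    return genes, effects


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _group_profile(base: np.ndarray, effects: dict[str, np.ndarray],
                   lineage: str, subtype: str | None, spec: SyntheticSpec,
                   mito_frac: float) -> np.ndarray:
    """Relative mean profile (sums to 1) of one (lineage, subtype, condition)."""
    prof = base.copy()
    prof[effects[lineage + "|markers"]] *= spec.marker_fold
    prof[effects[lineage + "|program"]] *= spec.program_fold
    if subtype is not None:
        prof[effects[subtype + "|markers"]] *= spec.marker_fold
        prof[effects[subtype + "|program"]] *= spec.program_fold
    mito_idx = effects["|mito"]
    non_mito = prof.sum() - prof[mito_idx].sum()
    # scale the mito block to carry exactly mito_frac of the expected reads
    prof[mito_idx] *= (mito_frac / (1.0 - mito_frac)) * non_mito / prof[mito_idx].sum()
    return prof / prof.sum()


def simulate_atlas(spec: SyntheticSpec | None = None
                   ) -> tuple[AnnData, pd.DataFrame]:
    """Simulate the multi-breed atlas; returns (counts, ground truth).

    The counts AnnData carries raw integer counts (CSR), a feature table with
    a mitochondrial flag, and per-cell library labels in ``obs["library"]``.
    The ground-truth frame records the true lineage, subtype, damaged flag
    and doublet flag per cell, aligned with ``obs_names``.
    """
    if spec is None:
        spec = default_spec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes, effects = _build_gene_universe(spec)

    mu0, sigma0 = spec.baseline_mean_distribution
    base = rng.lognormal(mu0, sigma0, size=spec.n_genes)
    # canonical markers are canonical because they are robustly detected:
    # floor marker/program baselines at the 75th percentile of the baseline
    # law so a fold-change on them is measurable at realistic depths
    floor = np.quantile(base, 0.75)
    boosted = np.unique(np.concatenate([idx for idx in effects.values()]))
    boosted = boosted[~np.isin(boosted, effects["|mito"])]
    base[boosted] = np.maximum(base[boosted], floor)

    # per-cell labels, breed by breed
    obs_rows = []
    for breed in spec.library_sizes:
        n_b = spec.library_sizes[breed]
        lw = spec.lineage_weights[breed]
        lin_names = list(lw)
        p = np.asarray([lw[k] for k in lin_names], dtype=float)
        lineage = rng.choice(lin_names, size=n_b, p=p / p.sum())
        subtype = np.full(n_b, None, dtype=object)
        for table, parent in ((spec.t_subtype_weights[breed], "T/ILC/NK"),
                              (spec.plasma_subtype_weights[breed], "plasma")):
            mask = lineage == parent
            if mask.any():
                names = list(table)
                q = np.asarray([table[k] for k in names], dtype=float)
                subtype[mask] = rng.choice(names, size=mask.sum(), p=q / q.sum())
        damaged = rng.random(n_b) < spec.damaged_rate
        for i in range(n_b):
            obs_rows.append((breed, lineage[i], subtype[i], damaged[i]))
    obs = pd.DataFrame(obs_rows, columns=["library", "lineage", "subtype",
                                          "is_damaged"])
    n_cells = len(obs)
    obs.index = [f"CELL{i:06d}" for i in range(n_cells)]

    mu_ls, sigma_ls = spec.libsize_lognormal
    depth = rng.lognormal(mu_ls, sigma_ls, size=n_cells)

    # gamma–Poisson counts, generated group-wise for vectorization
    shape = 1.0 / spec.dispersion
    group_key = pd.Series(
        obs["lineage"].astype(str) + "//" + obs["subtype"].astype(str) + "//"
        + np.where(obs["is_damaged"], "damaged", "normal"), index=obs.index)
    blocks, block_rows = [], []
    for key in sorted(group_key.unique()):
        rows = np.flatnonzero((group_key == key).to_numpy())
        lineage_name, subtype_name, condition = key.split("//")
        subtype_name = None if subtype_name == "None" else subtype_name
        prof = _group_profile(base, effects, lineage_name, subtype_name, spec,
                              spec.mito_expr_fraction[condition])
        for start in range(0, rows.size, 2048):
            idx = rows[start:start + 2048]
            mean = depth[idx, None] * prof[None, :]
            lam = rng.gamma(shape, mean / shape)
            counts = rng.poisson(lam)
            blocks.append(sp.csr_matrix(counts.astype(np.int32)))
            block_rows.append(idx)
    order = np.argsort(np.concatenate(block_rows))
    X = sp.vstack(blocks, format="csr")[order]

    var = pd.DataFrame({
        "gene_id": genes,
        "symbol": genes,
        "mito": [g.startswith("MT-") for g in genes],
    }, index=genes)
    adata = AnnData(X=X, obs=obs[["library"]].copy(), var=var)
    truth = obs.rename(columns={"library": "library_of_origin"})
    truth["is_doublet"] = False

    if spec.doublet_rate > 0:
        adata, truth = inject_doublets(adata, truth, spec.doublet_rate,
                                       seed=int(rng.integers(2**31)))
    return adata, truth


def simulate_compartment(breed: str, compartment: str, n_cells: int,
                         seed: int = 0,
                         base_spec: SyntheticSpec | None = None
                         ) -> tuple[AnnData, pd.DataFrame]:
    """Simulate a single-breed sub-compartment (T/ILC/NK or plasma subtypes).

    Used for subtype-recovery experiments: all cells belong to the parent
    lineage and split over its subtypes at the breed's weights; no doublets
    or damaged cells, so the compartment isolates the subtype signal.
    """
    if compartment not in ("T/ILC/NK", "plasma"):
        raise ValueError("compartment must be 'T/ILC/NK' or 'plasma'")
    spec = base_spec if base_spec is not None else default_spec()
    one_lineage = {lin: (1.0 if lin == compartment else 0.0) for lin in LINEAGES}
    spec = replace(
        spec,
        library_sizes={breed: n_cells},
        lineage_weights={breed: one_lineage},
        t_subtype_weights={breed: spec.t_subtype_weights[breed]},
        plasma_subtype_weights={breed: spec.plasma_subtype_weights[breed]},
        doublet_rate=0.0,
        damaged_rate=0.0,
        seed=seed,
    )
    return simulate_atlas(spec)


def inject_doublets(adata: AnnData, truth: pd.DataFrame, rate: float,
                    seed: int = 0) -> tuple[AnnData, pd.DataFrame]:
    """Append ``round(rate * n)`` doublets formed by summing random cell pairs.

    Pairs are drawn within the same library (droplet doublets cannot span
    libraries). Appended cells are flagged ``is_doublet`` in the returned
    ground truth, with parent barcodes recorded.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    n = adata.n_obs
    n_doub = round(rate * n)
    if n_doub == 0:
        return adata, truth
    rng = np.random.default_rng(seed)
    libraries = adata.obs["library"].to_numpy()
    lib_choices = rng.choice(libraries, size=n_doub)
    parents = np.empty((n_doub, 2), dtype=int)
    for i, lib in enumerate(lib_choices):
        pool = np.flatnonzero(libraries == lib)
        parents[i] = rng.choice(pool, size=2, replace=False)

    X = sp.csr_matrix(adata.X)
    doub_X = X[parents[:, 0]] + X[parents[:, 1]]
    new_obs = pd.DataFrame({"library": lib_choices},
                           index=[f"DBL{i:05d}" for i in range(n_doub)])
    out = AnnData(X=sp.vstack([X, doub_X], format="csr"),
                  obs=pd.concat([adata.obs, new_obs]),
                  var=adata.var.copy())

    doub_truth = pd.DataFrame({
        "library_of_origin": lib_choices,
        "lineage": truth["lineage"].to_numpy()[parents[:, 0]],
        "subtype": truth["subtype"].to_numpy()[parents[:, 0]],
        "is_damaged": False,
        "is_doublet": True,
        "parent1": truth.index.to_numpy()[parents[:, 0]],
        "parent2": truth.index.to_numpy()[parents[:, 1]],
    }, index=new_obs.index)
    out_truth = pd.concat([truth, doub_truth])
    if "parent1" not in truth.columns:
        out_truth.loc[truth.index, ["parent1", "parent2"]] = pd.NA
    return out, out_truth
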