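"""Preprocessing, Leiden clustering, marker annotation, cell cycle, dendrogram."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from skbio import TreeNode

from jejumap.cluster_annotate import (
    annotate_clusters,
    cell_cycle_phase,
    celltype_dendrogram,
    cluster_cells,
    preprocess,
)
from jejumap.gene_sets import LINEAGE_MARKERS
from jejumap.synth_atlas import LINEAGES, simulate_atlas

from conftest import make_adata, scaled_spec


def two_lineage_spec(n=500, seed=1):
    weights = {b: {lin: (0.5 if lin in ("T/ILC/NK", "epithelial") else 0.0)
                   for lin in LINEAGES} for b in ("AWB", "JH", "DU")}
    return scaled_spec(n, seed=seed, doublet_rate=0.0, damaged_rate=0.0,
                       lineage_weights=weights)


class TestPreprocess:
    def test_depth_invariance(self):
        """Cells with proportional count vectors get identical profiles."""
        rng = np.random.default_rng(0)
        base = rng.poisson(3.0, size=(10, 50)) + 1
        X = base.copy()
        X[1] = 2 * X[0]
        out = preprocess(make_adata(X), n_hvg=30, n_pcs=5)
        row0 = np.asarray(out.X[0].todense()).ravel()
        row1 = np.asarray(out.X[1].todense()).ravel()
        np.testing.assert_allclose(row0, row1, rtol=1e-6)

    def test_constant_gene_not_highly_variable(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(3.0, size=(50, 40)).astype(float) + 1
        X[:, 7] = 5.0
        X[:, 0] += X.sum(axis=1).max() - X.sum(axis=1)  # equalize depths
        out = preprocess(make_adata(X), n_hvg=10, n_pcs=5)
        assert not out.var["highly_variable"].iloc[7]

    def test_n_hvg_clamped_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(3.0, size=(30, 20)) + 1
        with pytest.warns(UserWarning, match="clamped"):
            preprocess(make_adata(X), n_hvg=100, n_pcs=5)

    def test_first_pc_separates_lineages(self):
        adata, truth = simulate_atlas(two_lineage_spec())
        out = preprocess(adata, seed=1)
        pc1 = out.obsm["X_pca"][:, 0]
        is_t = (truth["lineage"] == "T/ILC/NK").to_numpy().astype(float)
        r = np.corrcoef(pc1, is_t)[0, 1]
        assert abs(r) > 0.9


def _blob_adata(centers, n_per, sd=0.05, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([c + sd * rng.standard_normal((n_per, len(c)))
                     for c in centers])
    adata = make_adata(np.abs(pts))
    adata.obsm["X_pca"] = pts
    return adata


class TestClusterCells:
    def test_two_separated_blobs_recovered_exactly(self):
        adata = _blob_adata([np.zeros(5), np.full(5, 10.0)], 60)
        res = cluster_cells(adata, k=50, resolution=0.5, seed=0)
        labels = res.labels.to_numpy()
        truth = np.repeat([0, 1], 60)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_cluster_count_nondecreasing_in_resolution(self):
        adata = _blob_adata([np.zeros(5), np.full(5, 6.0), np.full(5, -6.0)],
                            50, sd=0.8)
        counts = [cluster_cells(adata, k=10, resolution=r, seed=0).n_clusters
                  for r in (0.5, 1.0, 1.5, 2.0)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_single_cloud_single_cluster(self):
        adata = _blob_adata([np.zeros(5)], 80, sd=0.3)
        res = cluster_cells(adata, k=60, resolution=0.5, seed=0)
        assert res.n_clusters == 1

    def test_partition_property(self):
        adata = _blob_adata([np.zeros(4), np.full(4, 8.0)], 40)
        res = cluster_cells(adata, k=8, seed=0)
        assert len(res.labels) == adata.n_obs
        assert res.labels.notna().all()

    def test_k_too_large_rejected(self):
        adata = _blob_adata([np.zeros(3)], 10)
        with pytest.raises(ValueError):
            cluster_cells(adata, k=10)


class TestAnnotateClusters:
    def _panel_adata(self, boosted: dict[int, list[str]], n_per=30, seed=0):
        """Clusters of cells with 8x elevated expression of given genes."""
        genes = sorted({g for gs in LINEAGE_MARKERS.values() for g in gs})
        genes += [f"BG{i}" for i in range(30)]
        rng = np.random.default_rng(seed)
        rows = []
        clusters = []
        for cid, boost_genes in boosted.items():
            lam = np.ones(len(genes))
            for g in boost_genes:
                lam[genes.index(g)] = 8.0
            rows.append(rng.poisson(lam, size=(n_per, len(genes))))
            clusters.extend([str(cid)] * n_per)
        X = np.log1p(np.vstack(rows).astype(float))
        adata = make_adata(X, genes=genes)
        return adata, pd.Series(clusters, index=adata.obs_names)

    def test_epithelial_and_plasma_markers_drive_labels(self):
        adata, clusters = self._panel_adata({
            0: ["EPCAM", "KRT8"],
            1: ["JCHAIN", "MZB1"],
            2: ["CD3E", "ZAP70", "CD8A", "NKG7"],
        })
        labels = annotate_clusters(adata, clusters, LINEAGE_MARKERS)
        assert labels[clusters == "0"].eq("epithelial").all()
        assert labels[clusters == "1"].eq("plasma").all()
        assert labels[clusters == "2"].eq("T/ILC/NK").all()

    def test_all_panel_genes_missing_rejected(self):
        adata = make_adata(np.ones((10, 4)), genes=["A", "B", "C", "D"])
        clusters = pd.Series(["0"] * 10, index=adata.obs_names)
        with pytest.raises(ValueError):
            annotate_clusters(adata, clusters, {"x": ["NOPE1"], "y": ["NOPE2"]})

    def test_lineage_recovery_on_default_atlas(self):
        """>= 90% of cells get their planted lineage back end to end."""
        adata, truth = simulate_atlas(
            scaled_spec(2000, seed=33, doublet_rate=0.0, damaged_rate=0.0))
        pp = preprocess(adata, seed=33)
        res = cluster_cells(pp, resolution=2.0, seed=33)
        labels = annotate_clusters(pp, res.labels, LINEAGE_MARKERS)
        recovery = (labels.to_numpy() == truth["lineage"].to_numpy()).mean()
        assert recovery >= 0.90


class TestCellCycle:
    def test_zero_phase_expression_gives_g1_and_argmax_rule(self):
        s_genes, g2m_genes = ["S1", "S2"], ["M1", "M2"]
        genes = s_genes + g2m_genes + [f"BG{i}" for i in range(46)]
        rng = np.random.default_rng(3)
        X = np.log1p(rng.poisson(2.0, size=(60, len(genes))).astype(float))
        X[0, :4] = 0.0          # no S/G2M signal at all
        X[1, 0:2] = 4.0         # S-high cell
        X[1, 2:4] = 0.5
        adata = make_adata(X, genes=genes)
        phases, _ = cell_cycle_phase(adata, s_genes, g2m_genes, seed=0, n_bins=5)
        assert phases.loc[adata.obs_names[0], "phase"] == "G1"
        row1 = phases.loc[adata.obs_names[1]]
        assert row1["s_score"] > row1["g2m_score"]
        assert row1["phase"] == "S"
        # invariant: G1 iff both scores <= 0, else argmax
        for _, row in phases.iterrows():
            if row["s_score"] <= 0 and row["g2m_score"] <= 0:
                assert row["phase"] == "G1"
            else:
                assert row["phase"] == ("S" if row["s_score"] >= row["g2m_score"]
                                        else "G2M")

    def test_residualized_expression_uncorrelated_with_scores(self):
        s_genes, g2m_genes = ["S1", "S2"], ["M1", "M2"]
        genes = s_genes + g2m_genes + [f"BG{i}" for i in range(26)]
        rng = np.random.default_rng(4)
        X = np.log1p(rng.poisson(3.0, size=(50, len(genes))).astype(float))
        adata = make_adata(X, genes=genes)
        phases, resid = cell_cycle_phase(adata, s_genes, g2m_genes, seed=0,
                                         regress=True, n_bins=5)
        R = np.asarray(resid.X)
        for score in (phases["s_score"], phases["g2m_score"]):
            s = score.to_numpy() - score.mean()
            corr = s @ (R - R.mean(axis=0))
            np.testing.assert_allclose(corr, 0.0, atol=1e-8)

    def test_both_sets_absent_rejected(self):
        adata = make_adata(np.ones((10, 3)), genes=["A", "B", "C"])
        with pytest.raises(ValueError):
            cell_cycle_phase(adata, ["NO1"], ["NO2"])


class TestDendrogram:
    def _adata_with_groups(self, profiles, n_per=20, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, names = [], []
        for name, prof in profiles.items():
            block = np.tile(prof, (n_per, 1))
            block = block + noise * rng.standard_normal(block.shape)
            rows.append(block)
            names.extend([name] * n_per)
        X = np.vstack(rows)
        adata = make_adata(X)
        return adata, pd.Series(names, index=adata.obs_names)

    def test_identical_groups_merge_at_height_zero(self):
        prof = np.linspace(1, 5, 30)
        adata, groups = self._adata_with_groups({"a": prof, "b": prof,
                                                 "c": prof[::-1]})
        newick = celltype_dendrogram(adata, groups, use_hvg=False)
        tree = TreeNode.read([newick])
        assert tree.find("a").distance(tree.find("b")) == pytest.approx(0, abs=1e-9)

    def test_leaf_and_node_counts(self):
        rng = np.random.default_rng(5)
        profiles = {f"g{i}": rng.random(25) for i in range(6)}
        adata, groups = self._adata_with_groups(profiles)
        tree = TreeNode.read([celltype_dendrogram(adata, groups, use_hvg=False)])
        assert tree.count(tips=True) == 6
        assert sum(1 for n in tree.non_tips(include_self=True)) == 5

    def test_perturbed_group_joins_outside_its_clade(self):
        """A breed's perturbed plasma profile leaves the plasma clade."""
        rng = np.random.default_rng(6)
        plasma = rng.random(40) * 3
        t_cell = rng.random(40) * 3
        adata, groups = self._adata_with_groups({
            "AWB_plasma": plasma, "DU_plasma": plasma,
            "JH_plasma": rng.permutation(plasma),    # perturbed
            "AWB_T": t_cell, "DU_T": t_cell,
        }, noise=0.05)
        tree = TreeNode.read([celltype_dendrogram(adata, groups, use_hvg=False)])
        d_intact = tree.find("AWB_plasma").distance(tree.find("DU_plasma"))
        d_perturbed = tree.find("JH_plasma").distance(tree.find("AWB_plasma"))
        assert d_perturbed > d_intact

    def test_fewer_than_two_groups_rejected(self):
        adata, groups = self._adata_with_groups({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            celltype_dendrogram(adata, groups, use_hvg=False)
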