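"""Breed profiles, fuzzifier estimate, fuzzy c-means vs brute-force oracle,
Dmin diagnostics and the four-pattern classification."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from jejumap.domestication import (
    FuzzyClustering,
    breed_profile,
    classify_patterns,
    estimate_fuzzifier,
    fuzzy_cmeans,
    min_centroid_distance,
)

from conftest import make_adata


class TestBreedProfile:
    def _adata(self, means_by_breed, n_per=20, noise=0.0, seed=0):
        """means_by_breed: genes x 3 array of per-breed means (AWB, JH, DU)."""
        rng = np.random.default_rng(seed)
        rows, breeds = [], []
        for j, b in enumerate(("AWB", "JH", "DU")):
            block = np.tile(means_by_breed[:, j], (n_per, 1))
            rows.append(block + noise * rng.standard_normal(block.shape))
            breeds.extend([b] * n_per)
        X = np.vstack(rows)
        adata = make_adata(X)
        return adata, pd.Series(breeds, index=adata.obs_names)

    def test_z_score_arithmetic(self):
        """Breed means (1, 2, 3) -> standardized (-1.2247, 0, 1.2247)."""
        adata, breeds = self._adata(np.array([[1.0, 2.0, 3.0]]))
        prof = breed_profile(adata, breeds)
        np.testing.assert_allclose(prof.iloc[0],
                                   [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_gene_dropped(self):
        adata, breeds = self._adata(np.array([[1.0, 2.0, 3.0],
                                              [2.0, 2.0, 2.0]]))
        with pytest.warns(UserWarning, match="zero-variance"):
            prof = breed_profile(adata, breeds)
        assert len(prof) == 1

    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        adata, breeds = self._adata(rng.random((30, 3)) * 4)
        prof = breed_profile(adata, breeds)
        np.testing.assert_allclose(prof.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(prof.to_numpy().std(axis=1), 1.0, atol=1e-9)

    def test_missing_breed_rejected(self):
        adata, breeds = self._adata(np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="DU"):
            breed_profile(adata[breeds != "DU"], breeds[breeds != "DU"])


class TestEstimateFuzzifier:
    def test_closed_form_value(self):
        """Independent evaluation of the estimate at N=2000, D=3."""
        N, D = 2000.0, 3.0
        expected = (1.0 + (1418.0 / N + 22.05) * D**-2.0
                    + (12.33 / N + 0.243)
                    * D**(-0.0406 * np.log(N) - 0.1134))
        assert estimate_fuzzifier(2000, 3) == pytest.approx(expected,
                                                            abs=1e-6)

    def test_greater_than_one_on_grid(self):
        for n in (2, 10, 100, 10_000):
            for d in (2, 3, 10, 50):
                assert estimate_fuzzifier(n, d) > 1.0

    def test_decreasing_in_conditions(self):
        for n in (50, 500, 5000):
            values = [estimate_fuzzifier(n, d) for d in range(2, 12)]
            assert all(b < a for a, b in zip(values, values[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_fuzzifier(1, 3)


def _two_shape_profiles(n_per=4, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    up = np.array([-1.1, 0.0, 1.1])
    down = -up
    X = np.vstack([up + noise * rng.standard_normal(3) for _ in range(n_per)]
                  + [down + noise * rng.standard_normal(3)
                     for _ in range(n_per)])
    return X, np.repeat([0, 1], n_per)


class TestFuzzyCMeans:
    def test_large_fuzzifier_flattens_memberships(self):
        X, _ = _two_shape_profiles(n_per=6)
        fit = fuzzy_cmeans(X, c=3, m=100.0, seed=0)
        np.testing.assert_allclose(fit.membership, 1 / 3, atol=1e-3)

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        fit = fuzzy_cmeans(rng.standard_normal((40, 3)), c=4, m=1.5, seed=1)
        np.testing.assert_allclose(fit.membership.sum(axis=1), 1.0, atol=1e-9)
        assert ((fit.membership >= 0) & (fit.membership <= 1)).all()

    def test_matches_exhaustive_partition_oracle_on_8_points(self):
        """c=2, m=1.05 on two tight shape clusters: hard labels equal the
        best 2-partition by within-cluster sum of squares, found by
        enumerating all 127 splits of 8 points."""
        X, truth = _two_shape_profiles(n_per=4, noise=0.05, seed=3)
        fit = fuzzy_cmeans(X, c=2, m=1.05, seed=4)
        labels = fit.hard_labels

        best_cost, best_split = np.inf, None
        for r in range(1, 5):
            for subset in combinations(range(8), r):
                mask = np.zeros(8, dtype=bool)
                mask[list(subset)] = True
                cost = sum(((X[m] - X[m].mean(axis=0))**2).sum()
                           for m in (mask, ~mask))
                if cost < best_cost:
                    best_cost, best_split = cost, mask
        agree = (labels == labels[0])
        assert (agree == best_split).all() or (agree == ~best_split).all()
        # and the oracle's best split is the planted one
        assert (best_split == (truth == 0)).all() or \
               (best_split == (truth == 1)).all()

    def test_objective_nonincreasing_across_iterations(self):
        """Re-running from the previous membership cannot increase the
        objective (monotone alternating optimization)."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 3))
        prev = None
        for n_iter in (1, 2, 3, 5, 10, 50):
            fit = fuzzy_cmeans(X, c=3, m=1.6, tol=0.0, max_iter=n_iter, seed=6)
            if prev is not None:
                assert fit.objective <= prev + 1e-9
            prev = fit.objective

    def test_invalid_cluster_count_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_cmeans(np.ones((5, 3)), c=5, m=1.5)


class TestMinCentroidDistance:
    def test_dmin_drops_beyond_true_shape_count(self):
        X, _ = _two_shape_profiles(n_per=30, noise=0.05, seed=7)
        table = min_centroid_distance(X, m=1.3, c_range=[2, 3], seed=8)
        assert table.loc[2, "dmin"] > table.loc[3, "dmin"]

    def test_dmin_nonnegative(self):
        rng = np.random.default_rng(9)
        table = min_centroid_distance(rng.standard_normal((40, 3)), m=1.5,
                                      c_range=[2, 3, 4], seed=10)
        assert (table["dmin"] >= 0).all()

    def test_single_shape_gives_near_zero_dmin(self):
        X = np.tile(np.array([-1.0, 0.0, 1.0]), (20, 1))
        table = min_centroid_distance(X, m=1.5, c_range=[2, 3], seed=11)
        assert (table["dmin"] < 1e-6).all()


def _clustering_from_centroids(centroids, gene_clusters, membership=0.9):
    genes = [f"g{i}" for i in range(len(gene_clusters))]
    c = len(centroids)
    U = np.full((len(genes), c), (1 - membership) / max(c - 1, 1))
    for i, ci in enumerate(gene_clusters):
        U[i, ci] = membership
    return FuzzyClustering(centroids=np.asarray(centroids, dtype=float),
                           membership=U, fuzzifier=1.5, objective=0.0,
                           converged=True, genes=genes)


def _deg_table(entries):
    """entries: gene -> direction ('up'/'down') or None."""
    genes = list(entries)
    return pd.DataFrame({
        "is_deg": [entries[g] is not None for g in genes],
        "direction": [entries[g] or "flat" for g in genes],
    }, index=genes)


class TestClassifyPatterns:
    def test_rule_application_on_worked_shapes(self):
        clustering = _clustering_from_centroids(
            [[-1.22, 0.0, 1.22],    # increasing
             [-0.5, 1.2, -0.7],     # JH-high
             [0.6, -1.3, 0.7],      # JH-low
             [1.22, 0.0, -1.22]],   # decreasing
            gene_clusters=[0, 1, 2, 3, 1])
        deg_awb = _deg_table({"g0": "up", "g1": "up", "g2": "down",
                              "g3": "down", "g4": None})
        deg_du = _deg_table({"g0": None, "g1": "up", "g2": "down",
                             "g3": None, "g4": "up"})
        out = classify_patterns(clustering, deg_awb, deg_du)
        assert out.loc["g0", "pattern"] == "type1"
        assert out.loc["g1", "pattern"] == "type2"
        assert out.loc["g2", "pattern"] == "type3"
        assert out.loc["g3", "pattern"] == "type4"
        # high membership but JH-high shape with only one up call -> none
        assert out.loc["g4", "pattern"] == "none"

    def test_no_deg_evidence_gives_none(self):
        clustering = _clustering_from_centroids([[-1.0, 0.0, 1.0],
                                                 [1.0, 0.0, -1.0]],
                                                gene_clusters=[0, 1])
        empty = _deg_table({"g0": None, "g1": None})
        out = classify_patterns(clustering, empty, empty)
        assert (out["pattern"] == "none").all()

    def test_patterns_exclusive_and_exhaustive(self):
        rng = np.random.default_rng(13)
        centroids = rng.standard_normal((5, 3))
        clustering = _clustering_from_centroids(
            centroids, gene_clusters=rng.integers(0, 5, size=40))
        degs = _deg_table({f"g{i}": rng.choice(["up", "down", None])
                           for i in range(40)})
        out = classify_patterns(clustering, degs, degs)
        assert set(out["pattern"]) <= {"type1", "type2", "type3", "type4",
                                       "none"}

    def test_planted_pattern_recovery(self):
        """400 planted genes (100 per pattern, noise sd 0.2) + 600 nulls:
        >= 85% of planted genes recover their pattern, <= 5% of nulls
        classified."""
        rng = np.random.default_rng(14)
        shapes = {
            "type1": np.array([-1.2, 0.0, 1.2]),
            "type2": np.array([-0.7, 1.4, -0.7]),
            "type3": np.array([0.7, -1.4, 0.7]),
            "type4": np.array([1.2, 0.0, -1.2]),
        }
        rows, expected, deg_awb, deg_du = [], [], {}, {}
        gi = 0
        for pattern, shape in shapes.items():
            for _ in range(100):
                rows.append(shape + 0.2 * rng.standard_normal(3))
                expected.append(pattern)
                g = f"g{gi}"
                if pattern == "type1":
                    deg_awb[g], deg_du[g] = "up", "down"
                elif pattern == "type2":
                    deg_awb[g], deg_du[g] = "up", "up"
                elif pattern == "type3":
                    deg_awb[g], deg_du[g] = "down", "down"
                else:
                    deg_awb[g], deg_du[g] = "down", "up"
                gi += 1
        for _ in range(600):
            row = rng.standard_normal(3)
            row = (row - row.mean()) / row.std()
            rows.append(row)
            expected.append("none")
            deg_awb[f"g{gi}"] = deg_du[f"g{gi}"] = None
            gi += 1
        profiles = pd.DataFrame(rows, index=[f"g{i}" for i in range(gi)],
                                columns=["AWB", "JH", "DU"])
        # moderate fuzziness: with only three conditions the empirical
        # fuzzifier estimate is large and memberships too flat to clear the
        # 0.5 core threshold, so the shape rules are exercised at m = 1.5
        fit = fuzzy_cmeans(profiles, c=9, m=1.5, seed=15)
        out = classify_patterns(fit, _deg_table(deg_awb), _deg_table(deg_du))
        expected = np.asarray(expected)
        planted = expected != "none"
        recovery = (out["pattern"].to_numpy()[planted]
                    == expected[planted]).mean()
        null_called = (out["pattern"].to_numpy()[~planted] != "none").mean()
        assert recovery >= 0.85
        assert null_called <= 0.05
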