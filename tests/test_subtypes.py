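"""CCA matching and robust marker discovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from caflineage import subtypes
from caflineage.errors import DataError


def cca_oracle(X, Y):
    """Generalized-eigenvalue CCA: eigenvalues of Sxx^-1 Sxy Syy^-1 Syx are
    the squared canonical correlations."""
    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    n = X.shape[0]
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    ev = np.linalg.eigvals(M).real
    ev = np.clip(ev, 0, 1)
    return np.sqrt(np.sort(ev)[::-1])


class TestCanonicalCorrelations:
    def test_self_correlation_is_one(self, rng):
        X = rng.normal(size=(30, 4))
        cc = subtypes.canonical_correlations(X, X, eps=0.0)
        assert cc[0] == pytest.approx(1.0, abs=1e-8)

    def test_single_cell_columns_reduce_to_pearson(self, rng):
        x = rng.normal(size=(50, 2))
        y = x @ np.array([[1.0, 0.3], [0.3, 1.0]]) + 0.1 * rng.normal(size=(50, 2))
        cc = subtypes.canonical_correlations(x[:, :2], y[:, :2], eps=0.0)
        # first canonical correlation >= |pearson| of any column pair
        r = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert cc[0] >= r - 1e-12

    def test_matches_generalized_eigenvalue_oracle(self, rng):
        for _ in range(30):
            f = rng.integers(12, 21)  # observations (features)
            cx, cy = rng.integers(2, 6), rng.integers(2, 6)
            X = rng.normal(size=(f, cx))
            Y = rng.normal(size=(f, cy))
            cc = subtypes.canonical_correlations(X, Y, eps=0.0)
            expected = cca_oracle(X, Y)[: len(cc)]
            np.testing.assert_allclose(cc, expected, atol=1e-6)

    def test_symmetry_and_monotone_vector(self, rng):
        X, Y = rng.normal(size=(15, 4)), rng.normal(size=(15, 5))
        c1 = subtypes.canonical_correlations(X, Y, eps=1e-3)
        c2 = subtypes.canonical_correlations(Y, X, eps=1e-3)
        np.testing.assert_allclose(c1, c2, atol=1e-10)
        assert np.all(np.diff(c1) <= 1e-12) and np.all((c1 >= 0) & (c1 <= 1))

    def test_invariant_to_invertible_remixing_of_cell_variables(self, rng):
        X, Y = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        c1 = subtypes.canonical_correlations(X, Y, eps=0.0)
        c2 = subtypes.canonical_correlations(X @ A, Y, eps=0.0)
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_rank_deficiency_needs_ridge(self, rng):
        X = rng.normal(size=(10, 8))  # 8 cell variables, 10 observations
        X[:, 1] = X[:, 0]
        Y = rng.normal(size=(10, 3))
        with pytest.raises(DataError, match="ridge"):
            subtypes.canonical_correlations(X, Y, eps=0.0)
        cc = subtypes.canonical_correlations(X, Y, eps=1e-3)
        assert np.all((cc >= 0) & (cc <= 1))


class TestMatchClusters:
    def _program_profiles(self, rng, n_samples, programs, cells=12, feats=40):
        """Each sample has one cluster per program; a program elevates its
        own block of features."""
        out = {}
        for s in range(n_samples):
            clusters = {}
            order = rng.permutation(len(programs))
            for ci, prog in enumerate(order):
                base = rng.normal(0, 0.3, size=(feats, cells))
                lo = prog * (feats // len(programs))
                hi = lo + feats // len(programs)
                base[lo:hi] += 3.0
                clusters[ci] = base
            out[f"S{s + 1}"] = (clusters, order)
        profiles = {s: c for s, (c, _) in out.items()}
        truth = {s: o for s, (_, o) in out.items()}
        return profiles, truth

    def test_two_samples_two_programs_matched(self, rng):
        profiles, truth = self._program_profiles(rng, 2, range(2))
        cmap = subtypes.match_clusters(profiles)
        for group in cmap.merged:
            progs = {truth[s][c] for s, c in group}
            assert len(progs) == 1

    def test_three_samples_planted_permutation_recovered(self, rng):
        profiles, truth = self._program_profiles(rng, 3, range(4))
        cmap = subtypes.match_clusters(profiles)
        correct = 0
        total = 0
        for group in cmap.merged:
            progs = [truth[s][c] for s, c in group]
            total += len(group)
            if len(set(progs)) == 1 and len(group) == 3:
                correct += len(group)
        assert correct / total >= 0.95

    def test_duplicated_cluster_breaks_tie_at_depth_two(self, rng):
        X = rng.normal(size=(30, 6))
        Y = X + 0.05 * rng.normal(size=(30, 6))
        profiles = {"S1": {0: X, 1: X.copy()}, "S2": {0: Y}}
        cmap = subtypes.match_clusters(profiles)
        # S2:0 joined exactly one of the identical S1 clusters
        sizes = sorted(len(g) for g in cmap.merged)
        assert sizes == [1, 2]
        assert cmap.assignment["tie_depth"].max() >= 2

    def test_single_cluster_per_sample_is_one_subtype(self, rng):
        profiles = {
            "S1": {0: rng.normal(size=(20, 5))},
            "S2": {0: rng.normal(size=(20, 5))},
        }
        cmap = subtypes.match_clusters(profiles)
        assert cmap.assignment["subtype"].nunique() == 1

    def test_requires_two_samples(self, rng):
        with pytest.raises(DataError):
            subtypes.match_clusters({"S1": {0: rng.normal(size=(10, 4))}})


class TestWilcoxonDE:
    def test_exact_small_sample_p(self):
        nm = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        out = subtypes.wilcoxon_de(
            nm, ["g"], np.array([0, 1, 2]), np.array([3, 4, 5]),
            min_positive_fraction=0.0,
        )
        assert out.loc["g", "p"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups(self):
        nm = np.tile(np.array([[1.0], [2.0], [3.0]]), (2, 1))
        out = subtypes.wilcoxon_de(
            nm, ["g"], np.array([0, 1, 2]), np.array([3, 4, 5]),
            min_positive_fraction=0.0,
        )
        assert out.loc["g", "p"] == pytest.approx(1.0)
        assert out.loc["g", "log2fc"] == pytest.approx(0.0)

    def test_vectorized_matches_scipy_per_gene(self, rng):
        nm = rng.lognormal(0, 1, size=(60, 15))
        nm[: 30, :5] *= 3
        a, b = np.arange(30), np.arange(30, 60)
        out = subtypes.wilcoxon_de(nm, [f"g{i}" for i in range(15)], a, b,
                                   min_positive_fraction=0.0)
        for g in out.index[:8]:
            j = int(g[1:])
            ref = stats.mannwhitneyu(
                nm[a, j], nm[b, j], alternative="two-sided", method="asymptotic"
            ).pvalue
            assert out.loc[g, "p"] == pytest.approx(ref, rel=1e-9)

    def test_planted_program_gene_significant(self, rng):
        n_a, n_b = 200, 500
        nm = rng.lognormal(0, 0.5, size=(n_a + n_b, 10))
        nm[:n_a, 0] *= 2.5
        out = subtypes.wilcoxon_de(
            nm, [f"g{i}" for i in range(10)], np.arange(n_a),
            np.arange(n_a, n_a + n_b), min_positive_fraction=0.0,
        )
        assert out.loc["g0", "p_adj"] < 0.001
        assert out.loc["g0", "log2fc"] > 0


class TestRobustMarkers:
    def _tables(self):
        t1 = pd.DataFrame(
            {"p": [1e-10, 1e-8, 1e-6, 0.5], "log2fc": [2.0, 1.0, -1.0, 0.3]},
            index=["A", "B", "C", "D"],
        )
        t2 = pd.DataFrame(
            {"p": [1e-9, 1e-7, 1e-5, 0.4], "log2fc": [1.5, -0.5, -0.8, 0.2]},
            index=["A", "B", "C", "D"],
        )
        return {"S1": t1, "S2": t2}

    def test_consistent_sign_retained_and_flip_removed(self):
        out = subtypes.robust_markers(self._tables(), top_n=3)
        assert "A" in out.index  # positive in both
        assert "C" in out.index  # negative in both
        assert "B" not in out.index  # +/- flip
        assert out.loc["A", "mean_p"] == pytest.approx((1e-10 + 1e-9) / 2)

    def test_gene_outside_top_n_excluded(self):
        out = subtypes.robust_markers(self._tables(), top_n=2)
        assert "C" not in out.index

    def test_order_invariant_to_sample_ordering(self):
        t = self._tables()
        a = subtypes.robust_markers({"S1": t["S1"], "S2": t["S2"]})
        b = subtypes.robust_markers({"S2": t["S2"], "S1": t["S1"]})
        assert list(a.index) == list(b.index)

    def test_requires_two_tables(self):
        with pytest.raises(DataError):
            subtypes.robust_markers({"S1": self._tables()["S1"]})
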