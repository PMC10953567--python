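import numpy as np
import pandas as pd
import pytest

from phosig.errors import ValidationError
from phosig.explore import (
    correlation_matrix,
    cut_k,
    hcluster,
    pca_with_ellipses,
    to_newick,
)

from conftest import tiny_sheet


def naive_average_agglomeration(D: np.ndarray) -> list[float]:
    """O(n^3) average-linkage agglomeration oracle; returns merge heights."""
    clusters = {i: [i] for i in range(len(D))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return heights


class TestCorrelation:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20)
        X = pd.DataFrame({"a": x, "b": x, "c": -x})
        r = correlation_matrix(X).r
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)

    def test_hand_pearson_on_3x4(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [2.0, 1.0, 3.0],
                          "c": [1.0, 1.0, 2.0], "d": [5.0, 4.0, 1.0]})
        r = correlation_matrix(X).r
        for u in X:
            for v in X:
                xm, ym = X[u] - X[u].mean(), X[v] - X[v].mean()
                hand = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
                assert r.loc[u, v] == pytest.approx(hand)

    def test_pairwise_complete_counts(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0, 4.0], "b": [1.0, 2.0, np.nan, 4.0]})
        out = correlation_matrix(X)
        assert out.n.loc["a", "b"] == 2


class TestHcluster:
    def test_identical_rows_merge_at_zero(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0]] * 2 + [[9.0, 1.0, 5.0]],
                         index=["a", "b", "c"])
        d = hcluster(X, distance="euclidean")
        assert d.heights[0] == pytest.approx(0.0)

    def test_coincident_pair_merges_first(self):
        X = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]],
                         index=["a", "b", "c"])
        d = hcluster(X, distance="euclidean")
        first = set(d.Z[0, :2].astype(int))
        assert first == {0, 1}

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            hcluster(pd.DataFrame([[1.0, 2.0]], index=["a"]))

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_heights_match_naive_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        X = pd.DataFrame(rng.normal(0, 1, size=(n, 4)))
        d = hcluster(X, distance="euclidean", linkage="average")
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(X.to_numpy()))
        oracle = naive_average_agglomeration(D)
        assert d.heights == pytest.approx(oracle)

    def test_newick_rendering_contains_all_leaves(self):
        X = pd.DataFrame(np.eye(4), index=list("abcd"))
        nwk = to_newick(hcluster(X, distance="euclidean"))
        assert all(leaf in nwk for leaf in "abcd") and nwk.endswith(";")


class TestCutK:
    def test_k_equals_n_gives_singletons(self):
        X = pd.DataFrame(np.diag([1.0, 2.0, 3.0, 4.0]), index=list("abcd"))
        d = hcluster(X, distance="euclidean")
        labs = cut_k(d, 4).labels
        assert labs.nunique() == 4

    def test_k_one_gives_single_cluster(self):
        X = pd.DataFrame(np.diag([1.0, 2.0, 3.0]), index=list("abc"))
        assert cut_k(hcluster(X, distance="euclidean"), 1).labels.nunique() == 1

    def test_four_planted_profiles_recovered_up_to_relabeling(self):
        rng = np.random.default_rng(5)
        centers = np.array([[5, 0, 0, 0], [0, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 5]],
                           dtype=float)
        rows, truth = [], []
        for c in range(4):
            for _ in range(10):
                rows.append(np.tile(centers[c], 2) + rng.normal(0, 0.2, 8))
                truth.append(c)
        X = pd.DataFrame(rows, index=[f"f{i}" for i in range(40)],
                         columns=[f"S{i + 1}" for i in range(8)])
        d = hcluster(X, distance="euclidean", linkage="average")
        labs = cut_k(d, 4, X, tiny_sheet()).labels
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labs.to_numpy()) == pytest.approx(1.0)

    def test_profiles_have_cluster_by_group_shape(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(0, 1, (12, 8)),
                         index=[f"f{i}" for i in range(12)],
                         columns=[f"S{i + 1}" for i in range(8)])
        d = hcluster(X, distance="euclidean")
        prof = cut_k(d, 3, X, tiny_sheet()).profiles
        assert prof.shape == (3, 4)


class TestPca:
    def _sheet(self):
        return tiny_sheet(n_per_group=(3, 3, 0, 0))

    def _matrix(self, arr):
        return pd.DataFrame(np.asarray(arr).T,
                            index=[f"f{i}" for i in range(np.shape(arr)[1])],
                            columns=[f"S{i + 1}" for i in range(np.shape(arr)[0])])

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        m = self._matrix(rng.normal(0, 1, (6, 10)))
        res = pca_with_ellipses(m, self._sheet())
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_collinear_data_loads_on_first_component(self):
        t = np.arange(6.0)
        arr = np.column_stack([t, 2 * t, -t, 3 * t])
        res = pca_with_ellipses(self._matrix(arr), self._sheet())
        assert res.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_match_eigendecomposition_oracle_up_to_sign(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(0, 1, (6, 5))
        m = self._matrix(arr)
        res = pca_with_ellipses(m, self._sheet())
        Xc = (arr - arr.mean(0)) / arr.std(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        oracle = Xc @ evecs[:, order]
        for j in range(min(3, oracle.shape[1])):
            got = res.scores.iloc[:, j].to_numpy()
            assert (np.allclose(got, oracle[:, j], atol=1e-8)
                    or np.allclose(got, -oracle[:, j], atol=1e-8))

    def test_scores_invariant_to_feature_reordering(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(0, 1, (6, 8))
        m = self._matrix(arr)
        res1 = pca_with_ellipses(m, self._sheet())
        res2 = pca_with_ellipses(m.sample(frac=1, random_state=0), self._sheet())
        pd.testing.assert_frame_equal(res1.scores, res2.scores)

    def test_small_group_ellipse_omitted_with_warning(self, caplog):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(0, 1, (5, 4)),
                         index=[f"f{i}" for i in range(5)],
                         columns=["S1", "S2", "S3", "S4"])
        sheet = tiny_sheet(n_per_group=(2, 2, 0, 0))
        with caplog.at_level("WARNING"):
            res = pca_with_ellipses(m, sheet)
        assert res.ellipses == {}
        assert any("ellipse omitted" in r.message for r in caplog.records)

    def test_isotropic_scores_give_near_circular_ellipse(self):
        rng = np.random.default_rng(6)
        n = 60
        arr = rng.normal(0, 1, (n, 40))
        m = pd.DataFrame(arr.T, index=[f"f{i}" for i in range(40)],
                         columns=[f"S{i + 1}" for i in range(n)])
        sheet = tiny_sheet(n_per_group=(n, 0, 0, 0))
        res = pca_with_ellipses(m, sheet)
        a, b = res.ellipses["DA-CR"]["semi_axes"]
        assert 0.5 < b / a <= 1.0
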