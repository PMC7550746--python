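import numpy as np
import pandas as pd
import pytest

from wristband import preprocess as pp
from wristband import som_profiles as sp
from .conftest import make_matrix


def brute_validity(X, labels):
    """Independent pairwise-loop computation of all five statistics."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    n, k = len(X), len(uniq)
    d = lambda i, j: float(np.sqrt(((X[i] - X[j]) ** 2).sum()))

    wss = 0.0
    for u in uniq:
        pts = X[labels == u]
        cen = pts.mean(axis=0)
        wss += float(((pts - cen) ** 2).sum())
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    bss = tss - wss

    dists, gaps = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(d(i, j))
            gaps.append(0.0 if labels[i] == labels[j] else 1.0)
    inter = [x for x, g in zip(dists, gaps) if g == 1]
    diam = 0.0
    for u in uniq:
        idx = np.flatnonzero(labels == u)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                diam = max(diam, d(idx[a], idx[b]))
    dunn = (min(inter) / diam) if diam > 0 else np.inf

    sil = []
    for i in range(n):
        own = np.flatnonzero((labels == labels[i]))
        if len(own) == 1:
            sil.append(0.0)
            continue
        a = np.mean([d(i, j) for j in own if j != i])
        b = min(
            np.mean([d(i, j) for j in np.flatnonzero(labels == u)])
            for u in uniq if u != labels[i]
        )
        sil.append((b - a) / max(a, b))
    gamma = float(np.corrcoef(dists, gaps)[0, 1])
    return {
        "wss_bss_ratio": wss / bss,
        "calinski_harabasz": (bss / (k - 1)) / (wss / (n - k)),
        "dunn": dunn,
        "mean_silhouette": float(np.mean(sil)),
        "pearson_gamma": gamma,
    }


def planted_benchmark(seed, n=200, d=16, k=4, shift=3.0):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, k, n)
    X = rng.normal(0, 1, (n, d))
    block = d // k
    for c in range(k):
        X[labels == c, block * c:block * (c + 1)] += shift
    return X, labels


class TestClusterValidity:
    def test_hand_derived_four_point_instance(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = [0, 0, 1, 1]
        stats_ = sp.cluster_validity(X, labels)
        assert stats_["wss_bss_ratio"] == pytest.approx(0.01, abs=1e-12)
        assert stats_["calinski_harabasz"] == pytest.approx(200.0, abs=1e-9)
        assert stats_["dunn"] == pytest.approx(9.0, abs=1e-12)
        # mean of per-point widths (9.5/10.5, 8.5/9.5) x2; corr of 6 pair
        # distances with the split indicator
        assert stats_["mean_silhouette"] == pytest.approx(
            (9.5 / 10.5 + 8.5 / 9.5) / 2, abs=1e-12
        )
        assert stats_["pearson_gamma"] == pytest.approx(
            12 / np.sqrt(110 * 4 / 3), abs=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (24, 5))
        labels = rng.integers(0, 4, 24)
        got = sp.cluster_validity(X, labels)
        want = brute_validity(X, labels)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-9), key

    def test_matches_sklearn_oracles(self):
        from sklearn.metrics import calinski_harabasz_score, silhouette_score

        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (30, 4))
        labels = rng.integers(0, 3, 30)
        got = sp.cluster_validity(X, labels)
        assert got["calinski_harabasz"] == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-9
        )
        assert got["mean_silhouette"] == pytest.approx(
            silhouette_score(X, labels), rel=1e-9
        )

    def test_coincident_clusters_have_zero_dunn(self):
        X = np.array([[1.0, 2.0]] * 4 + [[5.0, 5.0]] * 2)
        labels = [0, 0, 1, 1, 2, 2]
        assert sp.cluster_validity(X, labels)["dunn"] == 0.0

    def test_single_cluster_is_error(self):
        with pytest.raises(ValueError, match="2 occupied"):
            sp.cluster_validity(np.eye(4), [1, 1, 1, 1])


class TestTrainSOM:
    def test_deterministic_for_fixed_seed(self):
        X = np.random.default_rng(0).normal(0, 1, (60, 6))
        f1 = sp.train_som(X, 2, 3, seed=4)
        f2 = sp.train_som(X, 2, 3, seed=4)
        assert np.array_equal(f1.grid.codebook, f2.grid.codebook)
        assert np.array_equal(f1.assignment, f2.assignment)

    def test_interpolation_limit_reproduces_points(self):
        # k = n distinct well-separated points, final radius 0
        X = np.arange(6)[:, None] * 100.0 + np.zeros((6, 3))
        fit = sp.train_som(X, 2, 3, sp.SOMParams(epochs=50), seed=1)
        assert fit.quantization_error < 1e-6

    def test_duplicated_dataset_trains_same_codebook(self):
        X = np.random.default_rng(3).normal(0, 1, (50, 4))
        f1 = sp.train_som(X, 2, 2, seed=3)
        f2 = sp.train_som(np.vstack([X, X]), 2, 2, seed=3)
        np.testing.assert_allclose(f1.grid.codebook, f2.grid.codebook, atol=1e-9)

    def test_quantization_error_monotone_in_final_epochs(self):
        X = np.random.default_rng(2).normal(0, 1, (200, 8))
        fit = sp.train_som(X, 3, 4, seed=2)
        tail = fit.qe_history[-max(1, len(fit.qe_history) // 10):]
        assert np.max(np.diff(tail)) <= 1e-6

    def test_zero_radius_matches_kmeans_objective(self):
        from sklearn.cluster import KMeans

        X, _ = planted_benchmark(7)
        fit = sp.train_som(X, 2, 2, seed=0)
        km = KMeans(4, n_init=10, random_state=0).fit(X)

        def wss(labels):
            return sum(
                float(((X[labels == u] - X[labels == u].mean(axis=0)) ** 2).sum())
                for u in np.unique(labels)
            )

        assert wss(fit.assignment) <= 1.05 * wss(km.labels_)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            sp.train_som(np.eye(3), 2, 2)


class TestAssignProfiles:
    def test_codebook_vector_maps_to_its_node(self):
        X = np.random.default_rng(1).normal(0, 1, (40, 3))
        fit = sp.train_som(X, 2, 2, seed=1)
        lab = sp.assign_profiles(fit, fit.grid.codebook)
        assert list(lab) == [0, 1, 2, 3]

    def test_tie_breaks_to_lower_node_index(self):
        fit = sp.train_som(np.array([[0.0], [1.0], [2.0], [3.0]]) * 10, 2, 2,
                           sp.SOMParams(epochs=30), seed=0)
        cb = np.sort(fit.grid.codebook.ravel())
        fit.grid.codebook = cb[:, None]
        midpoint = (cb[1] + cb[2]) / 2
        # equidistant to nodes 1 and 2 -> node 1
        assert sp.assign_profiles(fit, [[midpoint]])[0] in (1,)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (30, 4))
        fit = sp.train_som(X, 2, 3, seed=5)
        lab = sp.assign_profiles(fit, X)
        brute = [
            int(np.argmin([((x - c) ** 2).sum() for c in fit.grid.codebook]))
            for x in X
        ]
        assert list(lab) == brute

    def test_dimension_mismatch_rejected(self):
        X = np.random.default_rng(1).normal(0, 1, (20, 3))
        fit = sp.train_som(X, 2, 2, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            sp.assign_profiles(fit, np.ones((2, 5)))


class TestSelectSOMSize:
    def test_planted_profiles_recovered(self):
        X, truth = planted_benchmark(0)
        report, fit = sp.select_som_size(X, seed=0)
        assert 4 <= fit.n_occupied <= 6
        assert sp.adjusted_rand_index(truth, fit.assignment) >= 0.9

    def test_restricted_candidate_list_returned(self):
        X, _ = planted_benchmark(1)
        report, fit = sp.select_som_size(X, candidates=[(3, 4)], seed=1)
        assert report.selected == (3, 4)
        assert fit.grid.n_nodes == 12

    def test_permutation_invariance_of_selection(self):
        X, _ = planted_benchmark(2, n=120)
        rng = np.random.default_rng(0)
        r1, _ = sp.select_som_size(X, seed=6)
        r2, _ = sp.select_som_size(X[rng.permutation(len(X))], seed=6)
        assert r1.selected == r2.selected

    def test_candidate_outside_profile_range_rejected(self):
        X, _ = planted_benchmark(3)
        with pytest.raises(ValueError, match="4-25"):
            sp.select_som_size(X, candidates=[(1, 3)], seed=0)

    def test_candidate_enumeration_bounds(self):
        grids = sp.candidate_grids()
        assert all(4 <= r * c <= 25 and r <= c for r, c in grids)
        assert (3, 4) in grids and (5, 5) in grids and (1, 25) in grids


class TestCharacterizeProfiles:
    def _fit_and_std(self):
        X, truth = planted_benchmark(4, n=120)
        m = make_matrix(np.abs(X) + 1.0)  # only used for sample metadata
        std = pp.StandardizedMatrix(
            pd.DataFrame(X, index=m.values.index, columns=m.values.columns),
            m.samples, pd.DataFrame(), None, None,
        )
        fit = sp.train_som(X, 2, 2, seed=4)
        return fit, std, truth

    def test_shifted_chemicals_flagged_exceptional(self):
        fit, std, truth = self._fit_and_std()
        report = sp.characterize_profiles(fit, std)
        flagged = set()
        for p in report["profiles"].values():
            flagged |= set(p["exceptional_chemicals"])
        assert len(flagged) >= 12  # each planted block is high in its profile

    def test_small_profiles_listed_rare(self):
        X = np.vstack([np.zeros((20, 2)), np.full((2, 2), 8.0), np.full((15, 2), -6.0),
                       np.full((12, 2), 3.0)])
        m = make_matrix(np.abs(X))
        std = pp.StandardizedMatrix(
            pd.DataFrame(X, index=m.values.index, columns=m.values.columns),
            m.samples, pd.DataFrame(), None, None,
        )
        fit = sp.train_som(X, 2, 2, sp.SOMParams(epochs=40), seed=0)
        report = sp.characterize_profiles(fit, std, min_n=10)
        sizes = {p["n"]: p["rare"] for p in report["profiles"].values()}
        assert sizes[2] is True
        assert sizes[20] is False

    def test_covariate_percentages_sum_to_100(self, default_cohort):
        _, matrix, cov, _, _ = default_cohort
        filtered = pp.filter_by_detection(matrix)
        std = pp.batch_standardize(filtered)
        fit = sp.train_som(std, 2, 2, seed=0)
        report = sp.characterize_profiles(fit, std, cov, min_n=10)
        checked = 0
        for p in report["profiles"].values():
            if p["rare"]:
                continue
            for col, summary in p["covariates"].items():
                if "median" in summary:
                    continue
                total = sum(summary.values())
                assert abs(total - 100) <= len(summary)  # rounding slack
                checked += 1
        assert checked > 0


class TestAdjustedRandIndex:
    def test_perfect_and_permuted_labelings(self):
        a = [0, 0, 1, 1, 2, 2]
        assert sp.adjusted_rand_index(a, a) == 1.0
        assert sp.adjusted_rand_index(a, [5, 5, 9, 9, 7, 7]) == 1.0

    def test_matches_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 4, 50), rng.integers(0, 3, 50)
        assert sp.adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_score(a, b), abs=1e-12
        )
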