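import numpy as np
import pandas as pd
import pytest
import scipy.stats

from morphocavity.geometry_io import LandmarkConfiguration
from morphocavity.procrustes import gpa
from morphocavity.shape_stats import (
    anova_per_axis,
    benjamini_hochberg,
    chi_square_test,
    cluster_count_vote,
    kruskal_wallis_test,
    lins_ccc,
    manova_per_landmark,
    pca_stability_resampling,
    repeatability_report,
    select_cluster_count,
    select_components_elbow,
    shape_pca,
    tukey_pairwise,
    ward_tree,
    within_inertia_profile,
)


def make_blobs(centers, n_per=20, sd=0.1, seed=0, dim=None):
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, float)
    dim = dim or centers.shape[1]
    X = np.concatenate(
        [c + rng.normal(scale=sd, size=(n_per, dim)) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels


def aligned_population(n=20, k=10, sd=0.05, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(k, 3))
    return gpa(base + rng.normal(scale=sd, size=(n, k, 3)))


class TestShapePCA:
    def test_rank_one_variation(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 3))
        direction = rng.normal(size=(10, 3))
        configs = np.stack([base + t * direction for t in np.linspace(-1, 1, 15)])
        pca = shape_pca(configs.reshape(15, -1))
        assert pca.explained_ratio[0] >= 0.999

    def test_spectrum_sums_to_one(self):
        sample = aligned_population()
        pca = shape_pca(sample)
        assert pca.explained_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(pca.explained_ratio) <= 1e-12)

    def test_scores_centered_and_reconstruct(self):
        sample = aligned_population()
        pca = shape_pca(sample)
        assert np.abs(pca.scores.mean(axis=0)).max() < 1e-10
        recon = pca.reconstruct()
        assert np.abs(recon - sample.flattened()).max() < 1e-8

    def test_eigenvalues_match_characteristic_polynomial_roots(self):
        """10x6 toy matrix: eigenvalues equal the roots of the characteristic
        polynomial of the covariance, found independently with numpy.roots."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        pca = shape_pca(X)
        cov = np.cov(X, rowvar=False)
        roots = np.roots(np.poly(cov))
        roots = np.sort(np.real(roots))[::-1]
        assert np.abs(pca.eigenvalues - roots[: len(pca.eigenvalues)]).max() < 1e-10

    def test_sign_convention(self):
        sample = aligned_population(seed=3)
        pca = shape_pca(sample)
        for row in pca.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            shape_pca(np.zeros((2, 6)))


class TestElbow:
    def test_two_regime_spectrum_matches_distance_oracle(self):
        spectrum = [0.5, 0.3, 0.05, 0.05, 0.05, 0.05]
        assert select_components_elbow(spectrum) == self._oracle(spectrum)
        # the stated chord rule puts the elbow at 3 for this spectrum
        assert select_components_elbow(spectrum) == 3

    def test_geometric_decay_matches_oracle(self):
        y = np.array([0.5**k for k in range(1, 11)])
        y = y / y.sum()
        assert select_components_elbow(y) == self._oracle(y)

    def test_flat_spectrum_returns_one(self):
        assert select_components_elbow([0.25, 0.25, 0.25, 0.25]) == 1

    def test_single_value(self):
        assert select_components_elbow([1.0]) == 1

    @staticmethod
    def _oracle(spectrum):
        """Explicit brute-force loop over chord distances."""
        y = np.asarray(spectrum, float)
        m = len(y)
        x0, y0, x1, y1 = 1.0, y[0], float(m), y[-1]
        chord = np.hypot(x1 - x0, y1 - y0)
        best_i, best_d = 1, -1.0
        for i in range(m):
            d = abs((x1 - x0) * (y0 - y[i]) - (x0 - (i + 1)) * (y1 - y0)) / chord
            if d > best_d + 1e-15:
                best_d, best_i = d, i + 1
        return best_i


class TestStability:
    def test_full_size_sd_zero(self):
        sample = aligned_population(n=15)
        table = pca_stability_resampling(sample, [15], reps=5, m=3, seed=0)
        assert table["sd"].iloc[0] < 1e-12  # single possible subset

    def test_deterministic_with_seed(self):
        sample = aligned_population(n=20)
        t1 = pca_stability_resampling(sample, [10, 15], reps=1, m=3, seed=9)
        t2 = pca_stability_resampling(sample, [10, 15], reps=1, m=3, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_size_too_large_rejected(self):
        sample = aligned_population(n=10)
        with pytest.raises(ValueError):
            pca_stability_resampling(sample, [11], reps=2)

    def test_mean_curve_flattens(self):
        # population with genuine 5-mode structure plus small isotropic noise
        rng = np.random.default_rng(4)
        base = rng.normal(size=(10, 3))
        modes = rng.normal(size=(5, 10, 3))
        amps = np.array([1.0, 0.7, 0.5, 0.35, 0.25])
        configs = np.stack(
            [
                base
                + np.tensordot(amps * rng.normal(size=5), modes, axes=1)
                + rng.normal(scale=0.02, size=(10, 3))
                for _ in range(60)
            ]
        )
        sample = gpa(configs)
        table = pca_stability_resampling(sample, range(20, 61, 10), reps=30, m=5, seed=0)
        means = table["mean"].to_numpy()
        assert abs(means[-1] - means[-2]) < 0.02


class TestWard:
    def test_three_blobs_recovered(self):
        X, truth = make_blobs([[0, 0], [10, 0], [0, 10]], n_per=15, sd=0.1, seed=5)
        tree = ward_tree(X)
        labels = tree.cut(3)
        # identical partition up to renaming
        for g in range(3):
            assert len(np.unique(labels[truth == g])) == 1
        assert len(np.unique(labels)) == 3

    def test_two_points_single_merge(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        tree = ward_tree(X)
        assert tree.linkage.shape[0] == 1
        assert tree.linkage[0, 2] == pytest.approx(5.0)

    def test_total_inertia_conservation(self):
        X, _ = make_blobs([[0, 0], [5, 5]], n_per=10, seed=6)
        tree = ward_tree(X)
        W1 = within_inertia_profile(tree, 1, 1)[1]
        total = np.sum((X - X.mean(axis=0)) ** 2)
        assert W1 == pytest.approx(total, abs=1e-9)

    def test_inertia_strictly_decreasing(self):
        X, _ = make_blobs([[0, 0], [4, 0], [0, 4]], n_per=10, sd=0.5, seed=7)
        tree = ward_tree(X)
        W = within_inertia_profile(tree, 1, 8)
        vals = [W[k] for k in sorted(W)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestClusterCount:
    def test_three_blobs(self):
        X, _ = make_blobs([[0, 0], [10, 0], [0, 10]], n_per=20, sd=0.1, seed=8)
        assert select_cluster_count(ward_tree(X)) == 3

    def test_two_blobs(self):
        X, _ = make_blobs([[0, 0, 0], [10, 10, 10]], n_per=20, sd=0.2, seed=9)
        assert select_cluster_count(ward_tree(X)) == 2

    def test_single_gaussian_flagged_low_confidence(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 3))
        k, ratios, low_conf = select_cluster_count(ward_tree(X), return_details=True)
        assert 2 <= k <= 10
        if max(ratios.values()) < 1.5:
            assert low_conf

    def test_vote_three_blobs_unanimous(self):
        X, _ = make_blobs([[0, 0], [10, 0], [0, 10]], n_per=20, sd=0.1, seed=11)
        choices, majority = cluster_count_vote(X)
        assert set(choices.values()) == {3}
        assert majority == 3

    def test_vote_two_blobs_majority(self):
        X, _ = make_blobs([[0, 0], [8, 8]], n_per=20, sd=0.3, seed=12)
        choices, majority = cluster_count_vote(X)
        assert majority == 2

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cluster_count_vote(np.ones((10, 2)))


class TestManova:
    def test_identical_groups_pillai_near_zero(self):
        rng = np.random.default_rng(13)
        block = rng.normal(size=(8, 1, 3))
        arr = np.concatenate([block, block])
        labels = np.array([1] * 8 + [2] * 8)
        out = manova_per_landmark(arr, labels)
        assert out["pillai"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_power_offset_landmark(self):
        rng = np.random.default_rng(14)
        arr = rng.normal(scale=1.0, size=(40, 2, 3))
        arr[20:, 1, :] += 5.0  # 5 sigma shift on landmark 1 only
        labels = np.array([1] * 20 + [2] * 20)
        out = manova_per_landmark(arr, labels)
        assert out.loc[1, "p"] < 1e-6
        assert out.loc[0, "p"] > 0.001

    def test_type_one_calibration(self):
        hits = 0
        N = 500
        for s in range(N):
            rng = np.random.default_rng(20_000 + s)
            arr = rng.normal(size=(24, 1, 3))
            labels = np.repeat([1, 2, 3], 8)
            hits += manova_per_landmark(arr, labels)["p"].iloc[0] < 0.05
        assert 0.03 <= hits / N <= 0.07

    def test_small_groups_rejected(self):
        arr = np.zeros((6, 1, 3))
        with pytest.raises(ValueError):
            manova_per_landmark(arr, np.array([1, 1, 1, 2, 2, 2]))


class TestAnova:
    def test_identical_groups(self):
        block = np.random.default_rng(15).normal(size=(10, 2, 3))
        arr = np.concatenate([block, block])
        labels = np.array([1] * 10 + [2] * 10)
        out = anova_per_axis(arr, labels)
        assert np.allclose(out["F"], 0.0, atol=1e-20)
        assert np.allclose(out["p"], 1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(16)
        arr = rng.normal(size=(24, 1, 3))
        arr[12:] += 0.5
        labels = np.array([1] * 12 + [2] * 12)
        out = anova_per_axis(arr, labels)
        for ax_i, ax in enumerate("XYZ"):
            t = scipy.stats.ttest_ind(arr[:12, 0, ax_i], arr[12:, 0, ax_i])
            row = out[(out["landmark"] == 0) & (out["axis"] == ax)].iloc[0]
            assert row["F"] == pytest.approx(t.statistic**2, rel=1e-10)
            assert row["p"] == pytest.approx(t.pvalue, rel=1e-10)

    def test_three_group_hand_fixture(self):
        """Hand-computable one-way ANOVA: groups (1,2,3),(2,3,4),(3,4,5)."""
        arr = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], float).reshape(9, 1, 1)
        arr = np.repeat(arr, 3, axis=2)
        labels = np.repeat([1, 2, 3], 3)
        out = anova_per_axis(arr, labels)
        # SSB = 3*((2-3)^2+(3-3)^2+(4-3)^2) = 6; SSW = 6*1 = 6
        # F = (6/2)/(6/6) = 3
        row = out[(out["landmark"] == 0) & (out["axis"] == "X")].iloc[0]
        assert row["F"] == pytest.approx(3.0, rel=1e-12)
        assert row["p"] == pytest.approx(scipy.stats.f.sf(3.0, 2, 6), rel=1e-12)


class TestTukey:
    def _fixture(self, shift=0.0, seed=17, n=12):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(3 * n, 1, 3))
        arr[n : 2 * n, 0, 0] += shift
        labels = np.repeat([1, 2, 3], n)
        return arr, labels

    def test_equal_means_p_near_one(self):
        block = np.random.default_rng(18).normal(size=(8, 1, 3))
        arr = np.concatenate([block, block, block])
        labels = np.repeat([1, 2, 3], 8)
        out = tukey_pairwise(arr, labels)
        assert np.all(out["p_adj"] > 0.999)

    def test_adjusted_ge_unadjusted_t(self):
        arr, labels = self._fixture(shift=0.8)
        out = tukey_pairwise(arr, labels)
        for _, row in out.iterrows():
            ia, ib = int(row["cluster_a"]), int(row["cluster_b"])
            ax = "XYZ".index(row["axis"])
            ga = arr[labels == ia, 0, ax]
            gb = arr[labels == ib, 0, ax]
            t = scipy.stats.ttest_ind(ga, gb)
            assert row["p_adj"] >= t.pvalue - 1e-12

    def test_sign_matches_mean_difference(self):
        arr, labels = self._fixture(shift=2.0)
        out = tukey_pairwise(arr, labels)
        for _, row in out.iterrows():
            ia, ib = int(row["cluster_a"]), int(row["cluster_b"])
            ax = "XYZ".index(row["axis"])
            diff = arr[labels == ia, 0, ax].mean() - arr[labels == ib, 0, ax].mean()
            assert row["sign"] == np.sign(diff)
            assert row["diff"] == pytest.approx(diff, rel=1e-12)

    def test_balanced_fixture_matches_studentized_range_oracle(self):
        """Independent computation from group means, pooled MSE and the
        studentized-range distribution."""
        arr, labels = self._fixture(shift=1.0, n=10)
        out = tukey_pairwise(arr, labels)
        groups = [arr[labels == g, 0, 0] for g in (1, 2, 3)]
        n = 10
        N = 30
        mse = sum(np.sum((g - g.mean()) ** 2) for g in groups) / (N - 3)
        for (i, j), pair in [((0, 1), (1, 2)), ((0, 2), (1, 3)), ((1, 2), (2, 3))]:
            q = abs(groups[i].mean() - groups[j].mean()) / np.sqrt(mse / n)
            p_oracle = scipy.stats.studentized_range.sf(q, 3, N - 3)
            row = out[
                (out["axis"] == "X")
                & (out["cluster_a"] == pair[0])
                & (out["cluster_b"] == pair[1])
            ].iloc[0]
            assert row["p_adj"] == pytest.approx(p_oracle, abs=1e-6)
        # critical-value cross-check: q(0.05; 3, N-3) from the independent
        # quantile routine reproduces the 0.05 boundary
        qcrit = scipy.stats.studentized_range.ppf(0.95, 3, N - 3)
        assert scipy.stats.studentized_range.sf(qcrit, 3, N - 3) == pytest.approx(
            0.05, abs=1e-6
        )


class TestLinsCCC:
    def test_identity(self):
        x = np.arange(10.0)
        assert lins_ccc(x, x) == pytest.approx(1.0)

    def test_hand_value(self):
        assert lins_ccc([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(
            0.714286, abs=1e-6
        )

    def test_negation_zero_mean(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert lins_ccc(x, -x) == pytest.approx(-1.0)

    def test_bounded(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert -1.0 <= lins_ccc(x, y) <= 1.0


class TestRepeatability:
    def _sessions(self, sigma2=0.0, seed=19, n_spec=20):
        rng = np.random.default_rng(seed)
        patch = np.concatenate([np.zeros(10, int), np.repeat([1, 2], 100)])
        latents = [rng.normal(scale=3.0, size=(210, 3)) for _ in range(n_spec)]
        def session(noise):
            return [
                LandmarkConfiguration(
                    f"s{i}",
                    c + rng.normal(scale=noise, size=c.shape) if noise else c,
                    patch,
                )
                for i, c in enumerate(latents)
            ]

        return {"op1": session(sigma2), "op2": session(sigma2)}

    def test_identical_sessions_ccc_one(self):
        out = repeatability_report(self._sessions())
        assert np.allclose(out["ccc"], 1.0)
        assert set(out["landmark_class"]) == {"fixed", "sliding"}

    def test_monotone_decrease_with_noise(self):
        values = []
        for sigma in (0.1, 0.5, 1.0):
            out = repeatability_report(self._sessions(sigma2=sigma, seed=20))
            values.append(out[out["landmark_class"] == "fixed"]["ccc"].iloc[0])
        assert values[0] > values[1] > values[2]

    def test_closed_form_two_operator_expectation(self):
        """CCC of latent + independent noise approaches Var/(Var + sigma^2)."""
        sigma = 1.0
        sessions = self._sessions(sigma2=sigma, seed=21)
        # both sessions carry independent noise around the same latent truth
        pooled = np.concatenate([c.coordinates.ravel() for c in sessions["op1"]])
        var = pooled.var() - sigma**2  # latent variance
        expected = var / (var + sigma**2)
        out = repeatability_report(sessions)
        got = (
            out.set_index("landmark_class")
            .loc[["fixed", "sliding"], "ccc"]
            .to_numpy()
        )
        # pooled over 20 specimens x landmarks x 3 axes: small simulation error
        assert np.abs(got - expected).max() < 0.02

    def test_mismatched_sessions_rejected(self):
        sessions = self._sessions()
        sessions["op2"] = sessions["op2"][:-1]
        with pytest.raises(ValueError, match="different specimens"):
            repeatability_report(sessions)


class TestCountTests:
    def test_chi_square_no_signal(self):
        stat, df, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == 0.0
        assert df == 1
        assert p == 1.0

    def test_chi_square_df(self):
        _, df, _ = chi_square_test([[17, 17], [44, 45], [12, 16]])
        assert df == 2

    def test_kruskal_hand_ranks(self):
        H, df, p = kruskal_wallis_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert H == pytest.approx(7.2, abs=1e-9)
        assert df == 2
        assert p == pytest.approx(scipy.stats.chi2.sf(7.2, 2), abs=1e-9)

    def test_kruskal_identical_groups(self):
        H, df, p = kruskal_wallis_test([[2, 2, 2], [2, 2, 2]])
        assert H == 0.0
        assert p == 1.0

    def test_kruskal_tie_correction_matches_manual_oracle(self):
        """Tie-corrected H equals the hand-assembled average-rank statistic
        divided by the standard tie-correction factor."""
        groups = [[1.0, 2.0, 2.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        H, _, _ = kruskal_wallis_test(groups)
        pooled = np.concatenate(groups)
        ranks = scipy.stats.rankdata(pooled)
        N = len(pooled)
        splits = np.split(ranks, [3, 6])
        H_raw = 12.0 / (N * (N + 1)) * sum(
            len(r) * (r.mean() - (N + 1) / 2) ** 2 for r in splits
        )
        _, counts = np.unique(pooled, return_counts=True)
        correction = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
        assert H == pytest.approx(H_raw / correction, rel=1e-12)


def test_benjamini_hochberg_monotone_and_bounded():
    rng = np.random.default_rng(22)
    p = rng.random(50)
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
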