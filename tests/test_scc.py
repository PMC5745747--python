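"""Shrunken centroid classifier against a brute-force oracle, CV threshold
selection, AUC filtering and signature derivation."""

import numpy as np
import pytest

from xplatsig import (
    CVConfig,
    ShrunkenCentroidClassifier,
    SimConfig,
    auc_filter,
    derive_signature,
    filter_low_mad,
    gene_aucs,
    mad_normalize_genes,
    model_from_dict,
    model_to_dict,
    posterior_probs,
    select_threshold_cv,
    simulate_two_platform,
    threshold_grid,
)


def brute_force_scc(X, y, delta):
    """Loop-based reference implementation of the centroid-shrinkage formulas."""
    classes = sorted(set(y))
    n, p = X.shape
    K = len(classes)
    centroids = np.array([[X[np.array(y) == c, i].mean() for i in range(p)]
                          for c in classes])
    overall = np.array([X[:, i].mean() for i in range(p)])
    s = np.zeros(p)
    for i in range(p):
        total = 0.0
        for k, c in enumerate(classes):
            for row in X[np.array(y) == c]:
                total += (row[i] - centroids[k, i]) ** 2
        s[i] = np.sqrt(total / (n - K))
    s0 = float(np.median(s))
    counts = [sum(1 for v in y if v == c) for c in classes]
    mk = [np.sqrt(1.0 / nk - 1.0 / n) for nk in counts]
    d = np.zeros((K, p))
    dp = np.zeros((K, p))
    shrunk = np.zeros((K, p))
    for k in range(K):
        for i in range(p):
            d[k, i] = (centroids[k, i] - overall[i]) / (mk[k] * (s[i] + s0))
            mag = abs(d[k, i]) - delta
            dp[k, i] = np.sign(d[k, i]) * mag if mag > 0 else 0.0
            shrunk[k, i] = overall[i] + mk[k] * (s[i] + s0) * dp[k, i]
    priors = [nk / n for nk in counts]
    surviving = [i for i in range(p) if any(dp[k, i] != 0 for k in range(K))]

    def scores(x):
        out = []
        for k in range(K):
            val = -2.0 * np.log(priors[k])
            for i in surviving:
                val += (x[i] - shrunk[k, i]) ** 2 / (s[i] + s0) ** 2
            out.append(val)
        return np.array(out)

    return {"centroids": centroids, "overall": overall, "s": s, "s0": s0,
            "d": d, "dp": dp, "shrunk": shrunk, "scores": scores,
            "classes": classes}


def random_instance(rng, n=6, p=8):
    X = rng.normal(size=(n, p))
    y = np.array(["HP"] * (n // 2) + ["SSA/P"] * (n - n // 2))
    return X, y


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_fit_and_scores_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_instance(rng)
        delta = rng.uniform(0.0, 2.0)
        clf = ShrunkenCentroidClassifier(delta=delta).fit(X, y)
        ref = brute_force_scc(X, y, delta)
        assert np.allclose(clf.centroids_, ref["centroids"], atol=1e-10)
        assert np.allclose(clf.within_sd_, ref["s"], atol=1e-10)
        assert clf.s0_ == pytest.approx(ref["s0"], abs=1e-10)
        assert np.allclose(clf.dik_, ref["d"], atol=1e-10)
        assert np.allclose(clf.shrunken_dik_, ref["dp"], atol=1e-10)
        assert np.allclose(clf.shrunken_centroids_, ref["shrunk"], atol=1e-10)
        X_test = rng.normal(size=(4, 8))
        got = clf.discriminant_scores(X_test)
        want = np.vstack([ref["scores"](x) for x in X_test])
        assert np.allclose(got, want, atol=1e-10)
        got_p = clf.predict_proba(X_test)
        want_p = np.exp(-want / 2) / np.exp(-want / 2).sum(axis=1, keepdims=True)
        assert np.allclose(got_p, want_p, atol=1e-10)

    def test_delta_zero_equals_unshrunken_nearest_centroid(self, rng):
        X, y = random_instance(rng, n=12, p=5)
        clf = ShrunkenCentroidClassifier(delta=0.0).fit(X, y)
        s = clf.within_sd_ + clf.s0_
        X_test = rng.normal(size=(20, 5))
        expected = []
        for x in X_test:
            d = (((x - clf.centroids_) / s) ** 2).sum(axis=1) - 2 * np.log(clf.priors_)
            expected.append(clf.classes_[np.argmin(d)])
        assert np.array_equal(clf.predict(X_test), expected)

    def test_huge_delta_falls_back_to_priors(self, rng):
        X, y = random_instance(rng, n=10, p=4)
        y = np.array(["HP"] * 7 + ["SSA/P"] * 3)  # unbalanced priors
        clf = ShrunkenCentroidClassifier(delta=1e6).fit(X, y)
        assert clf.n_surviving_ == 0
        X_test = rng.normal(size=(5, 4))
        assert np.all(clf.predict(X_test) == "HP")  # majority prior wins
        proba = clf.predict_proba(X_test)
        assert np.allclose(proba[:, 0], 0.7)  # posterior collapses to the prior


class TestPosteriors:
    def test_equal_scores_give_half(self):
        assert np.allclose(posterior_probs([[3.0, 3.0]]), [[0.5, 0.5]])

    def test_worked_example(self):
        p = posterior_probs([[0.0, 2.0 * np.log(3.0)]])
        assert np.allclose(p, [[0.75, 0.25]])

    def test_shift_invariance_and_sum_one(self, rng):
        scores = rng.normal(size=(10, 3)) * 100
        p1 = posterior_probs(scores)
        p2 = posterior_probs(scores + 57.0)
        assert np.allclose(p1, p2)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-12)

    def test_stable_for_huge_scores(self):
        p = posterior_probs([[1e8, 1e8 + 2.0]])
        assert np.all(np.isfinite(p)) and p[0, 0] > p[0, 1]


class TestShrinkagePath:
    def test_surviving_genes_non_increasing_in_delta(self, rng):
        X, y = random_instance(rng, n=20, p=15)
        clf = ShrunkenCentroidClassifier(delta=0.0).fit(X, y)
        grid = threshold_grid(X, y, 12)
        counts = []
        for delta in grid:
            clf._apply_shrinkage(delta)
            counts.append(clf.n_surviving_)
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 15 and counts[-1] == 0


class TestThresholdCV:
    def test_separable_data_picks_largest_zero_error_delta(self):
        rng = np.random.default_rng(0)
        n = 12
        X = np.zeros((2 * n, 2))
        X[:n] = rng.normal([-3, -3], 0.1, size=(n, 2))
        X[n:] = rng.normal([3, 3], 0.1, size=(n, 2))
        y = np.array(["HP"] * n + ["SSA/P"] * n)
        search = select_threshold_cv(X, y, CVConfig(iterations=5, seed=1))
        zero = search.grid[search.mean_error <= search.mean_error.min() + 1e-12]
        assert search.mean_error.min() == 0.0
        assert search.delta == pytest.approx(zero.max())

    def test_error_curve_shape_and_range(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(18, 6))
        y = np.array(["HP", "SSA/P"] * 9)
        search = select_threshold_cv(X, y, CVConfig(iterations=3, seed=4))
        assert search.mean_error.shape == (30,)
        assert np.all((search.mean_error >= 0) & (search.mean_error <= 1))

    def test_permuted_labels_error_near_chance(self):
        """With labels carrying no signal, CV cannot beat the 0.5 chance rate
        (small-sample anti-learning pushes the error above chance, never
        meaningfully below it)."""
        rng = np.random.default_rng(3)
        errors = []
        for _ in range(5):
            X = rng.normal(size=(30, 10))
            y = rng.permutation(np.array(["HP", "SSA/P"] * 15))
            search = select_threshold_cv(X, y, CVConfig(iterations=10, seed=5))
            errors.append(search.mean_error.min())
        assert np.mean(errors) > 0.4
        assert np.mean([s for s in errors]) < 0.8


class TestAUCFilter:
    def test_perfect_and_flat_genes(self):
        X = np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        y = np.array(["HP", "HP", "SSA/P", "SSA/P"])
        aucs = gene_aucs(X, y)
        assert aucs[0] == 1.0 and aucs[1] == 0.5
        assert list(auc_filter(X, y)) == [True, False]

    def test_three_quarters_auc_dropped_at_point_eight(self):
        X = np.array([[1.0], [2.0], [3.0], [1.5]])
        y = np.array(["HP", "HP", "SSA/P", "SSA/P"])
        assert gene_aucs(X, y)[0] == pytest.approx(0.75)
        assert not auc_filter(X, y)[0]

    def test_symmetrized_direction_does_not_matter(self, rng):
        x = rng.normal(size=(20, 1))
        y = np.array(["HP"] * 10 + ["SSA/P"] * 10)
        assert gene_aucs(x, y)[0] == gene_aucs(-x, y)[0]


@pytest.fixture(scope="module")
def trained():
    cfg = SimConfig(seed=31)
    a, b, truth = simulate_two_platform(cfg)
    a_n = mad_normalize_genes(filter_low_mad(a))
    concordant = list(truth.loc[truth.regime == "concordant", "gene_id"])
    return a_n, truth, derive_signature(
        a_n, concordant, CVConfig(iterations=20, seed=32))


class TestDeriveSignature:
    def test_signature_within_planted_genes(self, trained):
        _, truth, ts = trained
        planted = set(truth.loc[truth.regime == "concordant", "gene_id"])
        assert set(ts.signature.gene_ids) <= planted
        assert len(ts.signature) > 0

    def test_directions_match_class_means(self, trained):
        a_n, _, ts = trained
        hp = a_n.subset_labels(["HP"]).data
        ssa = a_n.subset_labels(["SSA/P"]).data
        for g, d in zip(ts.signature.gene_ids, ts.signature.direction):
            expected = 1 if ssa.loc[g].mean() >= hp.loc[g].mean() else -1
            assert d == expected

    def test_same_seed_reproduces_signature(self, trained):
        a_n, truth, ts = trained
        concordant = list(truth.loc[truth.regime == "concordant", "gene_id"])
        again = derive_signature(a_n, concordant, CVConfig(iterations=20, seed=32))
        assert again.signature.gene_ids == ts.signature.gene_ids
        assert again.search.delta == ts.search.delta

    def test_empty_concordant_set_rejected(self, trained):
        a_n, _, _ = trained
        with pytest.raises(ValueError, match="no concordant genes"):
            derive_signature(a_n, [], CVConfig(seed=0))


class TestModelSerialization:
    def test_roundtrip_preserves_predictions(self, rng):
        X, y = random_instance(rng, n=16, p=6)
        clf = ShrunkenCentroidClassifier(delta=0.7).fit(X, y)
        genes = [f"g{i}" for i in range(6)]
        clf2, genes2 = model_from_dict(model_to_dict(clf, genes))
        X_test = rng.normal(size=(10, 6))
        assert genes2 == genes
        assert np.array_equal(clf.predict(X_test), clf2.predict(X_test))
        assert np.allclose(clf.predict_proba(X_test), clf2.predict_proba(X_test))


def test_fit_rejects_single_sample_class():
    X = np.zeros((3, 2))
    y = np.array(["HP", "HP", "SSA/P"])
    with pytest.raises(ValueError, match=">=2 samples"):
        ShrunkenCentroidClassifier().fit(X, y)
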