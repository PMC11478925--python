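import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mrsdss.classify import (FeatureVector, apply_lda, decision_boundaries,
                             df_discriminants, evaluate_classifier,
                             posteriors_from_df, round_half_up, standardize,
                             train_lda)


def gaussian_cohort(rng, means, cov, n_per_class, labels=("EP", "MB", "PA")):
    X, y = [], []
    for mu, lab in zip(means, labels):
        X.append(rng.multivariate_normal(mu, cov, size=n_per_class))
        y += [lab] * n_per_class
    return np.vstack(X), y


@pytest.fixture
def toy_model(rng):
    means = [np.array([0.0, 0.0, 0.0, 0.0]),
             np.array([4.0, 0.0, 1.0, 0.0]),
             np.array([0.0, 4.0, 0.0, 1.0])]
    X, y = gaussian_cohort(rng, means, np.eye(4), 40)
    return train_lda(X, y, shrinkage=0.1), X, y


class TestStandardize:
    def test_training_mean_maps_to_zero(self, toy_model):
        model, X, _ = toy_model
        np.testing.assert_allclose(standardize(X.mean(axis=0), model),
                                   np.zeros(X.shape[1]), atol=1e-12)

    def test_mean_plus_sd_maps_to_one(self, toy_model):
        model, X, _ = toy_model
        x = X.mean(axis=0) + X.std(axis=0, ddof=1)
        np.testing.assert_allclose(standardize(x, model), np.ones(X.shape[1]),
                                   atol=1e-12)

    def test_full_training_set_standardizes_to_unit_stats(self, toy_model):
        model, X, _ = toy_model
        Z = np.array([standardize(x, model) for x in X])
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_feature_mismatch_rejected(self, toy_model):
        model, _, _ = toy_model
        fv = FeatureVector(("a", "b"), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="feature"):
            standardize(fv, model)


class TestTrainLDA:
    def test_separated_classes_training_accuracy_100(self, rng):
        means = [np.zeros(3), np.r_[10.0, 0.0, 0.0]]
        X, y = gaussian_cohort(rng, means, np.eye(3), 50, ("A", "B"))
        model = train_lda(X, y, shrinkage=0.0)
        ev = evaluate_classifier(model, X, y)
        assert ev.accuracy_percent == 100

    def test_equal_class_means_posteriors_equal_priors(self, rng):
        X = rng.normal(size=(90, 4))
        y = ["EP", "MB", "PA"] * 30
        priors = {"EP": 0.2, "MB": 0.5, "PA": 0.3}
        model = train_lda(X, y, priors=priors, shrinkage=0.1)
        # force exactly equal class means
        object.__setattr__(model, "class_means",
                           np.zeros_like(model.class_means))
        for x in rng.normal(size=(5, 4)):
            post = apply_lda(model, x).posteriors
            for lab, p in priors.items():
                assert post[lab] == pytest.approx(p, abs=1e-12)

    def test_two_canonical_axes_for_three_classes(self, toy_model):
        model, _, _ = toy_model
        assert model.projection.shape[1] == 2

    def test_projection_whitens_within_class(self, toy_model):
        model, _, _ = toy_model
        W = model.projection
        np.testing.assert_allclose(W.T @ model.pooled_cov @ W, np.eye(2),
                                   atol=1e-8)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="two classes"):
            train_lda(X, ["A"] * 10)

    def test_singular_without_shrinkage_rejected(self, rng):
        X = rng.normal(size=(6, 10))
        y = ["A", "A", "A", "B", "B", "B"]
        with pytest.raises(ValueError, match="shrinkage"):
            train_lda(X, y, shrinkage=0.0)

    def test_tiny_class_warns(self, rng):
        X = np.vstack([rng.normal(size=(10, 3)),
                       rng.normal(size=(1, 3)) + 5.0])
        y = ["A"] * 10 + ["B"]
        with pytest.warns(UserWarning, match="fewer than 2"):
            train_lda(X, y, shrinkage=0.1)


class TestApplyLDA:
    def test_class_mean_gets_max_posterior(self, toy_model):
        model, _, _ = toy_model
        for i, lab in enumerate(model.class_labels):
            x = model.mu + model.sigma * model.class_means[i]
            res = apply_lda(model, x)
            assert res.predicted == lab
            assert res.posteriors[lab] == max(res.posteriors.values())

    def test_equidistant_point_gives_uniform_posteriors(self):
        # three spherical classes at the vertices of an equilateral
        # triangle; the centroid is Mahalanobis-equidistant
        means = np.array([[1.0, 0.0], [-0.5, np.sqrt(3) / 2],
                          [-0.5, -np.sqrt(3) / 2]])
        rng = np.random.default_rng(0)
        X, y = [], []
        for mu, lab in zip(means, ("EP", "MB", "PA")):
            X.append(rng.multivariate_normal(mu, 0.05 * np.eye(2), size=200))
            y += [lab] * 200
        X = np.vstack(X)
        model = train_lda(X, y, shrinkage=0.0)
        object.__setattr__(model, "mu", np.zeros(2))
        object.__setattr__(model, "sigma", np.ones(2))
        object.__setattr__(model, "class_means", means)
        object.__setattr__(model, "pooled_cov", np.eye(2))
        model.__post_init__()
        post = apply_lda(model, np.zeros(2)).posteriors
        for p in post.values():
            assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_posteriors_match_gaussian_density_oracle(self, toy_model, rng):
        model, _, _ = toy_model
        cov = np.asarray(model.pooled_cov)
        for _ in range(100):
            x = rng.normal(scale=3.0, size=4)
            z = standardize(x, model)
            dens = np.array([
                multivariate_normal.pdf(z, mean=m, cov=cov) * pi
                for m, pi in zip(model.class_means, model.priors)
            ])
            expected = dens / dens.sum()
            post = apply_lda(model, x).posteriors
            np.testing.assert_allclose(
                [post[lab] for lab in model.class_labels], expected, atol=1e-9)

    def test_posteriors_sum_to_one(self, toy_model, rng):
        model, _, _ = toy_model
        for _ in range(20):
            post = apply_lda(model, rng.normal(scale=5.0, size=4)).posteriors
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_df_space_posteriors_agree_with_full_space(self, toy_model, rng):
        model, _, _ = toy_model
        for _ in range(20):
            x = rng.normal(scale=3.0, size=4)
            res = apply_lda(model, x)
            post_df = posteriors_from_df(model, res.df_scores)
            np.testing.assert_allclose(
                [res.posteriors[lab] for lab in model.class_labels],
                post_df, atol=1e-9)


class TestDecisionBoundaries:
    def test_two_class_boundary_is_perpendicular_bisector(self, rng):
        means = [np.array([-2.0, 0.0]), np.array([2.0, 0.0])]
        X, y = gaussian_cohort(rng, means, np.eye(2), 200, ("A", "B"))
        model = train_lda(X, y, shrinkage=0.0)
        bounds = decision_boundaries(model, (-6, 6), (-6, 6))
        pts = bounds[("A", "B")]
        U = model.df_class_means
        U = np.hstack([U, np.zeros((2, 1))])  # 1-D canonical space, padded
        u_a, u_b = U
        mid = (u_a + u_b) / 2.0
        direction = u_b - u_a
        # every boundary point is equidistant from both projected means
        for p in pts[:: max(1, len(pts) // 20)]:
            assert np.dot(p - mid, direction) == pytest.approx(0.0, abs=1e-8)

    def test_boundary_points_have_equal_top_posteriors(self, toy_model):
        model, _, _ = toy_model
        bounds = decision_boundaries(model)
        assert bounds
        for (a, b), pts in bounds.items():
            ia = model.class_labels.index(a)
            ib = model.class_labels.index(b)
            for p in pts[:: max(1, len(pts) // 10)]:
                post = posteriors_from_df(model, p)
                assert abs(post[ia] - post[ib]) <= 1e-6

    def test_prior_change_shifts_boundary_by_log_odds(self, rng):
        means = [np.array([-2.0, 0.0]), np.array([2.0, 0.0])]
        X, y = gaussian_cohort(rng, means, np.eye(2), 200, ("A", "B"))
        m_eq = train_lda(X, y, shrinkage=0.0)
        m_sk = train_lda(X, y, priors={"A": 0.9, "B": 0.1}, shrinkage=0.0)
        U = np.hstack([m_eq.df_class_means, np.zeros((2, 1))])
        u_a, u_b = U
        d = u_b - u_a
        b_eq = decision_boundaries(m_eq, (-8, 8), (-8, 8))[("A", "B")]
        b_sk = decision_boundaries(m_sk, (-8, 8), (-8, 8))[("A", "B")]
        # offset along the between-means direction: log(pi_a/pi_b)/|d|
        proj_eq = np.mean(b_eq @ d) / np.linalg.norm(d)
        proj_sk = np.mean(b_sk @ d) / np.linalg.norm(d)
        expected = np.log(0.9 / 0.1) / np.linalg.norm(d)
        assert proj_sk - proj_eq == pytest.approx(expected, abs=1e-6)


class TestEvaluate:
    def test_thirty_of_thirtythree_rounds_to_91(self, rng):
        # constructed test set with exactly 3 misclassified cases
        means = [np.zeros(2), np.r_[8.0, 0.0]]
        X, y = gaussian_cohort(rng, means, np.eye(2), 100, ("A", "B"))
        model = train_lda(X, y, shrinkage=0.0)
        X_test = np.vstack([np.tile([0.0, 0.0], (15, 1)),
                            np.tile([8.0, 0.0], (18, 1))])
        y_test = ["A"] * 15 + ["B"] * 15 + ["A"] * 3
        ev = evaluate_classifier(model, X_test, y_test)
        assert ev.n_total == 33 and ev.n_correct == 30
        assert ev.accuracy_percent == 91
        assert ev.accuracy_exact == pytest.approx(100 * 30 / 33)

    def test_all_correct_gives_100(self, toy_model):
        model, X, y = toy_model
        ev = evaluate_classifier(model, X, y)
        assert evaluate_classifier(model, X[:5], [
            apply_lda(model, x).predicted for x in X[:5]
        ]).accuracy_percent == 100

    def test_confusion_matrix_matches_tally_oracle(self, toy_model, rng):
        model, X, _ = toy_model
        labels = [str(l) for l in rng.choice(model.class_labels, size=len(X))]
        ev = evaluate_classifier(model, X, labels)
        tally = {(t, p): 0 for t in model.class_labels
                 for p in model.class_labels}
        for x, t in zip(X, labels):
            tally[(t, apply_lda(model, x).predicted)] += 1
        for (t, p), n in tally.items():
            assert ev.confusion.loc[t, p] == n

    def test_unknown_label_rejected(self, toy_model):
        model, X, _ = toy_model
        with pytest.raises(ValueError, match="unknown"):
            evaluate_classifier(model, X[:1], ["XX"])


class TestModelDiscipline:
    def test_model_arrays_are_frozen(self, toy_model):
        model, _, _ = toy_model
        with pytest.raises(ValueError):
            model.mu[0] = 99.0

    def test_applying_test_data_never_mutates_model(self, toy_model, rng):
        model, _, _ = toy_model
        before = {name: np.array(getattr(model, name)) for name in
                  ("mu", "sigma", "class_means", "pooled_cov", "priors",
                   "projection")}
        for _ in range(10):
            apply_lda(model, rng.normal(size=4))
        evaluate_classifier(model, rng.normal(size=(20, 4)),
                            [str(l) for l in
                             rng.choice(model.class_labels, size=20)])
        for name, arr in before.items():
            np.testing.assert_array_equal(arr, getattr(model, name))

    def test_lipid_shifted_ep_lowers_ep_recall(self, rng):
        """EP-like cases shifted toward higher lipid signal are recalled
        less often than unshifted EP cases (directional property)."""
        p = 6
        means = {"EP": np.zeros(p), "MB": np.full(p, 2.0),
                 "PA": np.r_[np.full(3, -2.0), np.zeros(3)]}
        cov = np.eye(p)
        X, y = [], []
        for lab, mu in means.items():
            X.append(rng.multivariate_normal(mu, cov, size=60))
            y += [lab] * 60
        model = train_lda(np.vstack(X), y, shrinkage=0.1)
        ep_plain = rng.multivariate_normal(means["EP"], cov, size=300)
        shift = np.zeros(p)
        shift[-1] = 2.5  # toward the MB side along the last feature
        ep_shifted = ep_plain + shift
        recall = lambda A: np.mean([apply_lda(model, x).predicted == "EP"
                                    for x in A])
        assert recall(ep_shifted) < recall(ep_plain)


def test_round_half_up():
    assert round_half_up(90.909) == 91
    assert round_half_up(42.42) == 42
    assert round_half_up(87.878) == 88
    assert round_half_up(87.5) == 88
    assert round_half_up(42.0) == 42
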