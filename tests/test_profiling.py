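"""PCA projection, Gaussian templates, posterior, PI and success rate."""

import math

import numpy as np
import pytest
from scipy import stats

import swa_brainage as sb
from swa_brainage.cohort import CANONICAL_LABELS, ClassLabel
from swa_brainage.profiling import (
    ClassTemplate,
    fit_projection,
    fit_template,
    perceived_information,
    posterior,
    success_rate,
)


def _profiles_from_matrix(X, labels):
    return [sb.SWAProfile(f"m{i}", lab, row) for i, (row, lab) in enumerate(zip(X, labels))]


class TestProjection:
    def test_variance_on_one_coordinate_gives_that_axis(self):
        rng = np.random.default_rng(0)
        X = np.full((20, 12), 100.0)
        X[:, 7] += rng.normal(0, 5, 20)
        proj = fit_projection(X, 1)
        axis = np.zeros(12)
        axis[7] = 1.0
        assert np.allclose(np.abs(proj.loadings[:, 0]), axis, atol=1e-9)
        assert proj.loadings[7, 0] > 0  # sign convention

    def test_full_dimension_is_an_isometry(self):
        rng = np.random.default_rng(1)
        X = 100 + rng.normal(0, 10, (15, 12))
        Z = fit_projection(X, 12).transform(X)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(X), pdist(Z))

    def test_retained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = 100 + rng.normal(0, 10, (40, 12)) @ np.diag(np.linspace(0.2, 3, 12))
        proj = fit_projection(X, 3)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False, ddof=1)))[::-1]
        assert np.allclose(proj.explained_variance, eig[:3])

    def test_agrees_with_sklearn_pca(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        X = 100 + rng.normal(0, 10, (30, 12))
        proj = fit_projection(X, 3)
        ref = PCA(n_components=3).fit(X)
        # same subspace: loadings agree with sklearn components up to sign
        for j in range(3):
            dot = abs(float(proj.loadings[:, j] @ ref.components_[j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_preconditions(self):
        X = np.ones((3, 12))
        with pytest.raises(ValueError):
            fit_projection(X, 13)
        with pytest.raises(ValueError):
            fit_projection(X, 3)  # needs >= d+1 rows


class TestTemplates:
    def test_identical_profiles_leave_only_the_ridge(self):
        X = np.tile(np.linspace(40, 60, 12), (5, 1))
        axis = np.zeros((12, 1))
        axis[0] = 1.0
        proj = sb.ProjectionModel(center=np.zeros(12), loadings=axis, d=1,
                                  explained_variance=np.array([1.0]))
        tpl = fit_template(X, proj, regularization=1e-6)
        assert np.allclose(tpl.cov, 1e-6 * np.eye(1), atol=1e-18)

    def test_two_point_closed_form_in_one_dimension(self):
        a, b = 3.0, 11.0
        X = np.full((2, 12), 50.0)
        X[0, 0], X[1, 0] = a, b
        axis = np.zeros((12, 1))
        axis[0] = 1.0
        proj = sb.ProjectionModel(center=np.zeros(12), loadings=axis, d=1,
                                  explained_variance=np.array([1.0]))
        tpl = fit_template(X, proj, regularization=1e-6, shrinkage=None)
        var = (a - b) ** 2 / 2
        assert tpl.mean[0] == pytest.approx((a + b) / 2)
        assert tpl.cov[0, 0] == pytest.approx(var * (1 + 1e-6))

    def test_single_profile_rejected(self):
        X = np.full((1, 12), 50.0)
        proj = sb.ProjectionModel(center=np.zeros(12), loadings=np.eye(12)[:, :2], d=2,
                                  explained_variance=np.ones(2))
        with pytest.raises(ValueError):
            fit_template(X, proj)

    def test_parameter_recovery_within_three_se(self):
        lab = ClassLabel(18, True)
        base = sb.default_cohort_spec(1.0, seed=8)
        n = 500
        spec = sb.CohortSpec(counts={lab: n}, means={lab: base.means[lab]},
                             covariances={lab: base.covariances[lab]}, seed=8)
        X = np.vstack([p.values for p in sb.simulate_profiles(spec)])
        proj = fit_projection(X, 12)
        tpl = fit_template(X, proj, regularization=1e-12, shrinkage=None,
                           max_condition=np.inf)
        mu_true = proj.transform(base.means[lab][None, :])[0]
        cov_true = proj.loadings.T @ base.covariances[lab] @ proj.loadings
        se_mu = np.sqrt(np.diag(cov_true) / n)
        assert np.all(np.abs(tpl.mean - mu_true) < 3 * se_mu)
        dd = np.diag(cov_true)
        se_cov = np.sqrt((np.outer(dd, dd) + cov_true**2) / (n - 1))
        assert np.all(np.abs(tpl.cov - cov_true) < 3 * se_cov)


class TestPosterior:
    def test_identical_templates_give_uniform_posterior(self):
        tpl = ClassTemplate(None, np.zeros(2), np.eye(2), 10)
        post = posterior(np.array([0.3, -0.2]), [tpl] * 6, np.full(6, 1 / 6))
        assert np.allclose(post, 1 / 6)

    def test_dominant_class_at_its_own_mean(self):
        templates = [
            ClassTemplate(None, np.array([100.0 * j, 0.0]), np.eye(2), 10)
            for j in range(6)
        ]
        post = posterior(np.array([300.0, 0.0]), templates, np.full(6, 1 / 6))
        assert post[3] >= 1 - 1e-6

    def test_two_gaussians_equal_variance_logistic_closed_form(self):
        m0, m1, v = -1.0, 2.0, 1.7
        templates = [ClassTemplate(None, np.array([m0]), np.array([[v]]), 9),
                     ClassTemplate(None, np.array([m1]), np.array([[v]]), 9)]
        for s in (-2.0, 0.0, 0.4, 3.0):
            post = posterior(np.array([s]), templates, np.array([0.5, 0.5]))
            logit = (s - (m0 + m1) / 2) * (m1 - m0) / v
            assert post[1] == pytest.approx(1 / (1 + math.exp(-logit)), abs=1e-12)

    def test_underflow_is_harmless(self):
        templates = [ClassTemplate(None, np.array([0.0]), np.array([[1e-6]]), 5),
                     ClassTemplate(None, np.array([1e4]), np.array([[1e-6]]), 5)]
        post = posterior(np.array([5e3]), templates, np.array([0.5, 0.5]))
        assert np.isfinite(post).all()
        assert np.all((post >= 0) & (post <= 1))
        # log-densities here are ~ -1e13, where double spacing is ~2e-3, so
        # normalization is only as exact as exp() at that magnitude
        assert post.sum() == pytest.approx(1.0, abs=1e-3)


class TestPerceivedInformation:
    def test_bounded_by_class_entropy(self, separated_profiles, null_cohort):
        for profiles in (separated_profiles, null_cohort(0)):
            res = perceived_information(profiles, seed=0, n_bootstrap=20)
            assert res.pi <= res.class_entropy + 1e-9

    def test_uniform_priors_entropy_is_log2_six(self, separated_profiles):
        res = perceived_information(separated_profiles, seed=0, n_bootstrap=20)
        assert res.class_entropy == pytest.approx(math.log2(6))

    def test_empirical_priors_entropy_below_uniform(self, separated_profiles):
        res = perceived_information(separated_profiles, priors="empirical",
                                    seed=0, n_bootstrap=20)
        assert res.class_entropy < math.log2(6)
        assert res.priors["6C"] == pytest.approx(11 / 54)

    def test_bootstrap_ci_brackets_the_estimate(self, separated_profiles, null_cohort):
        res = perceived_information(null_cohort(3), seed=3)
        lo, hi = res.bootstrap_ci
        assert lo <= res.pi + 0.2 and hi >= res.pi - 0.2 and lo <= hi

    def test_affine_invariance_with_full_rank_templates(self, null_cohort):
        # exact property of the Bayes/Gaussian machinery: an invertible affine
        # map of all profiles leaves PI unchanged when d = 12 and the raw
        # (unshrunk) covariance is used
        rng = np.random.default_rng(4)
        base = sb.default_cohort_spec(1.0, seed=4,
                                      counts={lab: 30 for lab in CANONICAL_LABELS[:3]})
        profiles = sb.simulate_profiles(base)
        kwargs = dict(d=12, regularization=1e-12, max_condition=np.inf,
                      shrinkage=None, n_bootstrap=10, seed=0)
        pi0 = perceived_information(profiles, **kwargs).pi
        A = np.eye(12) + 0.05 * rng.standard_normal((12, 12))
        assert np.linalg.cond(A) < 10
        b = rng.uniform(0, 50, 12)
        mapped = [
            sb.SWAProfile(p.mouse_id, p.label, A @ p.values + b) for p in profiles
        ]
        pi1 = perceived_information(mapped, **kwargs).pi
        assert pi1 == pytest.approx(pi0, abs=1e-6)

    def test_pi_increases_with_class_separation(self):
        pis = []
        for scale in (3.0, 0.3, 0.003):  # shrinking covariance = growing separation
            profiles = sb.simulate_profiles(sb.default_cohort_spec(scale, seed=6))
            pis.append(perceived_information(profiles, seed=6, n_bootstrap=10).pi)
        assert pis[0] < pis[1] < pis[2]

    def test_requires_three_per_class(self, separated_profiles):
        thin = [p for p in separated_profiles if not
                (p.label == ClassLabel(6, False) and p.mouse_id > "6C-02")]
        with pytest.raises(ValueError, match="6C"):
            perceived_information(thin)


class TestSuccessRate:
    def test_chance_level_when_classes_are_identical(self, null_cohort):
        rep = success_rate(null_cohort(5, n_per_class=40), seed=5)
        n_test = len(rep.true_labels)
        band = 2.576 * math.sqrt((1 / 6) * (5 / 6) / n_test)
        assert abs(rep.success_rate - 1 / 6) < band

    def test_confusion_matrix_is_consistent(self, separated_profiles):
        rep = success_rate(separated_profiles, seed=1)
        assert rep.confusion.sum() == len(rep.true_labels)
        assert rep.success_rate == np.trace(rep.confusion) / rep.confusion.sum()
        # test halves are floor(n/2) per class: 5+4+4+4+4+4
        assert len(rep.true_labels) == 25

    def test_relabelling_classes_permutes_the_confusion_matrix(self, separated_profiles):
        rep = success_rate(separated_profiles, seed=2)
        # cyclic permutation of the six labels
        cycle = {a: b for a, b in zip(CANONICAL_LABELS,
                                      CANONICAL_LABELS[1:] + CANONICAL_LABELS[:1])}
        relabelled = [sb.SWAProfile(p.mouse_id, cycle[p.label], p.values)
                      for p in separated_profiles]
        rep2 = success_rate(relabelled, seed=2)
        assert rep2.success_rate == rep.success_rate
        perm = [rep2.classes.index(cycle[c]) for c in rep.classes]
        assert np.array_equal(rep2.confusion[np.ix_(perm, perm)], rep.confusion)

    def test_two_gaussian_classes_match_analytic_bayes_error(self):
        # equal-variance 1-D pair: Bayes error = Phi(-delta / (2 sigma))
        delta, sigma, n = 2.0, 1.0, 400
        rng = np.random.default_rng(12)
        profiles = []
        for lab, mu in ((ClassLabel(6, False), -delta / 2), (ClassLabel(6, True), delta / 2)):
            for i in range(n):
                v = np.full(12, 50.0) + rng.normal(0, 0.01, 12)
                v[0] = 50 + mu + rng.normal(0, sigma)
                profiles.append(sb.SWAProfile(f"{lab}-{i}", lab, v))
        rep = success_rate(profiles, d=1, seed=12)
        bayes_error = stats.norm.cdf(-delta / (2 * sigma))
        se = math.sqrt(bayes_error * (1 - bayes_error) / len(rep.true_labels))
        assert abs((1 - rep.success_rate) - bayes_error) < 3.5 * se

    def test_requires_four_per_class(self, null_cohort):
        thin = null_cohort(0, n_per_class=3)
        with pytest.raises(ValueError):
            success_rate(thin)
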