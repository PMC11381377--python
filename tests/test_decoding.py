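import numpy as np
import pytest

from mitrain.core import CLASS_LEFT, CLASS_RIGHT, EpochedTrial
from mitrain.decoding import (
    DecoderBundle,
    LinearClassifier,
    SpatialModel,
    align_runs,
    align_trial,
    bundle_from_dict,
    bundle_to_dict,
    csp_features,
    csp_fit,
    decode_trial,
    invsqrtm,
    lda_fit,
    riemannian_mean,
    trial_covariance,
)


def _gaussian_trials(cov, n_trials, n_samples, rng, label=1):
    chol = np.linalg.cholesky(cov)
    return [EpochedTrial(samples=rng.normal(size=(n_samples, cov.shape[0])) @ chol.T,
                         label=label, trial_id=f"{label}-{i}")
            for i in range(n_trials)]


def _random_spd(dim, rng, scale=1.0):
    a = rng.normal(size=(dim, dim))
    return scale * (a @ a.T + dim * np.eye(dim))


class TestTrialCovariance:
    def test_white_noise_recovers_diagonal(self, rng):
        x = rng.normal(0, 2.0, (100_000, 4))
        p = trial_covariance(x)
        assert np.allclose(p, 4.0 * np.eye(4), atol=0.15)

    def test_duplicated_channel_needs_ridge(self, rng):
        x = rng.normal(size=(512, 3))
        x[:, 2] = x[:, 1]
        p_no = trial_covariance(x, ridge=0.0)
        assert np.linalg.eigvalsh(p_no).min() == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.eigvalsh(trial_covariance(x)).min() > 0
        assert p_no[1, 2] == pytest.approx(p_no[1, 1])

    def test_quadratic_scaling(self, rng):
        x = rng.normal(size=(512, 3))
        assert np.allclose(trial_covariance(3.0 * x, ridge=0.0),
                           9.0 * trial_covariance(x, ridge=0.0))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            trial_covariance(np.full((512, 2), np.nan))


class TestRiemannianMean:
    def test_single_matrix_is_its_own_mean(self):
        p = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert np.allclose(riemannian_mean([p]), p)

    def test_commuting_diagonal_closed_form(self):
        m = riemannian_mean([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        assert np.allclose(m, 2.0 * np.eye(2), atol=1e-8)

    def test_identity_fixed_point(self):
        assert np.allclose(riemannian_mean([np.eye(3)] * 3), np.eye(3))

    def test_congruence_invariance(self, rng):
        mats = [_random_spd(4, rng) for _ in range(5)]
        a = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        lhs = riemannian_mean([a.T @ p @ a for p in mats], max_iter=200)
        rhs = a.T @ riemannian_mean(mats, max_iter=200) @ a
        assert np.allclose(lhs, rhs, atol=1e-6 * np.abs(rhs).max())

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError):
            riemannian_mean([np.diag([1.0, -1.0])])
        with pytest.raises(ValueError):
            riemannian_mean([])


class TestAlignment:
    def test_identity_mean_is_identity_transform(self, rng):
        x = rng.normal(size=(64, 3))
        assert np.allclose(align_trial(x, np.eye(3)), x)

    def test_shared_covariance_aligns_to_identity(self, rng):
        cov = _random_spd(4, rng)
        trials = _gaussian_trials(cov, 1, 200_000, rng)
        aligned = align_trial(trials[0].samples, cov)
        assert np.allclose(trial_covariance(aligned, ridge=0.0), np.eye(4), atol=0.05)

    def test_aligned_run_karcher_mean_is_identity(self, rng):
        cov = _random_spd(5, rng)
        run = _gaussian_trials(cov, 12, 256, rng)
        aligned, _, means = align_runs([run])
        post = riemannian_mean([trial_covariance(t.samples) for t in aligned],
                               max_iter=200)
        assert np.allclose(post, np.eye(5), atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            align_trial(rng.normal(size=(10, 3)), np.eye(4))


class TestCSP:
    def test_two_channel_oracle(self, rng):
        t1 = _gaussian_trials(np.diag([4.0, 1.0]), 30, 2000, rng, label=CLASS_RIGHT)
        t2 = _gaussian_trials(np.diag([1.0, 4.0]), 30, 2000, rng, label=CLASS_LEFT)
        model = csp_fit(t1 + t2, m_per_side=1)
        first, last = model.filters[0], model.filters[-1]
        assert abs(first[0]) > 10 * abs(first[1])   # first filter ~ axis of class-1 variance
        assert abs(last[1]) > 10 * abs(last[0])
        assert model.eigenvalues[0] == pytest.approx(4.0, rel=0.2)
        assert model.eigenvalues[-1] == pytest.approx(0.25, rel=0.2)

    def test_indistinguishable_classes_give_unit_eigenvalues(self, rng):
        cov = _random_spd(4, rng)
        t1 = _gaussian_trials(cov, 40, 4000, rng, label=CLASS_RIGHT)
        t2 = _gaussian_trials(cov, 40, 4000, rng, label=CLASS_LEFT)
        model = csp_fit(t1 + t2, m_per_side=2)
        assert np.allclose(model.eigenvalues, 1.0, atol=0.1)

    def test_top_filter_maximises_rayleigh_quotient(self, rng):
        t1 = _gaussian_trials(_random_spd(6, rng), 20, 512, rng, label=CLASS_RIGHT)
        t2 = _gaussian_trials(_random_spd(6, rng), 20, 512, rng, label=CLASS_LEFT)
        trials = t1 + t2
        model = csp_fit(trials, m_per_side=1)
        covs = np.stack([trial_covariance(t.samples) for t in trials])
        labels = np.array([t.label for t in trials])
        p1 = covs[labels == CLASS_RIGHT].mean(axis=0)
        p2 = covs[labels == CLASS_LEFT].mean(axis=0)

        def quotient(w):
            return (w @ p1 @ w) / (w @ p2 @ w)

        top = quotient(model.filters[0])
        vecs = rng.normal(size=(10_000, 6))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        assert top >= max(quotient(v) for v in vecs) - 1e-9

    def test_label_swap_reverses_filter_order(self, rng):
        t1 = _gaussian_trials(_random_spd(5, rng), 20, 512, rng, label=CLASS_RIGHT)
        t2 = _gaussian_trials(_random_spd(5, rng), 20, 512, rng, label=CLASS_LEFT)
        model = csp_fit(t1 + t2, m_per_side=2)
        swapped = [EpochedTrial(samples=t.samples,
                                label=CLASS_LEFT if t.label == CLASS_RIGHT else CLASS_RIGHT)
                   for t in t1 + t2]
        model_sw = csp_fit(swapped, m_per_side=2)
        assert np.allclose(np.abs(model_sw.filters), np.abs(model.filters[::-1]),
                           atol=1e-6)

    def test_agrees_with_mne_reference(self, rng):
        """Cross-check the extreme variance-ratio against mne's CSP."""
        mne = pytest.importorskip("mne")
        from mne.decoding import CSP as MneCSP

        t1 = _gaussian_trials(_random_spd(5, rng, 2.0), 25, 512, rng, label=CLASS_RIGHT)
        t2 = _gaussian_trials(_random_spd(5, rng, 2.0), 25, 512, rng, label=CLASS_LEFT)
        trials = t1 + t2
        model = csp_fit(trials, m_per_side=1)

        X = np.stack([t.samples.T for t in trials])
        y = np.array([t.label for t in trials])
        ref = MneCSP(n_components=2, reg=None, log=True, norm_trace=False,
                     cov_est="epoch")
        ref.fit(X, y)
        covs = np.stack([trial_covariance(t.samples) for t in trials])
        p1 = covs[y == CLASS_RIGHT].mean(axis=0)
        p2 = covs[y == CLASS_LEFT].mean(axis=0)

        def quotient(w):
            return (w @ p1 @ w) / (w @ p2 @ w)

        ref_extremes = sorted(quotient(f) for f in ref.filters_)
        mine = quotient(model.filters[0])
        assert max(mine, 1 / mine) == pytest.approx(
            max(ref_extremes[-1], 1 / ref_extremes[0]), rel=0.05)

    def test_single_class_rejected(self, rng):
        t1 = _gaussian_trials(np.eye(3), 10, 128, rng, label=CLASS_RIGHT)
        with pytest.raises(ValueError):
            csp_fit(t1)


class TestFeatures:
    def test_unit_variance_projection_gives_zero(self, rng):
        x = rng.normal(size=(200_000, 2))
        x /= x.std(axis=0, ddof=1)
        f = csp_features(x, np.eye(2))
        assert np.allclose(f, 0.0, atol=1e-6)

    def test_scaling_adds_two_log_a(self, rng):
        x = rng.normal(size=(512, 4))
        filt = rng.normal(size=(3, 4))
        base = csp_features(x, filt)
        scaled = csp_features(5.0 * x, filt)
        assert np.allclose(scaled - base, 2 * np.log(5.0))


class TestLDA:
    def test_symmetric_gaussians_closed_form(self):
        f = np.array([[1.0, 0.0], [1.2, 0.5], [0.8, -0.5],
                      [-1.0, 0.0], [-1.2, 0.5], [-0.8, -0.5]])
        labels = np.array([1, 1, 1, 2, 2, 2])
        clf = lda_fit(f, labels)
        assert clf.bias == pytest.approx(0.0, abs=1e-9)
        assert clf.predict(np.array([0.5, 0.0])) == CLASS_RIGHT
        assert clf.predict(np.array([-0.5, 0.0])) == CLASS_LEFT

    def test_collinear_worked_example(self):
        f = np.array([[2.0, 0.0], [4.0, 0.0], [-2.0, 0.0], [-4.0, 0.0]])
        labels = np.array([1, 1, 2, 2])
        clf = lda_fit(f, labels)
        assert clf.weight[0] == pytest.approx(3.0, rel=1e-4)
        assert clf.weight[1] == pytest.approx(0.0, abs=1e-6)
        assert clf.bias == pytest.approx(0.0, abs=1e-9)
        assert all(clf.predict(x) == l for x, l in zip(f, labels))

    def test_translation_invariant_decisions(self, rng):
        f = rng.normal(size=(40, 6))
        labels = np.array([1, 2] * 20)
        clf = lda_fit(f, labels)
        shift = rng.normal(size=6)
        clf2 = lda_fit(f + shift, labels)
        assert np.allclose(clf2.weight, clf.weight)
        for x in f[:5]:
            assert clf2.decision(x + shift) == pytest.approx(clf.decision(x))

    def test_matches_sklearn_on_balanced_data(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        f = np.vstack([rng.normal(0.8, 1, (30, 4)), rng.normal(-0.8, 1, (30, 4))])
        labels = np.array([1] * 30 + [2] * 30)
        clf = lda_fit(f, labels)
        ref = LinearDiscriminantAnalysis().fit(f, labels)
        probe = rng.normal(0, 2, (200, 4))
        mine = np.array([clf.predict(x) for x in probe])
        assert np.mean(mine == ref.predict(probe)) >= 0.99

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(np.ones((3, 2)), np.array([1, 1, 2]))


class TestDecode:
    def test_zero_decision_value_maps_to_right(self, rng):
        spatial = SpatialModel(projection=np.eye(21), filters=np.eye(21)[:6],
                               eigenvalues=np.ones(21), global_mean=np.eye(21))
        bundle = DecoderBundle(spatial=spatial,
                               lda=LinearClassifier(weight=np.zeros(6), bias=0.0))
        res = decode_trial(rng.normal(size=(1024, 21)), bundle)
        assert res.decision_value == 0.0
        assert res.label == CLASS_RIGHT
        assert res.command == "right"

    def test_untrained_bundle_rejected(self, rng):
        spatial = SpatialModel(projection=np.eye(21), filters=np.eye(21)[:6],
                               eigenvalues=np.ones(21), global_mean=None)
        bundle = DecoderBundle(spatial=spatial,
                               lda=LinearClassifier(weight=np.zeros(6), bias=0.0))
        with pytest.raises(ValueError):
            decode_trial(rng.normal(size=(1024, 21)), bundle)

    def test_bundle_round_trips_through_json(self, rng):
        import json

        run1 = _gaussian_trials(_random_spd(6, rng), 10, 256, rng, label=CLASS_RIGHT)
        run2 = _gaussian_trials(_random_spd(6, rng), 10, 256, rng, label=CLASS_LEFT)
        from mitrain.decoding import fit_decoder

        bundle = fit_decoder([run1 + run2])
        restored = bundle_from_dict(json.loads(json.dumps(bundle_to_dict(bundle))))
        assert np.allclose(restored.spatial.filters, bundle.spatial.filters)
        assert np.allclose(restored.spatial.global_mean, bundle.spatial.global_mean)
        assert np.allclose(restored.lda.weight, bundle.lda.weight)
        assert restored.filter_spec == bundle.filter_spec
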