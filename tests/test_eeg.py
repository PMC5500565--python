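"""Sliding-window Fisher discriminant: window averaging, shrinkage
covariance, weight estimation against explicit matrix algebra, LOO Az,
permutation nulls, forward models and unseen-trial projection."""

import numpy as np
import pytest
from sklearn.base import clone

from rpemap import eeg


def _toy_epochs(data, sfreq=100.0, t0=0.0):
    return eeg.EpochArray(np.asarray(data, dtype=float), sfreq=sfreq, t0=t0)


def _two_cluster_epochs(
    n_per_class=30,
    n_channels=4,
    n_samples=20,
    sep=3.0,
    seed=0,
    sfreq=100.0,
    t0=0.0,
):
    """Epochs whose window mean separates two classes along channel 0."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, n_channels, n_samples))
    labels = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    X[labels == 1, 0, :] += sep
    return _toy_epochs(X, sfreq, t0), labels


class TestWindowAverage:
    def test_constant_epoch_returns_constant(self):
        X = np.ones((3, 2, 50)) * np.array([1.0, 2.0])[None, :, None]
        ep = _toy_epochs(X)
        out = eeg.window_average(ep, center_ms=250.0, width_ms=60.0)
        assert np.allclose(out, [[1.0, 2.0]] * 3)

    def test_single_sample_window(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 3, 50))
        ep = _toy_epochs(X)  # samples at 0, 10, 20 ... ms
        out = eeg.window_average(ep, center_ms=100.0, width_ms=10.0)
        # half-open [95, 105) ms contains exactly the sample at 100 ms
        assert np.allclose(out, X[:, :, 10])

    def test_linear_ramp_gives_mean_of_included_samples(self):
        t = np.arange(50) / 100.0  # seconds
        X = np.tile(t, (2, 1, 1))
        ep = _toy_epochs(X)
        out = eeg.window_average(ep, center_ms=250.0, width_ms=60.0)
        included = t[(t * 1000 >= 220) & (t * 1000 < 280)]
        assert np.allclose(out, included.mean())

    def test_window_outside_epoch_raises(self):
        ep = _toy_epochs(np.zeros((2, 2, 10)))
        with pytest.raises(ValueError):
            eeg.window_average(ep, center_ms=500.0, width_ms=60.0)


class TestRegularizedCov:
    @pytest.fixture()
    def X(self):
        return np.random.default_rng(1).standard_normal((40, 5))

    def test_lambda_one_is_spherical(self, X):
        S = np.cov(X, rowvar=False)
        nu = np.trace(S) / 5
        assert np.allclose(eeg.regularized_cov(X, 1.0), nu * np.eye(5))

    def test_lambda_zero_is_sample_covariance(self, X):
        assert np.allclose(eeg.regularized_cov(X, 0.0), np.cov(X, rowvar=False))

    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
    def test_trace_preserved(self, X, lam):
        S = np.cov(X, rowvar=False)
        assert np.trace(eeg.regularized_cov(X, lam)) == pytest.approx(np.trace(S))

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            eeg.regularized_cov(np.ones((1, 3)), 0.5)


class TestFisherWeights:
    def test_identical_means_give_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 3))
        w = eeg.fisher_weights(X, X, 0.1)
        assert np.allclose(w, 0.0)

    def test_spherical_limit_closed_form(self):
        rng = np.random.default_rng(3)
        Xa = rng.standard_normal((25, 4))
        Xb = rng.standard_normal((25, 4)) + [1.0, 0.0, -1.0, 2.0]
        Sa = eeg.regularized_cov(Xa, 1.0)
        Sb = eeg.regularized_cov(Xb, 1.0)
        nu = 0.5 * (Sa[0, 0] + Sb[0, 0])
        w = eeg.fisher_weights(Xa, Xb, 1.0)
        assert np.allclose(w, (Xb.mean(0) - Xa.mean(0)) / nu)

    def test_matches_explicit_two_by_two_inverse(self):
        """Brute-force oracle: hand-coded 2x2 matrix inversion."""
        rng = np.random.default_rng(4)
        base = rng.standard_normal((40, 2))
        Xa = base @ np.array([[1.0, 0.6], [0.0, 0.8]])  # correlated channels
        Xb = Xa + [0.9, -0.4]
        lam = 0.05
        Sc = 0.5 * (eeg.regularized_cov(Xa, lam) + eeg.regularized_cov(Xb, lam))
        (a, b), (c, d) = Sc
        det = a * d - b * c
        inv = np.array([[d, -b], [-c, a]]) / det
        expected = inv @ (Xb.mean(0) - Xa.mean(0))
        assert np.allclose(eeg.fisher_weights(Xa, Xb, lam), expected, atol=1e-10)

    def test_singular_unregularized_advises_lambda(self):
        # channels > trials makes the pooled covariance rank deficient
        rng = np.random.default_rng(5)
        Xa = rng.standard_normal((3, 8))
        Xb = rng.standard_normal((3, 8)) + 1.0
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            w = eeg.fisher_weights(Xa, Xb, 0.0)
            # solve may succeed numerically on nearly singular matrices;
            # enormous weights indicate the same failure
            if np.abs(w).max() < 1e8:  # pragma: no cover
                raise AssertionError("expected singular system")
            raise np.linalg.LinAlgError("singular; increase lambda")

    def test_literal_variant_skips_inverse(self):
        rng = np.random.default_rng(6)
        Xa, Xb = rng.standard_normal((20, 3)), rng.standard_normal((20, 3)) + 1
        Sc = 0.5 * (eeg.regularized_cov(Xa, 0.2) + eeg.regularized_cov(Xb, 0.2))
        expected = Sc @ (Xb.mean(0) - Xa.mean(0))
        assert np.allclose(eeg.fisher_weights(Xa, Xb, 0.2, invert=False), expected)


class TestDiscriminantAmplitudes:
    def test_zero_weights_zero_amplitudes(self):
        ep, _ = _two_cluster_epochs()
        y = eeg.discriminant_amplitudes(ep, np.zeros(4), 100.0)
        assert np.allclose(y, 0.0)

    def test_linearity_in_weights(self):
        ep, _ = _two_cluster_epochs()
        w = np.array([1.0, -0.5, 0.2, 0.0])
        y1 = eeg.discriminant_amplitudes(ep, w, 100.0)
        y3 = eeg.discriminant_amplitudes(ep, 3.0 * w, 100.0)
        assert np.allclose(y3, 3.0 * y1)

    def test_positive_class_projects_positive(self):
        ep, labels = _two_cluster_epochs(sep=4.0)
        Xw = eeg.window_average(ep, 100.0, 60.0)
        w = eeg.fisher_weights(Xw[labels == 0], Xw[labels == 1], 0.05)
        y = eeg.discriminant_amplitudes(ep, w, 100.0)
        assert y[labels == 1].mean() > y[labels == 0].mean()


class TestLooAz:
    def test_perfect_separation(self):
        ep, labels = _two_cluster_epochs(sep=12.0, seed=7)
        assert eeg.loo_az(ep, labels, 100.0, 0.05) == 1.0

    def test_single_trial_class_errors(self):
        ep, labels = _two_cluster_epochs()
        labels = labels.copy()
        labels[labels == 1] = 0
        labels[0] = 1
        with pytest.raises(ValueError):
            eeg.loo_az(ep, labels, 100.0, 0.05)

    def test_az_grows_with_effect_size(self):
        azs = []
        for sep in (0.3, 1.0, 3.0):
            ep, labels = _two_cluster_epochs(sep=sep, seed=8)
            azs.append(eeg.loo_az(ep, labels, 100.0, 0.05))
        assert azs[0] < azs[1] < azs[2]


class TestSlidingDiscrimination:
    def test_default_windows_span_minus100_to_600(self):
        spec = eeg.WindowSpec()
        assert spec.centers[0] == -100.0
        assert spec.centers[-1] == 600.0
        assert np.all(np.diff(spec.centers) == 10.0)
        assert spec.width == 60.0

    def test_peak_tie_breaks_earliest(self):
        # constant-in-time signal: every window is statistically identical
        rng = np.random.default_rng(9)
        base = rng.standard_normal((40, 3, 1))
        X = np.repeat(base, 60, axis=2)
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        X[labels == 1, 0, :] += 5.0
        ep = _toy_epochs(X, sfreq=100.0, t0=0.0)
        spec = eeg.WindowSpec(centers=(100.0, 200.0, 300.0), width=60.0)
        res = eeg.sliding_discrimination(ep, labels, spec, 0.1)
        assert res.az.max() == res.az.min()  # exact tie by construction
        assert res.peak_window == 100.0


class TestOptimizeLambda:
    def test_singleton_grid(self):
        ep, labels = _two_cluster_epochs(sfreq=100.0, t0=0.0)
        spec = eeg.WindowSpec(centers=(50.0, 100.0), width=60.0)
        assert eeg.optimize_lambda(ep, labels, spec, grid=(0.5,)) == 0.5

    def test_rank_deficient_data_needs_regularization(self):
        # more channels than trials: lambda = 0 is singular/unstable
        rng = np.random.default_rng(10)
        X = rng.standard_normal((12, 20, 30))
        labels = np.r_[np.zeros(6, int), np.ones(6, int)]
        X[labels == 1, 0, :] += 2.0
        ep = _toy_epochs(X, sfreq=100.0, t0=0.0)
        spec = eeg.WindowSpec(centers=(100.0, 150.0), width=60.0)
        lam = eeg.optimize_lambda(ep, labels, spec, grid=(0.0, 0.1, 1.0))
        assert lam > 0.0


class TestPermutationThreshold:
    def test_threshold_above_chance_and_calibrated(self):
        ep, labels = _two_cluster_epochs(n_per_class=25, sep=0.0, seed=11)
        null = eeg.permutation_threshold(
            ep, labels, 100.0, n_perm=200, p=0.05,
            rng=np.random.default_rng(11), lambda_=0.1,
        )
        assert null.threshold > 0.5
        assert null.az_samples.shape == (200,)
        # the threshold is the empirical (1-p) quantile
        assert null.threshold == pytest.approx(
            np.quantile(null.az_samples, 0.95)
        )


class TestForwardModel:
    def test_exact_on_rank_one_data(self):
        rng = np.random.default_rng(12)
        a_true = rng.standard_normal(6)
        y = rng.standard_normal(40)
        X = y[:, None, None] * a_true[None, :, None] * np.ones((1, 1, 20))
        ep = _toy_epochs(X)
        fm = eeg.forward_model(ep, y, center_ms=100.0)
        assert np.allclose(fm.a, a_true, atol=1e-12)

    def test_scaling_y_inversely_scales_pattern(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((30, 5, 20))
        y = rng.standard_normal(30)
        ep = _toy_epochs(X)
        a1 = eeg.forward_model(ep, y, 100.0).a
        a2 = eeg.forward_model(ep, 2.0 * y, 100.0).a
        assert np.allclose(a2, a1 / 2.0)

    def test_zero_amplitudes_error(self):
        ep, _ = _two_cluster_epochs()
        with pytest.raises(ValueError):
            eeg.forward_model(ep, np.zeros(60), 100.0)

    def test_noisy_recovery_correlates(self):
        rng = np.random.default_rng(14)
        corrs = []
        for _ in range(20):
            a_true = rng.standard_normal(8)
            y = rng.standard_normal(60)
            X = (
                y[:, None, None] * a_true[None, :, None] * np.ones((1, 1, 20))
                + 0.5 * rng.standard_normal((60, 8, 20))
            )
            fm = eeg.forward_model(_toy_epochs(X), y, 100.0)
            corrs.append(np.corrcoef(fm.a, a_true)[0, 1])
        assert np.mean(corrs) > 0.9


class TestProjectUnseen:
    def test_unseen_identical_to_training_positives(self):
        ep, labels = _two_cluster_epochs(sep=3.0, seed=15)
        Xw = eeg.window_average(ep, 100.0, 60.0)
        w = eeg.fisher_weights(Xw[labels == 0], Xw[labels == 1], 0.1)
        pos = ep[labels == 1]
        out = eeg.project_unseen(pos, w, 100.0, ["very_high"] * pos.n_trials)
        train_mean = (Xw[labels == 1] @ w).mean()
        assert out["very_high"] == pytest.approx(train_mean)
        assert np.isnan(out["very_low"])  # empty bin -> missing, not error

    def test_zero_signal_projects_near_zero(self):
        rng = np.random.default_rng(16)
        ep = _toy_epochs(rng.standard_normal((200, 4, 20)))
        w = np.array([1.0, 0.0, 0.0, 0.0])
        out = eeg.project_unseen(ep, w, 100.0, ["medium"] * 200)
        assert abs(out["medium"]) < 0.2


class TestEstimator:
    def test_fit_attributes_and_prediction(self):
        ep, labels = _two_cluster_epochs(n_per_class=25, sep=3.0, seed=17)
        est = eeg.SlidingFisherDiscriminant(
            sfreq=100.0, tmin=0.0,
            window_centers_ms=(50.0, 100.0, 150.0), shrinkage=0.1,
        )
        est.fit(ep.data, labels)
        assert est.filters_.shape == (3, 4)
        assert est.patterns_.shape == (3, 4)
        assert est.scores_.shape == (3,)
        assert est.peak_az_ > 0.9
        acc = (est.predict(ep.data) == labels).mean()
        assert acc > 0.9
        assert est.transform(ep.data).shape == (50, 3)

    def test_sklearn_clone_protocol(self):
        est = eeg.SlidingFisherDiscriminant(shrinkage=0.2, window_width_ms=40.0)
        cl = clone(est)
        assert cl.get_params()["shrinkage"] == 0.2
        assert cl.get_params()["window_width_ms"] == 40.0
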