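import numpy as np
import pytest
from scipy.special import expit

from gradedbci.decode import (
    BetaRegression,
    SVRDecoder,
    _beta_loglik,
    make_decoder,
    median_abs_error,
    rolling_training_set,
    scale_angle,
    unscale_angle,
)


def simulate_beta(rng, n, p, beta, b0=0.0, phi=50.0):
    X = rng.standard_normal((n, p))
    mu = expit(b0 + X @ beta)
    y = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-3, 1 - 1e-3)
    return X, y


class TestScaleAngle:
    @pytest.mark.parametrize(
        "angle,expected", [(90, 0.5), (0, 0.001), (180, 0.999), (165, 0.91667)]
    )
    def test_values(self, angle, expected):
        assert scale_angle(angle) == pytest.approx(expected, abs=1e-5)

    def test_fes_domain(self):
        assert scale_angle(82.0, 36.0, 128.0) == pytest.approx(0.5)
        assert unscale_angle(0.5, 36.0, 128.0) == pytest.approx(82.0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            scale_angle(190.0)
        with pytest.raises(ValueError):
            scale_angle(-1.0)


class TestBetaRegression:
    def test_intercept_only(self, rng):
        y = np.clip(rng.beta(5, 3, size=300), 1e-3, 1 - 1e-3)
        X = np.zeros((300, 4))
        m = BetaRegression().fit(X, y)
        # the intercept-only MLE solves the digamma mean equation, which
        # sits within a few 1e-3 of the sample mean at moderate phi
        assert expit(m.intercept_) == pytest.approx(y.mean(), abs=5e-3)
        assert np.allclose(m.coef_, 0.0, atol=1e-6)
        sm = pytest.importorskip("statsmodels.othermod.betareg")
        fit = sm.BetaModel(y, np.ones((y.size, 1))).fit(disp=0)
        assert expit(m.intercept_) == pytest.approx(expit(fit.params[0]), abs=1e-5)

    def test_recovery_and_statsmodels_crosscheck(self, rng):
        beta = np.array([0.8, -0.5, 0.0, 0.3, 0.0])
        X, y = simulate_beta(rng, 500, 5, beta, b0=0.2)
        m = BetaRegression().fit(X, y)
        assert m.converged_
        # MLE recovers the generator within 3 Wald sigma
        assert np.all(np.abs(m.coef_ - beta) < 3 * m.se_)
        # independent implementation agrees
        sm = pytest.importorskip("statsmodels.othermod.betareg")
        Z = np.column_stack([np.ones(len(y)), X])
        fit = sm.BetaModel(y, Z).fit(disp=0)
        assert np.allclose(fit.params[1:6], m.coef_, atol=1e-4)
        assert np.allclose(fit.bse[1:6], m.se_, atol=1e-3)

    def test_loglik_path_monotone(self, rng):
        """The scoring iteration never decreases the log-likelihood, i.e. the
        deviance decreases monotonically."""
        X, y = simulate_beta(rng, 400, 8, rng.normal(0, 0.4, 8))
        m = BetaRegression().fit(X, y)
        assert np.all(np.diff(m.loglik_path_) >= -1e-9)

    def test_likelihood_dominance(self, rng):
        beta = np.array([0.6, -0.4, 0.2])
        X, y = simulate_beta(rng, 600, 3, beta, phi=50.0)
        m = BetaRegression().fit(X, y)
        ll_true = _beta_loglik(y, expit(X @ beta), 50.0)
        assert m.loglik_ >= ll_true - 1e-6

    def test_predict_basics(self):
        m = BetaRegression()
        m.intercept_ = 0.0
        m.coef_ = np.zeros(3)
        m.phi_ = 10.0
        m.n_features_in_ = 3
        assert m.predict(np.zeros((1, 3)))[0] == pytest.approx(0.5)

    def test_flat_channel_invariance(self, rng):
        """Adding a channel with zero coefficient never changes predictions."""
        X, y = simulate_beta(rng, 300, 4, np.array([0.5, -0.3, 0.2, 0.0]))
        m = BetaRegression().fit(X, y)
        base = m.predict(X)
        m.coef_ = np.append(m.coef_, 0.0)
        m.n_features_in_ = 5
        extended = m.predict(np.column_stack([X, rng.standard_normal(300)]))
        assert np.allclose(base, extended)

    def test_monotone_in_positive_coefficient(self, rng):
        X, y = simulate_beta(rng, 300, 3, np.array([0.8, 0.0, 0.0]))
        m = BetaRegression().fit(X, y)
        x = np.zeros((2, 3))
        x[1, 0] = 1.0
        lo, hi = m.predict(x)
        assert (hi > lo) == (m.coef_[0] > 0)

    def test_too_few_frames(self, rng):
        X, y = simulate_beta(rng, 50, 96, np.zeros(96))
        with pytest.raises(ValueError):
            BetaRegression().fit(X, y)

    def test_significant_channel_counts(self, rng):
        """On generator defaults the per-channel Wald tests detect most
        informative channels, and false positives on flat channels stay
        within the binomial band once the frames are thinned to
        independence (the 1 s smoothing boxcar autocorrelates consecutive
        frames, which makes full-resolution Wald tests anti-conservative)."""
        from gradedbci.task_design import make_block, make_virtual_session
        from gradedbci.synthetic import assign_profiles, simulate_mwp

        profiles = assign_profiles(56, seed=0)
        cues = []
        t0 = 0.0
        for spec in make_virtual_session(0):
            cs = make_block(spec, t0)
            t0 = cs[-1].offset_s
            cues += cs
        t, X = simulate_mwp(cues, profiles, seed=1)
        onsets = np.array([c.onset_s for c in cues])
        angs = np.array([c.target_angle_deg for c in cues])
        idx = np.clip(np.searchsorted(onsets, t - 0.75, side="right") - 1, 0, None)
        y = scale_angle(angs[idx])
        Xs = (X - X.mean(0)) / X.std(0)
        informative = np.array([p.klass != "flat" for p in profiles])
        # full-resolution fit: high power on informative channels
        m = BetaRegression().fit(Xs, y)
        sig = m.p_values_ < 0.05
        assert sig[informative].sum() >= 0.6 * informative.sum()
        # thinned fit (one frame per smoothing window): calibrated false
        # positives — Bin(40, 0.05) stays below 8 with 99.9% probability
        m10 = BetaRegression().fit(Xs[::10], y[::10])
        assert (m10.p_values_[~informative] < 0.05).sum() <= 8


class TestSVRDecoder:
    def test_interpolation_bound(self, rng):
        X = rng.standard_normal((300, 8))
        y = np.clip(expit(X[:, 0]), 1e-3, 1 - 1e-3)
        m = SVRDecoder(epsilon=0.05).fit(X, y)
        mae = median_abs_error(unscale_angle(m.predict(X)), unscale_angle(y))
        assert mae <= 0.05 * 180 + 2.0

    def test_constant_target(self, rng):
        X = rng.standard_normal((200, 5))
        y = np.full(200, 0.4)
        m = SVRDecoder().fit(X, y)
        assert np.allclose(m.predict(X), 0.4, atol=m.epsilon + 1e-6)

    def test_predict_one_matches_batch(self, rng):
        X = rng.standard_normal((300, 8))
        y = np.clip(expit(X[:, 0] - 0.5 * X[:, 1]), 1e-3, 1 - 1e-3)
        m = SVRDecoder().fit(X, y)
        batch = m.predict(X[:10])
        single = np.array([m.predict_one(x) for x in X[:10]])
        assert np.allclose(batch, single, atol=1e-10)

    def test_make_decoder(self):
        assert isinstance(make_decoder("beta"), BetaRegression)
        assert isinstance(make_decoder("svr"), SVRDecoder)
        with pytest.raises(ValueError):
            make_decoder("mlp")


class TestRollingFit:
    def test_window(self, rng):
        blocks = [
            (np.full((10, 2), i, dtype=float), np.full(10, 0.5)) for i in range(5)
        ]
        X, y = rolling_training_set(blocks)
        assert set(np.unique(X)) == {2.0, 3.0, 4.0}
        X1, _ = rolling_training_set(blocks[:1])
        assert set(np.unique(X1)) == {0.0}
        with pytest.raises(ValueError):
            rolling_training_set([])


class TestMedianAbsError:
    def test_examples(self):
        assert median_abs_error([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert median_abs_error([60.0, 70.0], [50.0, 60.0]) == 10.0
        assert median_abs_error([50, 80, 120], [52.5, 90, 127.5]) == 7.5

    def test_errors(self):
        with pytest.raises(ValueError):
            median_abs_error([], [])
        with pytest.raises(ValueError):
            median_abs_error([1.0], [1.0, 2.0])
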