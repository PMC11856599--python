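"""Mixture-model formulas, likelihood, HPD machinery and identification rules."""

import numpy as np
import pytest
from scipy.special import expit

import gazestrat as gs
from gazestrat.mem import (
    MemData,
    MemParameters,
    MemPosterior,
    SamplerConfig,
    fit,
    hpd_interval,
    identify_cutoff,
    identify_hpd,
    log_likelihood,
    selection_probability,
    success_probability,
)


class TestSelectionProbability:
    def test_zero_weights_give_half(self):
        assert selection_probability(np.zeros(3), np.ones(3)) == pytest.approx(0.5)

    def test_log_three_gives_three_quarters(self):
        p = selection_probability(np.array([1.0, 0, 0]), np.array([np.log(3), 0, 0]))
        assert p == pytest.approx(0.75)

    def test_matches_high_precision_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            omega = rng.normal(size=3)
            f = rng.normal(size=3)
            ours = selection_probability(omega, f)
            eta = np.longdouble(0)
            for w, x in zip(omega, f):
                eta += np.longdouble(w) * np.longdouble(x)
            ref = 1 / (1 + np.exp(-eta))
            assert abs(ours - float(ref)) < 1e-12

    def test_complement_sums_to_one(self):
        omega = np.array([0.5, -1.0, 2.0])
        f = np.random.default_rng(1).normal(size=(10, 3))
        p = selection_probability(omega, f)
        assert np.allclose(p + (1 - p), 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            selection_probability(np.zeros(2), np.zeros(3))


class TestSuccessProbability:
    def test_equal_ability_and_difficulty(self):
        assert success_probability(1.2, 1.2, 0.0, 1) == pytest.approx(0.5)
        assert success_probability(1.2, 1.2, 0.0, 2) == pytest.approx(0.5)

    def test_sensitivity_gain(self):
        assert success_probability(0.0, 0.0, np.log(3), 1) == pytest.approx(0.75)

    def test_cm_never_below_re_on_grid(self):
        grid = np.linspace(-4, 4, 9)
        for th in grid:
            for b in grid:
                for e in np.linspace(0, 3, 7):
                    assert success_probability(th, b, e, 1) >= success_probability(
                        th, b, e, 2
                    )

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            success_probability(0.0, 0.0, -0.1, 1)


def _random_instance(rng, I=4, J=3, K=2):
    data = MemData(
        y=rng.integers(0, 2, (I, J)),
        f=rng.normal(size=(I, J, K)),
        mask=np.ones((I, J), bool),
        metric_names=tuple(f"m{k}" for k in range(K)),
    )
    params = MemParameters(
        theta=rng.normal(size=I),
        b=rng.normal(size=J),
        e=np.abs(rng.normal(size=J)),
        omega=rng.normal(size=K),
    )
    return params, data


def _loglik_longdouble(params, data):
    """Brute-force mixture log likelihood in extended precision."""
    total = np.longdouble(0)
    I, J, _ = data.shape
    for i in range(I):
        for j in range(J):
            if not data.mask[i, j]:
                continue
            eta = np.longdouble(0)
            for k, w in enumerate(params.omega):
                eta += np.longdouble(w) * np.longdouble(data.f[i, j, k])
            p = 1 / (1 + np.exp(-eta))
            p1 = 1 / (1 + np.exp(-(np.longdouble(params.theta[i]) - params.b[j] + params.e[j])))
            p2 = 1 / (1 + np.exp(-(np.longdouble(params.theta[i]) - params.b[j])))
            y = data.y[i, j]
            b1 = p1 if y == 1 else 1 - p1
            b2 = p2 if y == 1 else 1 - p2
            total += np.log(p * b1 + (1 - p) * b2)
    return float(total)


class TestLogLikelihood:
    def test_degenerate_mixture_reduces_to_single_component(self):
        """Huge omega drives P(m=1) to 1 and the mixture to the CM model."""
        rng = np.random.default_rng(3)
        params, data = _random_instance(rng)
        data.f[:] = 1.0
        params.omega[:] = 400.0
        p1 = success_probability(params.theta[:, None], params.b, params.e, 1)
        pure = np.where(data.y == 1, p1, 1 - p1)
        assert log_likelihood(params, data) == pytest.approx(np.log(pure).sum())

    def test_single_cell_at_chance(self):
        data = MemData(
            y=np.array([[1, 0], [0, 1]]),
            f=np.zeros((2, 2, 1)),
            mask=np.eye(2, dtype=bool),
            metric_names=("m0",),
        )
        params = MemParameters(
            theta=np.zeros(2), b=np.zeros(2), e=np.zeros(2), omega=np.array([2.0])
        )
        assert log_likelihood(params, data) == pytest.approx(2 * np.log(0.5))

    def test_agrees_with_extended_precision(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            params, data = _random_instance(rng)
            assert log_likelihood(params, data) == pytest.approx(
                _loglik_longdouble(params, data), abs=1e-10
            )

    def test_shape_mismatch(self):
        rng = np.random.default_rng(5)
        params, data = _random_instance(rng)
        params.theta = params.theta[:-1]
        with pytest.raises(ValueError):
            log_likelihood(params, data)


class TestHpdInterval:
    def test_uniform_draws_span_their_support(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.3, 0.7, 5000)
        lo, hi = hpd_interval(x, 0.95)
        assert 0.29 < lo < 0.35
        assert 0.65 < hi < 0.71

    def test_shortest_interval_on_skewed_draws(self):
        rng = np.random.default_rng(7)
        x = rng.beta(10, 2, 20000)
        lo, hi = hpd_interval(x, 0.9)
        qlo, qhi = np.quantile(x, [0.05, 0.95])
        assert (hi - lo) <= (qhi - qlo) + 1e-9


def _posterior_from_pcm(p_draws):
    """Wrap fixed P(m=1) draws (S,) into a 1x1-cell posterior via logit-f."""
    S = p_draws.shape[0]
    f = np.ones((1, 1, 1))
    omega = np.log(p_draws / (1 - p_draws)).reshape(1, S, 1)
    data = MemData(
        y=np.array([[1]]), f=f, mask=np.ones((1, 1), bool), metric_names=("m0",)
    )
    return MemPosterior(
        data=data,
        theta=np.zeros((1, S, 1)),
        b=np.zeros((1, S, 1)),
        e=np.zeros((1, S, 1)),
        omega=omega,
        diagnostics={},
        accept_rates={},
    )


class TestIdentificationRules:
    def test_cutoff_rule_examples(self):
        post = _posterior_from_pcm(np.full(200, 0.9))
        assert identify_cutoff(post, 0.5).labels[0, 0] == "CM"
        post = _posterior_from_pcm(np.full(200, 0.3))
        assert identify_cutoff(post, 0.5).labels[0, 0] == "RE"

    def test_cutoff_above_half_can_yield_ie(self):
        post = _posterior_from_pcm(np.full(200, 0.6))
        assert identify_cutoff(post, 0.7).labels[0, 0] == "IE"

    def test_cutoff_half_is_binary(self):
        rng = np.random.default_rng(8)
        post = _posterior_from_pcm(rng.uniform(0.05, 0.95, 500))
        labels = identify_cutoff(post, 0.5).labels
        assert set(np.unique(labels)) <= {"CM", "RE"}

    def test_hpd_rule_examples(self):
        rng = np.random.default_rng(9)
        post = _posterior_from_pcm(rng.uniform(0.8, 0.95, 1000))
        assert identify_hpd(post, 0.95).labels[0, 0] == "CM"
        post = _posterior_from_pcm(rng.uniform(0.05, 0.2, 1000))
        assert identify_hpd(post, 0.95).labels[0, 0] == "RE"
        post = _posterior_from_pcm(rng.uniform(0.3, 0.7, 1000))
        assert identify_hpd(post, 0.95).labels[0, 0] == "IE"

    def test_hpd_needs_draws(self):
        post = _posterior_from_pcm(np.linspace(0.4, 0.6, 50))
        with pytest.raises(ValueError, match="100 draws"):
            identify_hpd(post)

    def test_invalid_cutoff(self):
        post = _posterior_from_pcm(np.full(200, 0.6))
        with pytest.raises(ValueError):
            identify_cutoff(post, 1.0)


class TestFit:
    @pytest.fixture(scope="class")
    def small_fit(self):
        cfg = gs.simulate.SimConfig(seed=13, n_participants=40, n_items=8)
        truth = gs.simulate.generate_truth(cfg)
        feats = gs.simulate.simulate_features(truth, cfg)
        data = MemData.from_features(feats)
        post = fit(data, SamplerConfig(chains=2, iterations=600, seed=5))
        return truth, post

    def test_sensitivity_draws_nonnegative(self, small_fit):
        _, post = small_fit
        assert (post.e >= 0).all()

    def test_draw_shapes_and_diagnostics(self, small_fit):
        _, post = small_fit
        assert post.theta.shape == (2, 300, 40)
        assert post.omega.shape[2] == 3
        assert "max_rhat" in post.diagnostics

    def test_selection_probabilities_separate_strategies(self, small_fit):
        """Posterior P(m=1) is higher on true CM trials than true RE trials.

        Individual weight signs are only weakly identified at this small
        scale (the standardized metrics are collinear); the fitted selection
        probability itself must still discriminate.
        """
        truth, post = small_fit
        pm = post.p_cm_mean()
        assert pm[truth.strategy == "CM"].mean() > pm[truth.strategy == "RE"].mean() + 0.3

    def test_posterior_mean_pcm_in_unit_interval(self, small_fit):
        _, post = small_fit
        pm = post.p_cm_mean()
        assert ((pm > 0) & (pm < 1)).all()

    def test_requires_minimum_size(self):
        data = MemData(
            y=np.zeros((1, 3), int),
            f=np.zeros((1, 3, 1)),
            mask=np.ones((1, 3), bool),
            metric_names=("m0",),
        )
        with pytest.raises(ValueError):
            fit(data, SamplerConfig(chains=1, iterations=100, seed=0))
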