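"""Maximum-entropy core: oracle equivalence, outputs, gain, serialization.

The independent oracle is a dense (progressively refined) grid search over
the penalized objective — no gradients, no solver — evaluated directly
from the definition l(lambda) = mean(lambda.f_presence) − ln Z − beta|lambda|.
"""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp

from nicheshift.maxent_core import (
    ConvergenceError,
    FeatureConfig,
    FeatureExpansion,
    MaxentModel,
    fit_maxent,
)


def penalized_objective(lam, F_p, F_b, beta):
    lam = np.atleast_1d(lam)
    return float(np.mean(F_p @ lam) - logsumexp(F_b @ lam) - np.sum(beta * np.abs(lam)))


def grid_search_oracle(F_p, F_b, beta, lo=-20.0, hi=20.0, levels=4, n=81):
    """Dense grid search over lambda, progressively refined around the best."""
    p = F_p.shape[1]
    center = np.zeros(p)
    half = (hi - lo) / 2.0
    best_lam, best_val = center, penalized_objective(center, F_p, F_b, beta)
    for _ in range(levels):
        axes = [np.linspace(c - half, c + half, n) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        lams = np.stack([g.ravel() for g in grids], axis=1)
        vals = (
            F_p @ lams.T
        ).mean(axis=0) - logsumexp(F_b @ lams.T, axis=0) - np.abs(lams) @ beta
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val, best_lam = float(vals[i]), lams[i]
        center = lams[i]
        half = 2.0 * half / (n - 1)  # keep a margin around the refined cell
    return best_lam, best_val


@pytest.fixture
def small_instance():
    """1 feature, 6 background cells, 3 presences — oracle-checkable by hand."""
    rng = np.random.default_rng(0)
    F_b = rng.uniform(0, 1, (6, 1))
    F_p = F_b[[0, 1, 2]]
    return F_p, F_b


class TestFit:
    def test_huge_regularization_gives_uniform(self, small_instance):
        F_p, F_b = small_instance
        model = fit_maxent(F_p, F_b, r=1e6)
        assert np.all(model.lam == 0)
        np.testing.assert_allclose(model.raw_output(F_b), 1 / 6, rtol=1e-12)
        assert model.entropy == pytest.approx(np.log(6), rel=1e-12)

    def test_matched_means_keep_lambda_zero(self):
        # presence = the whole background -> f_bar equals the uniform mean
        rng = np.random.default_rng(1)
        F_b = rng.uniform(0, 1, (8, 1))
        model = fit_maxent(F_b, F_b, r=1.0)
        assert np.all(model.lam == 0)

    def test_against_grid_search_oracle(self, small_instance):
        F_p, F_b = small_instance
        model = fit_maxent(F_p, F_b, r=0.5)
        lam_star, val_star = grid_search_oracle(F_p, F_b, model.beta)
        assert model.lam[0] == pytest.approx(lam_star[0], abs=1e-3)
        # oracle raw weights
        eta = F_b[:, 0] * lam_star[0]
        q_oracle = np.exp(eta - logsumexp(eta))
        np.testing.assert_allclose(model.raw_output(F_b), q_oracle, atol=1e-6)
        # gain against the oracle definition
        gain_oracle = float(np.mean(F_p[:, 0] * lam_star[0]) - logsumexp(eta) + np.log(6))
        assert model.gain(F_p) == pytest.approx(gain_oracle, abs=1e-6)

    def test_normalization_after_fit(self, small_instance):
        F_p, F_b = small_instance
        model = fit_maxent(F_p, F_b, r=1.0)
        assert model.raw_output(F_b).sum() == pytest.approx(1.0, abs=1e-8)

    def test_m_below_two_rejected(self, small_instance):
        _, F_b = small_instance
        with pytest.raises(ValueError):
            fit_maxent(F_b[:1], F_b)

    def test_monotone_regularization(self):
        rng = np.random.default_rng(7)
        F_b = rng.uniform(0, 1, (30, 3))
        F_p = F_b[rng.choice(30, 10, replace=False)]
        gains = [fit_maxent(F_p, F_b, r=r).gain(F_p) for r in (0.25, 0.5, 1, 2, 4)]
        assert np.all(np.diff(gains) <= 1e-9)

    def test_concavity_at_optimum(self, small_instance):
        F_p, F_b = small_instance
        rng = np.random.default_rng(99)
        model = fit_maxent(F_p, F_b, r=0.5)
        val_star = penalized_objective(model.lam, F_p, F_b, model.beta)
        for _ in range(100):
            delta = rng.normal(size=model.lam.shape)
            delta *= 0.01 / np.linalg.norm(delta)
            assert penalized_objective(model.lam + delta, F_p, F_b, model.beta) <= val_star + 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n_bg=st.integers(4, 20),
    p=st.integers(1, 2),
    m=st.integers(2, 4),
    r=st.sampled_from([0.25, 1.0, 2.0]),
    seed=st.integers(0, 10_000),
)
def test_oracle_equivalence_property(n_bg, p, m, r, seed):
    """Fitted penalized objective within 1e-4 of the dense grid-search optimum."""
    rng = np.random.default_rng(seed)
    F_b = rng.uniform(0, 1, (n_bg, p))
    F_p = F_b[rng.choice(n_bg, size=min(m, n_bg), replace=False)]
    if len(F_p) < 2:
        return
    try:
        model = fit_maxent(F_p, F_b, r=r)
    except ConvergenceError:
        pytest.fail("solver did not converge on a tiny instance")
    _, val_oracle = grid_search_oracle(F_p, F_b, model.beta)
    val_fit = penalized_objective(model.lam, F_p, F_b, model.beta)
    assert val_fit >= val_oracle - 1e-4


class TestOutputs:
    def test_uniform_logistic_is_half(self, small_instance):
        F_p, F_b = small_instance
        model = fit_maxent(F_p, F_b, r=1e6)
        np.testing.assert_allclose(model.logistic_output(F_b), 0.5, rtol=1e-12)
        assert model.gain(F_p) == pytest.approx(0.0, abs=1e-12)

    def test_logistic_matches_hand_formula(self, small_instance):
        F_p, F_b = small_instance
        model = fit_maxent(F_p, F_b, r=0.5)
        q = model.raw_output(F_b)
        hand = q * np.exp(model.entropy) / (1 + q * np.exp(model.entropy))
        np.testing.assert_allclose(model.logistic_output(F_b), hand, atol=1e-9)

    def test_logistic_monotone_and_limits(self, small_instance):
        F_p, F_b = small_instance
        model = fit_maxent(F_p, F_b, r=0.5)
        q = np.array([1e-30, 1e-6, 1e-3, 0.5])
        s = model.logistic_from_raw(q)
        assert np.all(np.diff(s) > 0)
        assert s[0] < 1e-12

    def test_no_scale_invariance(self, small_instance):
        F_p, F_b = small_instance
        model = fit_maxent(F_p, F_b, r=0.5)
        lam2 = 2 * model.lam
        eta = F_b @ lam2
        q2 = np.exp(eta - logsumexp(eta))
        assert not np.allclose(q2, model.raw_output(F_b))


class TestFeatures:
    def test_feature_count_combinatorics(self):
        env = np.random.default_rng(2).uniform(0, 10, (50, 2))
        exp = FeatureExpansion.from_background(
            env, ["A", "B"], FeatureConfig(("linear", "quadratic", "product"))
        )
        assert exp.n_features == 2 + 2 + 1

    def test_hinge_zero_at_knot_and_linear_bounds(self):
        env = np.linspace(0, 1, 101).reshape(-1, 1)
        exp = FeatureExpansion.from_background(
            env, ["A"], FeatureConfig(("linear", "quadratic", "hinge"), hinge_knots=3)
        )
        t = exp.knots[0][0]
        F = exp.transform(np.array([[t]]))
        names = exp.feature_names
        assert F[0, names.index(f"hinge(A,{t:.6g})")] == pytest.approx(0.0, abs=1e-12)
        assert F[0, names.index(f"rhinge(A,{t:.6g})")] == pytest.approx(0.0, abs=1e-12)
        # at the background max: linear = quadratic = 1
        F_max = exp.transform(np.array([[1.0]]))
        assert F_max[0, names.index("A")] == 1.0
        assert F_max[0, names.index("A^2")] == 1.0

    def test_clamping_caps_projection_beyond_training_range(self):
        env = np.linspace(0, 1, 11).reshape(-1, 1)
        exp = FeatureExpansion.from_background(env, ["A"], FeatureConfig(("linear",)))
        assert exp.transform(np.array([[2.0]]), clamp=True)[0, 0] == 1.0
        assert exp.transform(np.array([[2.0]]), clamp=False)[0, 0] == 2.0

    def test_constant_variable_dropped_with_warning(self):
        env = np.column_stack([np.linspace(0, 1, 20), np.full(20, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            exp = FeatureExpansion.from_background(env, ["A", "B"], FeatureConfig(("linear",)))
        assert exp.variables == ["A"]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(("linear", "threshold"))


class TestSerialization:
    def test_json_round_trip_lossless(self, small_instance):
        F_p, F_b = small_instance
        env = np.random.default_rng(5).uniform(0, 30, (40, 2))
        exp = FeatureExpansion.from_background(env, ["BIO1", "BIO12"])
        Fb = exp.transform(env)
        Fp = Fb[:5]
        model = fit_maxent(Fp, Fb, exp, r=1.0)
        text = model.to_json()
        back = MaxentModel.from_json(text)
        np.testing.assert_array_equal(back.lam, model.lam)
        np.testing.assert_array_equal(back.beta, model.beta)
        assert back.log_Z == model.log_Z
        assert back.entropy == model.entropy
        assert back.expansion.variables == model.expansion.variables
        np.testing.assert_array_equal(back.expansion.lo, model.expansion.lo)
        # projected outputs identical after round-trip
        np.testing.assert_array_equal(back.raw_output(Fb), model.raw_output(Fb))
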