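"""Mood model: feedback coding, TML recursion, enumeration, likelihood."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from moodchoice import mood
from moodchoice.mood import (MoodModelSpec, MoodParams, code_feedback,
                             compute_tml, enumerate_mood_models,
                             interpolate_ratings, mood_loglik,
                             subjective_feedback)

from conftest import make_table


def brute_force_tml(feedback, accuracy, spec, params, ev_choice=None):
    """Reference O(n^2) evaluation of the decaying-sum mood equation."""
    n = len(feedback)
    ev_q = 2.0 * np.asarray(accuracy, dtype=float) - 1.0
    pos = params.R if spec.asymmetric else 1.0
    coded = np.where(np.asarray(feedback) > 0, pos, -1.0)
    if spec.simplified:
        wq1 = wq2 = params.omega_f
    else:
        wq1, wq2 = params.omega_q1, params.omega_q2
    ev_c = np.zeros(n) if ev_choice is None else np.asarray(ev_choice, float)
    tml = np.zeros(n)
    f = np.zeros(n)
    for t in range(n):
        tml_prev = tml[t - 1] if t > 0 else 0.0
        delta = params.delta if spec.reciprocal else 0.0
        f[t] = coded[t] + delta * tml_prev
        val = params.omega0 + params.omega_t * (t + 1)
        if spec.uses_quiz:
            for j in range(t + 1):
                w = params.gamma ** (t - j)
                val += wq1 * w * ev_q[j] + wq2 * w * (f[j] - ev_q[j])
        if spec.uses_choice:
            for j in range(t + 1):
                val += params.omega_p * params.gamma ** (t - j) * ev_c[j]
        tml[t] = val
    return tml


class TestFeedbackCoding:
    def test_asymmetric_positive_uses_r(self):
        spec = MoodModelSpec(source="quiz_only", asymmetric=True)
        p = MoodParams(R=2.5)
        assert code_feedback(1, spec, p) == pytest.approx(2.5)

    def test_symmetric_positive_is_one(self):
        spec = MoodModelSpec(source="quiz_only")
        assert code_feedback(1, spec, MoodParams(R=2.5)) == pytest.approx(1.0)

    def test_negative_always_minus_one(self):
        spec = MoodModelSpec(source="quiz_only", asymmetric=True)
        assert code_feedback(-1, spec, MoodParams(R=2.5)) == pytest.approx(-1.0)

    def test_invalid_feedback_rejected(self):
        spec = MoodModelSpec(source="quiz_only")
        with pytest.raises(ValueError):
            code_feedback(0, spec, MoodParams())

    @pytest.mark.parametrize("coded,prev,delta,expected", [
        (-1.0, 1.0, 0.5, -0.5),
        (1.0, 7.3, 0.0, 1.0),
        (1.0, 0.0, 0.5, 1.0),
    ])
    def test_subjective_feedback(self, coded, prev, delta, expected):
        p = MoodParams(delta=delta)
        assert subjective_feedback(coded, prev, p) == pytest.approx(expected)


class TestTml:
    def test_decaying_feedback_sum(self):
        table = make_table([1, -1, 1])
        spec = MoodModelSpec(source="quiz_only", simplified=True)
        p = MoodParams(omega_f=1.0, gamma=0.5)
        tml = compute_tml(table, spec, p).tml
        assert tml[2] == pytest.approx(0.25 * 1 + 0.5 * (-1) + 1 * 1)
        np.testing.assert_allclose(tml, [1.0, -0.5, 0.75])

    def test_reciprocal_hand_unrolled(self):
        table = make_table([1, -1, 1])
        spec = MoodModelSpec(source="quiz_only", simplified=True,
                             reciprocal=True)
        p = MoodParams(omega_f=1.0, gamma=0.5, delta=0.5)
        trace = compute_tml(table, spec, p)
        np.testing.assert_allclose(trace.f, [1.0, -0.5, 1.0], atol=1e-12)
        np.testing.assert_allclose(trace.tml, [1.0, 0.0, 1.0], atol=1e-12)

    def test_null_model_is_linear_in_time(self):
        table = make_table([1, -1, 1, 1])
        spec = MoodModelSpec(source="null")
        p = MoodParams(omega0=0.2, omega_t=-0.01)
        tml = compute_tml(table, spec, p).tml
        np.testing.assert_allclose(tml, 0.2 - 0.01 * np.arange(1, 5))

    def test_missing_accuracy_rejected(self):
        table = make_table([1, -1])
        table.loc[0, "accuracy_mean"] = np.nan
        spec = MoodModelSpec(source="quiz_only", simplified=True)
        with pytest.raises(ValueError, match="accuracy_mean"):
            compute_tml(table, spec, MoodParams())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        gamma=st.floats(0.0, 1.0),
        delta=st.floats(-0.5, 0.5),
        r=st.floats(0.2, 3.0),
        simplified=st.booleans(),
        asymmetric=st.booleans(),
        reciprocal=st.booleans(),
    )
    def test_recursion_matches_brute_force(self, seed, gamma, delta, r,
                                           simplified, asymmetric, reciprocal):
        rng = np.random.default_rng(seed)
        n = 200
        fb = rng.choice([-1, 1], size=n)
        acc = rng.choice([0.35, 0.6, 0.8], size=n)
        table = make_table(fb, accuracy=0.6)
        table["accuracy_mean"] = acc
        spec = MoodModelSpec(source="quiz_only", simplified=simplified,
                             asymmetric=asymmetric, reciprocal=reciprocal)
        p = MoodParams(omega0=0.1, omega_f=0.4, omega_q1=0.3, omega_q2=0.5,
                       omega_t=-0.01, gamma=gamma, R=r, delta=delta)
        fast = compute_tml(table, spec, p).tml
        slow = brute_force_tml(fb, acc, spec, p)
        np.testing.assert_allclose(fast, slow, atol=1e-12, rtol=1e-10)

    def test_choice_source_matches_brute_force(self):
        rng = np.random.default_rng(5)
        fb = rng.choice([-1, 1], size=60)
        ev_c = rng.normal(size=60)
        table = make_table(fb)
        spec = MoodModelSpec(source="both")
        p = MoodParams(omega_q1=0.2, omega_q2=0.4, omega_p=0.3, gamma=0.8)
        fast = compute_tml(table, spec, p, ev_choice=ev_c).tml
        slow = brute_force_tml(fb, table["accuracy_mean"], spec, p,
                               ev_choice=ev_c)
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_gamma_zero_depends_on_current_trial_only(self):
        rng = np.random.default_rng(0)
        fb = rng.choice([-1, 1], size=50)
        table = make_table(fb)
        spec = MoodModelSpec(source="quiz_only", simplified=True)
        p = MoodParams(omega_f=0.7, gamma=0.0, omega0=0.3, omega_t=0.02)
        tml = compute_tml(table, spec, p).tml
        t = np.arange(1, 51)
        expected = 0.3 + 0.02 * t + 0.7 * np.where(fb > 0, 1.0, -1.0)
        np.testing.assert_allclose(tml, expected)

    def test_simplified_equals_full_with_equal_weights(self):
        rng = np.random.default_rng(1)
        fb = rng.choice([-1, 1], size=120)
        table = make_table(fb)
        table["accuracy_mean"] = rng.choice([0.35, 0.6, 0.8], size=120)
        simp = MoodModelSpec(source="quiz_only", simplified=True,
                             asymmetric=True, reciprocal=True)
        full = MoodModelSpec(source="quiz_only", asymmetric=True,
                             reciprocal=True)
        p_simp = MoodParams(omega_f=0.45, gamma=0.77, R=1.8, delta=0.2)
        p_full = MoodParams(omega_q1=0.45, omega_q2=0.45, gamma=0.77, R=1.8,
                            delta=0.2)
        np.testing.assert_allclose(compute_tml(table, simp, p_simp).tml,
                                   compute_tml(table, full, p_full).tml,
                                   atol=1e-12)

    def test_objective_limit_reduces_best_model(self):
        # delta = 0 and R = 1 turn the richest quiz model into plain
        # objective-feedback integration
        fb = [1, -1, -1, 1, 1]
        table = make_table(fb)
        rich = MoodModelSpec(source="quiz_only", simplified=True,
                             asymmetric=True, reciprocal=True)
        plain = MoodModelSpec(source="quiz_only", simplified=True)
        p = MoodParams(omega_f=0.5, gamma=0.6, R=1.0, delta=0.0)
        np.testing.assert_allclose(compute_tml(table, rich, p).tml,
                                   compute_tml(table, plain, p).tml)


class TestEnumeration:
    def test_family_size(self):
        specs = enumerate_mood_models()
        assert len(specs) == 18
        assert len(set(specs)) == 18

    def test_best_and_null_members_present(self):
        specs = enumerate_mood_models()
        assert MoodModelSpec(source="quiz_only", simplified=True,
                             asymmetric=True, reciprocal=True) in specs
        null = [s for s in specs if s.source == "null"]
        assert len(null) == 1
        assert null[0].free_param_names() == ["omega0", "omega_t", "obs_sd"]

    def test_flags_require_quiz_source(self):
        with pytest.raises(ValueError):
            MoodModelSpec(source="null", asymmetric=True)
        with pytest.raises(ValueError):
            MoodModelSpec(source="choice_only", reciprocal=True)


class TestInterpolation:
    def test_linear_between_ratings(self):
        r = np.full(6, np.nan)
        r[1], r[4] = 0.0, 3.0  # trials 2 and 5
        out = interpolate_ratings(r)
        assert out[2] == pytest.approx(1.0)
        assert out[3] == pytest.approx(2.0)
        # endpoints held constant
        assert out[0] == pytest.approx(0.0)
        assert out[5] == pytest.approx(3.0)

    def test_flat_input_stays_flat(self):
        r = np.full(9, np.nan)
        r[[1, 4, 7]] = 2.5
        np.testing.assert_allclose(interpolate_ratings(r), 2.5)

    def test_matches_piecewise_linear_oracle(self):
        rng = np.random.default_rng(3)
        r = np.full(40, np.nan)
        idx = np.sort(rng.choice(40, size=12, replace=False))
        r[idx] = rng.normal(size=12)
        out = interpolate_ratings(r)
        from scipy.interpolate import interp1d
        oracle = interp1d(idx.astype(float), r[idx], bounds_error=False,
                          fill_value=(r[idx[0]], r[idx[-1]]))
        np.testing.assert_allclose(out, oracle(np.arange(40.0)), atol=1e-12)
        np.testing.assert_allclose(out[idx], r[idx])

    def test_too_few_ratings_rejected(self):
        r = np.full(5, np.nan)
        r[2] = 1.0
        with pytest.raises(ValueError):
            interpolate_ratings(r)


class TestLikelihood:
    def test_zero_residuals(self):
        fb = [1, -1, 1, 1, -1, 1]
        table = make_table(fb)
        spec = MoodModelSpec(source="quiz_only", simplified=True)
        p = MoodParams(omega_f=0.5, gamma=0.5, obs_sd=1.0)
        tml = compute_tml(table, spec, p).tml
        table["mood_rating"] = tml
        ll = mood_loglik(table, spec, p, zscore=False)
        assert ll == pytest.approx(-len(fb) / 2 * np.log(2 * np.pi))

    def test_no_ratings_gives_zero(self):
        table = make_table([1, -1, 1])
        spec = MoodModelSpec(source="null")
        assert mood_loglik(table, spec, MoodParams()) == 0.0

    def test_matches_density_sum_oracle(self):
        from scipy.stats import norm
        rng = np.random.default_rng(9)
        fb = rng.choice([-1, 1], size=30)
        table = make_table(fb)
        r = np.full(30, np.nan)
        r[::3] = rng.normal(size=10)
        table["mood_rating"] = r
        spec = MoodModelSpec(source="quiz_only", simplified=True)
        p = MoodParams(omega_f=0.4, gamma=0.7, obs_sd=0.8)
        tml = compute_tml(table, spec, p).tml
        ll = mood_loglik(table, spec, p, interpolate=False, zscore=False)
        rated = ~np.isnan(r)
        oracle = norm.logpdf(r[rated], loc=tml[rated], scale=0.8).sum()
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_invalid_obs_sd_rejected(self):
        with pytest.raises(ValueError):
            MoodParams(obs_sd=0.0)


def test_forgetting_decay_weight():
    """With gamma = 0.77, an event four decay steps old keeps ~35% weight."""
    table = make_table([1] + [-1] * 4 + [1] * 4)
    table["accuracy_mean"] = 0.5  # EV = 0
    spec = MoodModelSpec(source="quiz_only", simplified=True)
    p0 = MoodParams(omega_f=1.0, gamma=0.77)
    base = compute_tml(table, spec, p0).tml
    # impulse response: flip the feedback of one trial, watch trial 5
    flipped = table.copy()
    flipped.loc[0, "feedback"] = -1
    d_old = base[4] - compute_tml(flipped, spec, p0).tml[4]
    flipped = table.copy()
    flipped.loc[4, "feedback"] = 1
    d_new = base[4] - compute_tml(flipped, spec, p0).tml[4]
    ratio = abs(d_old) / abs(d_new)
    assert ratio == pytest.approx(0.77**4, abs=1e-12)
    assert 100 * ratio == pytest.approx(35.0, abs=0.5)
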