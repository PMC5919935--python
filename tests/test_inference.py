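"""Inversion and group-level Bayesian model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moodchoice import inference, mood, synthetic
from moodchoice.inference import (ParamSpec, default_param_spec, family_bms,
                                  fit_mood_model, group_bms, group_param_test,
                                  invert_model)
from moodchoice.mood import MoodModelSpec, MoodParams, compute_tml

from conftest import make_table


class TestLaplaceEvidence:
    def test_linear_gaussian_matches_conjugate_closed_form(self):
        """Null mood model with known noise sd is Bayesian linear regression;
        the Laplace evidence must equal the exact marginal likelihood."""
        rng = np.random.default_rng(8)
        n = 40
        sigma = 0.5
        table = make_table(rng.choice([-1, 1], size=n).tolist())
        y = 0.3 - 0.02 * np.arange(1, n + 1) + rng.normal(0, sigma, n)
        table["mood_rating"] = y
        spec = MoodModelSpec(source="null")
        prior_sd = 2.0
        priors = {
            "omega0": ParamSpec("omega0", "identity", 0.0, prior_sd),
            "omega_t": ParamSpec("omega_t", "identity", 0.0, prior_sd),
        }
        fit = fit_mood_model(table, spec, seed=0, priors=priors,
                             fixed={"obs_sd": sigma}, interpolate=False)
        # exact marginal likelihood of y ~ N(X mu0, sigma^2 I + X S0 X')
        y_z, mask = mood.prepare_rating_target(table, interpolate=False)
        X = np.column_stack([np.ones(n), np.arange(1, n + 1)])
        cov = sigma**2 * np.eye(n) + prior_sd**2 * (X @ X.T)
        oracle = stats.multivariate_normal.logpdf(y_z[mask], np.zeros(n), cov)
        assert fit.log_evidence == pytest.approx(oracle, abs=1e-3)

    def test_no_data_returns_prior(self):
        table = make_table([1, -1, 1])  # no ratings at all
        spec = MoodModelSpec(source="null")
        fit = fit_mood_model(table, spec, seed=0)
        assert fit.log_evidence == pytest.approx(0.0, abs=1e-6)
        # posterior collapses to the prior: transformed means are 0
        assert fit.posterior_mean["omega0"] == pytest.approx(0.0, abs=1e-6)
        assert fit.posterior_mean["obs_sd"] == pytest.approx(1.0, abs=1e-4)

    def test_near_noiseless_recovery(self):
        """Weak noise, weak priors: the latent mood trace is recovered."""
        rng = np.random.default_rng(5)
        n = 240
        fb = rng.choice([-1, 1], size=n)
        table = make_table(fb.tolist())
        spec = MoodModelSpec(source="quiz_only", simplified=True)
        truth = MoodParams(omega_f=0.5, gamma=0.75, omega0=0.1,
                           omega_t=-0.005)
        tml = compute_tml(table, spec, truth).tml
        r = np.full(n, np.nan)
        r[1::3] = tml[1::3] + rng.normal(0, 1e-3, size=len(r[1::3]))
        table["mood_rating"] = r
        fit = fit_mood_model(table, spec, seed=1, interpolate=False)
        est = MoodParams(**fit.posterior_mean)
        est_tml = compute_tml(table, spec, est).tml
        y, mask = mood.prepare_rating_target(table, interpolate=False)
        # fitted trace reproduces the (z-scored) observations
        assert np.corrcoef(est_tml[mask], y[mask])[0, 1] > 0.999
        # decay is scale-free and recovered tightly
        assert est.gamma == pytest.approx(0.75, abs=0.02)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        table = make_table(rng.choice([-1, 1], size=60).tolist())
        r = np.full(60, np.nan)
        r[1::3] = rng.normal(size=20)
        table["mood_rating"] = r
        spec = MoodModelSpec(source="quiz_only", simplified=True)
        f1 = fit_mood_model(table, spec, seed=42)
        f2 = fit_mood_model(table, spec, seed=42)
        assert f1.log_evidence == f2.log_evidence
        assert f1.posterior_mean == f2.posterior_mean

    def test_bic_fallback(self):
        rng = np.random.default_rng(3)
        table = make_table(rng.choice([-1, 1], size=60).tolist())
        r = np.full(60, np.nan)
        r[1::3] = rng.normal(size=20)
        table["mood_rating"] = r
        spec = MoodModelSpec(source="null")
        fit = fit_mood_model(table, spec, seed=0, method="bic")
        assert fit.method == "bic"
        assert fit.log_evidence == pytest.approx(
            fit.log_lik - 0.5 * 3 * np.log(60), abs=1e-9)

    def test_evidence_penalizes_complexity(self):
        """On data from the plain feedback-integration model, the richer
        asymmetric+reciprocal variant must not gain evidence on average."""
        gaps = []
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            n = 240
            table = make_table(rng.choice([-1, 1], size=n).tolist())
            spec0 = MoodModelSpec(source="quiz_only", simplified=True)
            truth = MoodParams(omega_f=0.5, gamma=0.7)
            tml = compute_tml(table, spec0, truth).tml
            r = np.full(n, np.nan)
            r[1::3] = tml[1::3] + rng.normal(0, 0.3, size=80)
            table["mood_rating"] = r
            rich = MoodModelSpec(source="quiz_only", simplified=True,
                                 asymmetric=True, reciprocal=True)
            e0 = fit_mood_model(table, spec0, seed=seed,
                                interpolate=False).log_evidence
            e1 = fit_mood_model(table, rich, seed=seed,
                                interpolate=False).log_evidence
            gaps.append(e1 - e0)
        assert np.mean(gaps) < 1.0


class TestGroupBms:
    def test_uniform_evidence_gives_uniform_xp(self):
        lme = np.zeros((10, 5))
        res = group_bms(lme, seed=0)
        np.testing.assert_allclose(res.exceedance_probability, 0.2, atol=0.01)
        np.testing.assert_allclose(res.expected_frequency, 0.2, atol=1e-6)

    def test_xp_sums_to_one(self):
        rng = np.random.default_rng(0)
        lme = rng.normal(size=(8, 6))
        res = group_bms(lme, seed=1, n_samples=100_000)
        assert res.exceedance_probability.sum() == pytest.approx(1.0, abs=1e-3)

    def test_two_model_beta_oracle(self):
        """K=2 with every agent favouring model 0 by 3 nats: xp from the
        Dirichlet MC must match the exact Beta tail probability."""
        n = 10
        lme = np.zeros((n, 2))
        lme[:, 0] = 3.0
        res = group_bms(lme, seed=0, n_samples=200_000)
        a = res.alpha
        exact = 1.0 - stats.beta.cdf(0.5, a[0], a[1])
        assert res.exceedance_probability[0] == pytest.approx(exact, abs=0.005)
        assert res.exceedance_probability[0] > 0.99

    def test_single_agent_equal_evidence(self):
        lme = np.zeros((1, 2))
        res = group_bms(lme, seed=0)
        assert res.exceedance_probability[0] == pytest.approx(0.5, abs=0.01)

    def test_non_finite_evidence_named(self):
        lme = np.zeros((3, 2))
        lme[1, 1] = np.nan
        with pytest.raises(ValueError, match="agent 1, model 1"):
            group_bms(lme)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        lme = rng.normal(size=(5, 4))
        r1 = group_bms(lme, seed=9)
        r2 = group_bms(lme, seed=9)
        np.testing.assert_array_equal(r1.exceedance_probability,
                                      r2.exceedance_probability)


class TestFamilyBms:
    def test_symmetric_families(self):
        lme = np.zeros((8, 4))
        res = family_bms(lme, {"a": [0, 1], "b": [2, 3]}, seed=0)
        np.testing.assert_allclose(res.exceedance_probability, 0.5, atol=0.01)
        np.testing.assert_allclose(res.expected_frequency, 0.5, atol=1e-6)

    def test_overlap_rejected(self):
        lme = np.zeros((2, 3))
        with pytest.raises(ValueError, match="overlap"):
            family_bms(lme, {"a": [0, 1], "b": [1, 2]})

    def test_incomplete_cover_rejected(self):
        lme = np.zeros((2, 3))
        with pytest.raises(ValueError, match="cover"):
            family_bms(lme, {"a": [0], "b": [2]})

    def test_dominant_model_dominates_family(self):
        lme = np.zeros((12, 4))
        lme[:, 0] = 4.0
        model_level = group_bms(lme, seed=0)
        fam = family_bms(lme, {"with0": [0, 1], "without0": [2, 3]}, seed=0)
        assert fam.exceedance_probability[0] > 0.95
        assert fam.exceedance_probability[0] >= \
            model_level.exceedance_probability[0] - 0.01

    def test_uneven_sizes_follow_evidence(self):
        # a member of the larger family dominating the data must carry its
        # family despite the smaller per-member prior mass
        lme = np.zeros((10, 4))
        lme[:, 2] = 4.0
        res = family_bms(lme, {"small": [0], "large": [1, 2, 3]}, seed=0)
        assert res.names == ["small", "large"]
        assert res.exceedance_probability[1] > 0.95


class TestGroupParamTest:
    def test_zero_variance_reported_undefined(self):
        out = group_param_test([0.0, 0.0, 0.0, 0.0])
        assert out["t_defined"] is False
        assert out["wilcoxon_defined"] is False

    def test_constant_signal_with_jitter(self):
        rng = np.random.default_rng(0)
        out = group_param_test(1.0 + 1e-6 * rng.normal(size=8))
        assert out["t"] > 100
        assert out["p_t"] < 1e-6

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0.4, 1.0, size=15)
        out = group_param_test(v)
        t_manual = np.mean(v) / (np.std(v, ddof=1) / np.sqrt(len(v)))
        assert out["t"] == pytest.approx(t_manual, abs=1e-10)
        p_manual = 2 * stats.t.sf(abs(t_manual), len(v) - 1)
        assert out["p_t"] == pytest.approx(p_manual, abs=1e-12)


def test_recovery_study_near_noiseless():
    """With near-noiseless ratings the harness picks the generating model
    and recovers the scale-free decay parameter almost perfectly."""
    from moodchoice.synthetic import (AgentGroundTruth, TaskConfig,
                                      simulate_agent, BEST_CHOICE_SPEC)
    from moodchoice.choice import ChoiceParams

    gen_spec = MoodModelSpec(source="quiz_only", simplified=True)
    specs = [MoodModelSpec(source="null"), gen_spec]
    tables, truths = [], []
    rng = np.random.default_rng(0)
    for a in range(4):
        truth = AgentGroundTruth(
            mood_spec=gen_spec,
            mood_params=MoodParams(omega_f=0.5, omega_t=-0.01,
                                   gamma=float(rng.uniform(0.55, 0.9))),
            choice_spec=BEST_CHOICE_SPEC,
            choice_params=ChoiceParams(k_g=1.0, k_l=1.2, sigma=0.12),
            rating_noise_sd=1e-3, seed=100 + a)
        tables.append(simulate_agent(TaskConfig(n_sessions=2, seed=a), truth))
        truths.append({"gamma": truth.mood_params.gamma})

    def fit_fn(table, spec, seed):
        return inference.fit_mood_model(table, spec, seed=seed,
                                        interpolate=False, n_starts=4)

    rep = inference.recovery_study(tables, truths, specs, fit_fn,
                                   generating_index=1, seed=0)
    assert rep["winner_index"] == 1
    assert rep["parameters"]["gamma"]["correlation"] > 0.95
    assert abs(rep["parameters"]["gamma"]["bias"]) < 0.05


def test_param_spec_transforms():
    assert default_param_spec("sigma").transform == "log"
    assert default_param_spec("gamma").transform == "logit01"
    assert default_param_spec("omega_f").transform == "identity"
    with pytest.raises(ValueError):
        ParamSpec("x", transform="sqrt")
    with pytest.raises(ValueError):
        ParamSpec("x", prior_sd=0.0)


def test_invert_model_flags_saddle_or_converges():
    """The inversion result always reports convergence honestly."""
    specs = [ParamSpec("a", "identity", prior_sd=100.0),
             ParamSpec("b", "identity", prior_sd=100.0)]
    fit = invert_model(lambda v: -((v["a"] - 1) ** 2 + (v["b"] + 2) ** 2),
                       specs, seed=0)
    assert fit.converged
    assert fit.posterior_mean["a"] == pytest.approx(1.0, abs=1e-3)
    assert fit.posterior_mean["b"] == pytest.approx(-2.0, abs=1e-3)
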