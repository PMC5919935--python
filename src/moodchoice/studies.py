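"""Canned validation studies: parameter, model, and modulation recovery.

Each study simulates a cohort under the default ground-truth conditions,
runs the corresponding analysis chain, and returns a plain dict of computed
quantities.  They encode the package's reference validation experiments:

* mood_recovery_study — cohort generated from the feedback-integration mood
  model (positive feedback weight, positive reciprocal influence, negative
  time drift at the population level); fits the full 18-model family and
  checks that group-level BMS concentrates on the generating family and
  that the group sign tests recover the generating signs.
* confidence_null_study — fits the mood family to confidence ratings, which
  by construction carry no feedback signal; the null mood model should win.
* modulation_recovery_study — cohort whose choices are modulated by the
  vmPFC proxy (gain weight) and the aIns proxy (loss weight); runs the
  per-region modulation comparison, NPM construction, residual regressions,
  the mediation contrast, and the restricted-trial effect size.

Model-recovery fits use the rated-trials-only likelihood: the generative
observation model places ratings only on scheduled trials, and fitting the
interpolated series would low-pass the target and bias selection toward
smoother variants.  The interpolated target remains the pipeline default.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import inference, npm as npm_mod
from .choice import ChoiceModelSpec, chosen_option_utility
from .mood import MoodParams, compute_tml, enumerate_mood_models
from .pipeline import _choice_params
from .synthetic import (BEST_CHOICE_SPEC, BEST_MOOD_SPEC, TaskConfig,
                        default_truth_distribution, gen_cohort)

__all__ = [
    "mood_recovery_study",
    "confidence_null_study",
    "modulation_recovery_study",
    "npm_weight_study",
    "npm_family_study",
]


def _mood_family_lme(tables, seed, rating_column="mood_rating", n_starts=8):
    """Log-evidence matrix of the full 18-model mood family.

    Choice-source models use the chosen-option utility from a preliminary
    expected-utility choice fit, as in the pipeline.
    """
    specs = enumerate_mood_models()
    evs = []
    for a, tb in enumerate(tables):
        cfit = inference.fit_choice_model(tb, BEST_CHOICE_SPEC,
                                          seed=seed + 71 + a,
                                          n_starts=n_starts)
        evs.append(chosen_option_utility(
            tb, BEST_CHOICE_SPEC, _choice_params(cfit.posterior_mean)))
    lme = np.empty((len(tables), len(specs)))
    fits = []
    for a, tb in enumerate(tables):
        row = []
        for m, sp in enumerate(specs):
            fit = inference.fit_mood_model(
                tb, sp, seed=seed + 1000 * a + m, interpolate=False,
                rating_column=rating_column,
                ev_choice=evs[a] if sp.uses_choice else None,
                n_starts=n_starts)
            lme[a, m] = fit.log_evidence
            row.append(fit)
        fits.append(row)
    return specs, lme, fits


def mood_recovery_study(n_agents: int = 23, seed: int = 101,
                        task: TaskConfig | None = None,
                        n_starts: int = 8) -> dict:
    """Recover the generating mood model and parameter signs from a cohort.

    The generating-family BMS check groups models by their identifiable
    structure — quiz-feedback source, single (simplified) weight, asymmetric
    coding — because the reciprocal term is absorbed into the effective
    decay within that family and is recovered through its sign, not by
    model selection.
    """
    task = task or TaskConfig()
    dist = default_truth_distribution()
    tables, truths = gen_cohort(task, n_agents, dist, seed=seed)
    specs, lme, fits = _mood_family_lme(tables, seed, n_starts=n_starts)
    names = [s.label() for s in specs]
    gen_idx = specs.index(BEST_MOOD_SPEC)
    bms = inference.group_bms(lme, names=names, seed=seed)
    fam = [i for i, s in enumerate(specs)
           if s.uses_quiz and s.simplified and s.asymmetric]
    other = [i for i in range(len(specs)) if i not in fam]
    fbms = inference.family_bms(lme, {"generating": fam, "other": other},
                                names=names, seed=seed)
    gen_fits = [fits[a][gen_idx] for a in range(n_agents)]
    sign_tests = {}
    for p in ("omega_f", "delta", "omega_t"):
        vals = [f.posterior_mean[p] for f in gen_fits]
        sign_tests[p] = inference.group_param_test(vals)
    est_gamma = np.array([f.posterior_mean["gamma"] for f in gen_fits])
    tru_gamma = np.array([t.mood_params.gamma for t in truths])
    return {
        "names": names,
        "log_evidence": lme,
        "bms": bms,
        "generating_index": gen_idx,
        "family_members": fam,
        "family_xp": float(fbms.exceedance_probability[0]),
        "sign_tests": sign_tests,
        "gamma_mean_estimate": float(est_gamma.mean()),
        "gamma_mean_truth": float(tru_gamma.mean()),
        "gamma_correlation": float(np.corrcoef(tru_gamma, est_gamma)[0, 1]),
        "n_agents": n_agents,
        "n_trials": task.n_trials,
    }


def confidence_null_study(n_agents: int = 10, seed: int = 202,
                          task: TaskConfig | None = None,
                          n_starts: int = 8) -> dict:
    """Fit the mood family to feedback-independent confidence ratings."""
    task = task or TaskConfig()
    dist = default_truth_distribution()
    tables, _ = gen_cohort(task, n_agents, dist, seed=seed)
    specs, lme, _ = _mood_family_lme(tables, seed,
                                     rating_column="confidence_rating",
                                     n_starts=n_starts)
    names = [s.label() for s in specs]
    bms = inference.group_bms(lme, names=names, seed=seed)
    null_idx = names.index("null")
    return {
        "names": names,
        "log_evidence": lme,
        "bms": bms,
        "null_index": null_idx,
        "null_wins": bool(bms.best_index == null_idx),
        "null_xp": float(bms.exceedance_probability[null_idx]),
        "n_agents": n_agents,
    }


def _modulated_truth_distribution() -> dict:
    dist = default_truth_distribution()
    dist["choice_spec"] = replace(BEST_CHOICE_SPEC,
                                  modulations=("gain", "loss"))
    # gain weight rises with vmPFC intrinsic activity; loss weight rises
    # with aIns intrinsic activity (i.e. falls with mood)
    dist["choice"] = dict(dist["choice"], k_mg=(0.3, 0.08),
                          k_ml=(0.3, 0.08))
    dist["modulator_signals"] = {"gain": "vmpfc", "loss": "ains"}
    return dist


def modulation_recovery_study(n_agents: int = 16, seed: int = 303,
                              task: TaskConfig | None = None,
                              n_starts: int = 8) -> dict:
    """Recover region-specific choice modulations and the NPM effect chain."""
    task = task or TaskConfig()
    dist = _modulated_truth_distribution()
    tables, truths = gen_cohort(task, n_agents, dist, seed=seed)
    base = BEST_CHOICE_SPEC
    variants = [base,
                replace(base, modulations=("gain",)),
                replace(base, modulations=("loss",)),
                replace(base, modulations=("gain", "loss"))]
    out: dict = {"n_agents": n_agents, "per_roi": {}}

    glob = [tb["global"].to_numpy(float) for tb in tables]
    for roi in ("vmpfc", "ains"):
        series = [npm_mod.orthogonalize(tb[roi].to_numpy(float), [glob[a]])
                  for a, tb in enumerate(tables)]
        res = npm_mod.fit_modulated_models(tables, base, series,
                                           variants=variants, seed=seed + 17,
                                           n_starts=n_starts)
        entry = {
            "names": res["names"],
            "xp": res["bms"].exceedance_probability.tolist(),
            "best": res["bms"].best_name,
            "best_index": res["bms"].best_index,
        }
        if roi == "ains":
            kml = [res["fits"][a][2].posterior_mean["k_ml"]
                   for a in range(n_agents)]
            entry["k_ml_values"] = kml
            entry["k_ml_test"] = inference.group_param_test(kml)
        out["per_roi"][roi] = entry

    # NPM chain: mood fit -> TML -> ROI weights -> NPM series
    npms, weights = [], []
    for a, tb in enumerate(tables):
        mfit = inference.fit_mood_model(tb, BEST_MOOD_SPEC, seed=seed + 900 + a,
                                        interpolate=False, n_starts=n_starts)
        trace = compute_tml(tb, BEST_MOOD_SPEC,
                            MoodParams(**mfit.posterior_mean))
        w = npm_mod.fit_npm_weights(
            trace.tml, tb["vmpfc"].to_numpy(float),
            tb["ains"].to_numpy(float),
            trial_index=np.arange(1, len(tb) + 1), global_signal=glob[a])
        weights.append(w)
        npms.append(npm_mod.compute_npm(w, tb["vmpfc"].to_numpy(float),
                                        tb["ains"].to_numpy(float)))
    out["beta_vmpfc"] = [w.beta_vmpfc for w in weights]
    out["beta_ains"] = [w.beta_ains for w in weights]

    base_fits = [inference.fit_choice_model(tb, base, seed=seed + 40 + a,
                                            n_starts=n_starts)
                 for a, tb in enumerate(tables)]
    sp_base = [(base, _choice_params(f.posterior_mean)) for f in base_fits]
    out["residual_vs_npm"] = npm_mod.residual_choice_regression(
        tables, sp_base, npms)

    spec_both = replace(base, modulations=("gain", "loss"))
    mixed = [{"gain": npm_mod.orthogonalize(tb["vmpfc"].to_numpy(float),
                                            [glob[a]]),
              "loss": npm_mod.orthogonalize(tb["ains"].to_numpy(float),
                                            [glob[a]])}
             for a, tb in enumerate(tables)]
    mod_fits = [inference.fit_choice_model(tb, spec_both, seed=seed + 60 + a,
                                           npm=mixed[a], n_starts=n_starts)
                for a, tb in enumerate(tables)]
    sp_mod = [(spec_both, _choice_params(f.posterior_mean))
              for f in mod_fits]
    out["residual_vs_npm_modulated"] = npm_mod.residual_choice_regression(
        tables, sp_mod, npms, npms=mixed)
    shrink = (np.abs(out["residual_vs_npm"]["slopes"])
              - np.abs(out["residual_vs_npm_modulated"]["slopes"]))
    out["mediation_shrink"] = shrink.tolist()
    out["mediation_test"] = inference.group_param_test(shrink)

    effects_all, effects_restricted = [], []
    for a, tb in enumerate(tables):
        eff = npm_mod.restricted_trial_effect(tb, base, sp_base[a][1],
                                              npms[a])
        if eff["all_trials"] is not None and eff["restricted"] is not None:
            effects_all.append(eff["all_trials"])
            effects_restricted.append(eff["restricted"])
    out["effect_all_trials"] = float(np.mean(effects_all))
    out["effect_restricted"] = float(np.mean(effects_restricted))
    return out


def npm_weight_study(n_agents: int = 16, seed: int = 404,
                     task: TaskConfig | None = None,
                     n_starts: int = 8) -> dict:
    """Group tests of the four NPM modulation weights.

    Fits the fully modulated variant of the best choice model (gain, loss,
    sigma, and additive modulations all driven by the NPM) on a cohort whose
    choices are generated with region-specific gain/loss modulation, and
    returns the across-agent tests of k_mg, k_ml, k_msigma, k_m0.  These
    weight-level tests are the robust readout of the NPM analysis:
    model-level selection among the 16 variants is fragile on cohorts of
    this size because a sigma modulation can mimic a concordant gain+loss
    modulation through the mean-utility channel with one parameter fewer.
    """
    task = task or TaskConfig()
    dist = _modulated_truth_distribution()
    tables, _ = gen_cohort(task, n_agents, dist, seed=seed)
    glob = [tb["global"].to_numpy(float) for tb in tables]
    full = replace(BEST_CHOICE_SPEC,
                   modulations=("gain", "loss", "sigma", "additive"))
    tests: dict = {}
    vals = {p: [] for p in ("k_mg", "k_ml", "k_msigma", "k_m0")}
    for a, tb in enumerate(tables):
        mfit = inference.fit_mood_model(tb, BEST_MOOD_SPEC,
                                        seed=seed + 900 + a,
                                        interpolate=False, n_starts=n_starts)
        trace = compute_tml(tb, BEST_MOOD_SPEC,
                            MoodParams(**mfit.posterior_mean))
        w = npm_mod.fit_npm_weights(
            trace.tml, tb["vmpfc"].to_numpy(float),
            tb["ains"].to_numpy(float),
            trial_index=np.arange(1, len(tb) + 1), global_signal=glob[a])
        npm = npm_mod.compute_npm(w, tb["vmpfc"].to_numpy(float),
                                  tb["ains"].to_numpy(float))
        cfit = inference.fit_choice_model(tb, full, seed=seed + 50 + a,
                                          npm=npm, n_starts=n_starts)
        for p in vals:
            vals[p].append(cfit.posterior_mean[p])
    for p, v in vals.items():
        tests[p] = inference.group_param_test(v)
    return {"weight_tests": tests, "n_agents": n_agents}


def npm_family_study(n_agents: int = 16, seed: int = 404,
                     task: TaskConfig | None = None,
                     n_starts: int = 8) -> dict:
    """Family-wise BMS over the 16 NPM modulation variants.

    Choices are modulated through the regions' intrinsic activity; fitting
    uses the NPM series, so the gain/loss modulation families should be
    plausible and the sigma/additive families implausible.
    """
    task = task or TaskConfig()
    dist = _modulated_truth_distribution()
    tables, _ = gen_cohort(task, n_agents, dist, seed=seed)
    glob = [tb["global"].to_numpy(float) for tb in tables]
    npms = []
    for a, tb in enumerate(tables):
        mfit = inference.fit_mood_model(tb, BEST_MOOD_SPEC,
                                        seed=seed + 900 + a,
                                        interpolate=False, n_starts=n_starts)
        trace = compute_tml(tb, BEST_MOOD_SPEC,
                            MoodParams(**mfit.posterior_mean))
        w = npm_mod.fit_npm_weights(
            trace.tml, tb["vmpfc"].to_numpy(float),
            tb["ains"].to_numpy(float),
            trial_index=np.arange(1, len(tb) + 1), global_signal=glob[a])
        npms.append(npm_mod.compute_npm(w, tb["vmpfc"].to_numpy(float),
                                        tb["ains"].to_numpy(float)))
    res = npm_mod.fit_modulated_models(tables, BEST_CHOICE_SPEC, npms,
                                       seed=seed, n_starts=n_starts)
    out = {"names": res["names"],
           "xp": res["bms"].exceedance_probability.tolist(),
           "family_xp": {},
           "weight_tests": res["weight_tests"]}
    for dim, fam in res["families"].items():
        on = fam.names.index(f"{dim}_on")
        out["family_xp"][dim] = float(fam.exceedance_probability[on])
    return out
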