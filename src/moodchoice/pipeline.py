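"""End-to-end orchestration: simulate, fit model families, select, analyse.

The pipeline follows the analysis order of the behavioural study it
implements: fit the mood-model family to ratings and select the best model
by random-effects Bayesian model selection; regenerate the theoretical mood
level (TML) for every agent by applying the group-mean posterior parameters
to that agent's own feedback history; fit the choice-model family and select
the best choice model; then run the neural-proxy-for-mood (NPM) analysis —
ROI-to-TML regression, NPM construction, residual-choice regressions,
modulated-model comparison, and the restricted-trial effect size.

Every stage is seeded and the report records the configuration hash, so a
rerun with the same config reproduces the same numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import inference, npm as npm_mod
from ._version import __version__
from .choice import (ChoiceModelSpec, ChoiceParams, chosen_option_utility,
                     enumerate_choice_models, enumerate_npm_models)
from .io import to_jsonable
from .mood import (MoodModelSpec, MoodParams, compute_tml,
                   enumerate_mood_models)
from .synthetic import (BEST_CHOICE_SPEC, TaskConfig, gen_cohort)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("moodchoice.pipeline")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    task: TaskConfig = field(default_factory=TaskConfig)
    n_agents: int = 23
    seed: int = 0
    truth_distribution: dict | None = None
    mood_models: list | None = None  # None -> full 18-member family
    choice_models: list | None = None  # None -> full 132-member family
    npm_variants: list | None = None  # None -> all 16 modulation variants
    interpolate: bool = True
    orth_last_feedback: bool = False
    n_starts: int = inference.N_STARTS
    bms_samples: int = 100_000
    run_mood: bool = True
    run_choice: bool = True
    run_npm: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(to_jsonable(dataclasses.asdict(self)),
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(report: dict, name: str):
    log.info("stage %s", name)
    report["stages_run"].append(name)


def _bms_or_trivial(lme: np.ndarray, names: list[str], n_samples: int,
                    seed: int) -> inference.BMSResult:
    if lme.shape[1] == 1:
        return inference.BMSResult(
            names=names, alpha=np.array([1.0 + lme.shape[0]]),
            expected_frequency=np.array([1.0]),
            exceedance_probability=np.array([1.0]),
            n_samples=0, seed=seed)
    return inference.group_bms(lme, names=names, n_samples=n_samples,
                               seed=seed)


def _group_mean_params(fits: list[inference.InversionResult]) -> dict:
    names = fits[0].param_names
    return {n: float(np.mean([f.posterior_mean[n] for f in fits]))
            for n in names}


def run_pipeline(config: RunConfig, tables=None, truths=None) -> dict:
    """Run the full analysis; returns a self-describing report dict.

    ``tables`` may be supplied to analyse an existing cohort; otherwise a
    synthetic cohort is generated from the config.  Stage failures raise
    with the stage name; the partial report is attached to the exception.
    """
    t0 = time.time()
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_agents": config.n_agents,
        "stages_run": [],
    }
    try:
        _run_stages(config, report, tables, truths)
    except Exception as exc:
        stage = report["stages_run"][-1] if report["stages_run"] else "setup"
        exc.partial_report = report  # type: ignore[attr-defined]
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    report["elapsed_s"] = time.time() - t0
    return report


def _run_stages(config: RunConfig, report: dict, tables, truths) -> None:
    seed = config.seed
    if tables is None:
        _stage(report, "simulate")
        tables, truths = gen_cohort(config.task, config.n_agents,
                                    config.truth_distribution, seed=seed)
        report["simulate"] = {"n_agents": len(tables),
                              "n_trials": int(len(tables[0]))}
    n_agents = len(tables)

    ev_choice_series = [None] * n_agents
    best_mood_spec = None
    tml_series = None

    if config.run_mood:
        _stage(report, "mood_family")
        mood_specs = (config.mood_models if config.mood_models is not None
                      else enumerate_mood_models())
        needs_ev = any(s.uses_choice for s in mood_specs)
        if needs_ev:
            # chosen-option utility from a preliminary expected-utility fit
            prelim = [inference.fit_choice_model(
                tables[a], BEST_CHOICE_SPEC, seed=seed + 71 + a,
                n_starts=config.n_starts) for a in range(n_agents)]
            ev_choice_series = [
                chosen_option_utility(
                    tables[a], BEST_CHOICE_SPEC,
                    _choice_params(prelim[a].posterior_mean))
                for a in range(n_agents)]
        lme = np.empty((n_agents, len(mood_specs)))
        mood_fits = []
        for a in range(n_agents):
            row = []
            for m, spec in enumerate(mood_specs):
                fit = inference.fit_mood_model(
                    tables[a], spec, seed=seed + 1000 * a + m,
                    interpolate=config.interpolate,
                    ev_choice=ev_choice_series[a] if spec.uses_choice else None,
                    n_starts=config.n_starts)
                lme[a, m] = fit.log_evidence
                row.append(fit)
            mood_fits.append(row)
            log.info("mood fits done for agent %d/%d", a + 1, n_agents)
        bms = _bms_or_trivial(lme, [s.label() for s in mood_specs],
                              config.bms_samples, seed)
        best_idx = bms.best_index
        best_mood_spec = mood_specs[best_idx]
        best_fits = [mood_fits[a][best_idx] for a in range(n_agents)]
        report["mood_family"] = {
            "models": [s.label() for s in mood_specs],
            "n_models": len(mood_specs),
            "log_evidence": lme.tolist(),
            "bms": _bms_report(bms),
            "best_model": best_mood_spec.label(),
            "posterior_means": [
                {k: float(v) for k, v in f.posterior_mean.items()}
                for f in best_fits],
        }

        _stage(report, "tml_generation")
        group_params = _group_mean_params(best_fits)
        mp = MoodParams(**group_params)
        tml_series = [
            compute_tml(tables[a], best_mood_spec, mp,
                        ev_choice=(ev_choice_series[a]
                                   if best_mood_spec.uses_choice else None)).tml
            for a in range(n_agents)]
        report["tml_generation"] = {"group_mean_params": group_params}

    best_choice_spec = None
    best_choice_params = None
    if config.run_choice:
        _stage(report, "choice_family")
        choice_specs = (config.choice_models
                        if config.choice_models is not None
                        else enumerate_choice_models())
        lme = np.empty((n_agents, len(choice_specs)))
        choice_fits = []
        for a in range(n_agents):
            row = []
            for m, spec in enumerate(choice_specs):
                fit = inference.fit_choice_model(
                    tables[a], spec, seed=seed + 5000 + 1000 * a + m,
                    n_starts=config.n_starts)
                lme[a, m] = fit.log_evidence
                row.append(fit)
            choice_fits.append(row)
            log.info("choice fits done for agent %d/%d", a + 1, n_agents)
        bms = _bms_or_trivial(lme, [s.label() for s in choice_specs],
                              config.bms_samples, seed + 1)
        best_idx = bms.best_index
        best_choice_spec = choice_specs[best_idx]
        best_choice_fits = [choice_fits[a][best_idx] for a in range(n_agents)]
        best_choice_params = [
            _choice_params(f.posterior_mean) for f in best_choice_fits]
        report["choice_family"] = {
            "models": [s.label() for s in choice_specs],
            "n_models": len(choice_specs),
            "log_evidence": lme.tolist(),
            "bms": _bms_report(bms),
            "best_model": best_choice_spec.label(),
            "posterior_means": [
                {k: (float(v) if not isinstance(v, dict) else v)
                 for k, v in f.posterior_mean.items()}
                for f in best_choice_fits],
        }

    if config.run_npm:
        if best_choice_spec is None or tml_series is None:
            raise ValueError("NPM stage needs the mood and choice stages")
        if "vmpfc" not in tables[0].columns or tables[0]["vmpfc"].isna().all():
            report["npm"] = {"skipped": "no ROI columns in the data"}
            return
        _stage(report, "npm")
        weights, npm_series = [], []
        for a in range(n_agents):
            tb = tables[a]
            lf = np.concatenate(([0.0], tb["feedback"].to_numpy(float)[:-1]))
            w = npm_mod.fit_npm_weights(
                tml_series[a], tb["vmpfc"].to_numpy(float),
                tb["ains"].to_numpy(float),
                trial_index=np.arange(1, len(tb) + 1),
                global_signal=tb["global"].to_numpy(float),
                last_feedback=lf,
                orth_last_feedback=config.orth_last_feedback)
            weights.append(w)
            npm_series.append(npm_mod.compute_npm(
                w, tb["vmpfc"].to_numpy(float), tb["ains"].to_numpy(float)))
        specs_params = [(best_choice_spec, best_choice_params[a])
                        for a in range(n_agents)]
        resid_mood = npm_mod.residual_choice_regression(
            tables, specs_params,
            [npm_mod.interpolated_mood(tables[a]) for a in range(n_agents)])
        resid_npm = npm_mod.residual_choice_regression(
            tables, specs_params, npm_series)
        modulated = npm_mod.fit_modulated_models(
            tables, best_choice_spec, npm_series,
            variants=config.npm_variants, seed=seed + 9000,
            n_starts=config.n_starts, n_samples=config.bms_samples)
        restricted = [npm_mod.restricted_trial_effect(
            tables[a], best_choice_spec, best_choice_params[a],
            npm_series[a]) for a in range(n_agents)]
        report["npm"] = {
            "weights": [w.to_dict() for w in weights],
            "residual_vs_mood": resid_mood,
            "residual_vs_npm": resid_npm,
            "modulation_bms": _bms_report(modulated["bms"]),
            "modulation_families": {
                k: _bms_report(v) for k, v in modulated["families"].items()},
            "weight_tests": modulated["weight_tests"],
            "restricted_effect": restricted,
        }


def _choice_params(vals: dict) -> ChoiceParams:
    weights = {k[2:]: v for k, v in vals.items() if k.startswith("w_")}
    scalars = {k: v for k, v in vals.items() if not k.startswith("w_")}
    return ChoiceParams(weights=weights, **scalars)


def _bms_report(bms: inference.BMSResult) -> dict:
    return {
        "names": bms.names,
        "alpha": bms.alpha.tolist(),
        "expected_frequency": bms.expected_frequency.tolist(),
        "exceedance_probability": bms.exceedance_probability.tolist(),
        "best": bms.best_name,
        "n_samples": bms.n_samples,
        "seed": bms.seed,
    }
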