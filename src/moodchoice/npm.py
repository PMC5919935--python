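"""Neural proxy for mood (NPM): from ROI baselines to choice modulation.

The analysis chain mirrors how trial-level region-of-interest (ROI) baseline
signals are turned into a behavioural modulator: ROI series are
orthogonalized with respect to nuisance signals (whole-brain mean, trial
index, optionally the last feedback), regressed together against the latent
mood level (TML) to obtain weights beta_vmPFC and beta_aIns, combined into

    NPM(t) = beta_vmPFC * baseline_vmPFC(t) + beta_aIns * baseline_aIns(t),

and then (a) regressed against the residual error of the fitted choice model
(actual choice minus acceptance probability) and (b) allowed to modulate the
choice parameters themselves, with Bayesian comparison of the modulation
variants.  A restricted-trial analysis quantifies the mood effect on the
subset of trials whose model-predicted acceptance probability is not pinned
near 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import inference
from .choice import ChoiceModelSpec, ChoiceParams, accept_probability
from .inference import group_param_test

__all__ = [
    "NpmWeights",
    "orthogonalize",
    "fit_npm_weights",
    "compute_npm",
    "interpolated_mood",
    "model_residuals",
    "residual_choice_regression",
    "fit_modulated_models",
    "restricted_trial_effect",
    "nonlinearity_check",
]


@dataclass
class NpmWeights:
    """Fitted ROI-to-mood weights and the recipe that produced them."""

    beta_vmpfc: float
    beta_ains: float
    per_agent: bool = True
    recipe: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"beta_vmpfc": self.beta_vmpfc, "beta_ains": self.beta_ains,
                "per_agent": self.per_agent, "recipe": dict(self.recipe)}

    @classmethod
    def from_dict(cls, d: dict) -> "NpmWeights":
        return cls(**d)


def _design(columns: list, n: int | None = None,
            intercept: bool = True) -> np.ndarray:
    if n is None:
        n = len(np.asarray(columns[0]))
    cols = [np.ones(n)] if intercept else []
    cols += [np.asarray(c, dtype=float) for c in columns]
    return np.column_stack(cols)


def orthogonalize(signal, nuisance: list | None = None) -> np.ndarray:
    """OLS-residualize ``signal`` on the nuisance columns plus an intercept.

    The residual has zero sample correlation with every retained nuisance
    column.  Rank-deficient nuisance sets are handled by least squares
    (redundant directions carry no extra projection); a warning is emitted.
    """
    y = np.asarray(signal, dtype=float)
    nuisance = nuisance or []
    X = _design(list(nuisance), n=len(y))
    if len(nuisance):
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn("rank-deficient nuisance set; redundant columns "
                          "contribute no additional projection")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def fit_npm_weights(
    tml,
    vmpfc,
    ains,
    trial_index=None,
    global_signal=None,
    last_feedback=None,
    orth_last_feedback: bool = False,
) -> NpmWeights:
    """Regress TML on the two orthogonalized ROI baselines.

    Both ROI series are orthogonalized with respect to the whole-brain mean
    signal and the trial index before entering a joint regression explaining
    TML.  With ``orth_last_feedback`` the previous quiz feedback (+1/-1) is
    additionally regressed out of TML and both ROI series, testing that the
    coupling is not an evoked response to the last outcome.
    """
    tml = np.asarray(tml, dtype=float)
    v = np.asarray(vmpfc, dtype=float)
    a = np.asarray(ains, dtype=float)
    nuis = []
    recipe = {"nuisance": [], "orth_last_feedback": bool(orth_last_feedback)}
    if global_signal is not None:
        nuis.append(np.asarray(global_signal, dtype=float))
        recipe["nuisance"].append("global")
    if trial_index is not None:
        nuis.append(np.asarray(trial_index, dtype=float))
        recipe["nuisance"].append("trial")
    v = orthogonalize(v, nuis)
    a = orthogonalize(a, nuis)
    y = tml
    if orth_last_feedback:
        if last_feedback is None:
            raise ValueError("last_feedback series required for this recipe")
        lf = [np.asarray(last_feedback, dtype=float)]
        v = orthogonalize(v, lf)
        a = orthogonalize(a, lf)
        y = orthogonalize(y, lf)
    X = _design([v, a])
    cond = np.linalg.cond(X)
    if cond > 1e6:
        warnings.warn(f"ill-conditioned ROI design (cond={cond:.2g})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return NpmWeights(beta_vmpfc=float(beta[1]), beta_ains=float(beta[2]),
                      recipe=recipe)


def compute_npm(weights: NpmWeights, vmpfc, ains) -> np.ndarray:
    """NPM(t) = beta_vmPFC * vmpfc(t) + beta_aIns * ains(t)."""
    return (weights.beta_vmpfc * np.asarray(vmpfc, dtype=float)
            + weights.beta_ains * np.asarray(ains, dtype=float))


def interpolated_mood(table: pd.DataFrame) -> np.ndarray:
    """Per-trial mood covariate: linearly interpolated sparse ratings."""
    from .mood import interpolate_ratings

    return interpolate_ratings(table["mood_rating"].to_numpy(dtype=float))


def model_residuals(table: pd.DataFrame, spec: ChoiceModelSpec,
                    params: ChoiceParams, npm=None) -> np.ndarray:
    """Residual error of choice: actual choice minus acceptance probability."""
    p = accept_probability(
        spec, params,
        table["gain"].to_numpy(dtype=float),
        table["loss"].to_numpy(dtype=float),
        table["size"].to_numpy(dtype=float),
        np.arange(1, len(table) + 1), npm=npm)
    return table["choice"].to_numpy(dtype=float) - p


def _ols_slope(y: np.ndarray, x: np.ndarray) -> float:
    X = _design([x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


def residual_choice_regression(
    tables: list[pd.DataFrame],
    specs_params: list[tuple[ChoiceModelSpec, ChoiceParams]],
    covariates: list[np.ndarray],
    npms: list | None = None,
) -> dict:
    """Per-agent slope of choice residuals on a covariate, plus group test.

    The covariate is the mood rating or the NPM series.  A constant
    covariate yields an undefined slope, reported as such; the group test
    runs on the defined slopes.
    """
    slopes = []
    for i, table in enumerate(tables):
        spec, params = specs_params[i]
        npm = npms[i] if npms is not None else None
        resid = model_residuals(table, spec, params, npm=npm)
        cov = np.asarray(covariates[i], dtype=float)
        mask = ~np.isnan(cov) & ~np.isnan(resid)
        if mask.sum() < 3 or np.std(cov[mask]) == 0:
            slopes.append(np.nan)
        else:
            slopes.append(_ols_slope(resid[mask], cov[mask]))
    slopes = np.asarray(slopes)
    defined = slopes[~np.isnan(slopes)]
    out = {"slopes": slopes.tolist()}
    out["group"] = (group_param_test(defined) if len(defined) >= 2
                    else {"n": int(len(defined))})
    return out


def fit_modulated_models(
    tables: list[pd.DataFrame],
    base_spec: ChoiceModelSpec,
    modulator_series: list,
    variants: list[ChoiceModelSpec] | None = None,
    seed: int = 0,
    n_starts: int = inference.N_STARTS,
    n_samples: int = 100_000,
) -> dict:
    """Invert modulation variants of the base choice model across agents.

    ``modulator_series`` holds one per-trial proxy series per agent (the NPM,
    or a single ROI baseline).  ``variants`` defaults to the full 16-member
    modulation family of the base model.  Returns per-variant evidences, the
    model-level BMS, per-dimension family BMS (modulation on vs off), and
    group tests on the modulation weights of the full variant set.
    """
    from .choice import MODULATIONS, enumerate_npm_models

    if variants is None:
        variants = enumerate_npm_models(base_spec)
    n_agents = len(tables)
    lme = np.empty((n_agents, len(variants)))
    fits = []
    for a, table in enumerate(tables):
        npm = np.asarray(modulator_series[a], dtype=float)
        row = []
        for m, spec in enumerate(variants):
            fit = inference.fit_choice_model(
                table, spec, seed=seed + 1000 * a + m, npm=npm,
                n_starts=n_starts)
            lme[a, m] = fit.log_evidence
            row.append(fit)
        fits.append(row)
    names = [v.label() for v in variants]
    bms = inference.group_bms(lme, names=names, n_samples=n_samples, seed=seed)

    family_results = {}
    for dim in MODULATIONS:
        on = [i for i, v in enumerate(variants) if dim in v.modulations]
        off = [i for i, v in enumerate(variants) if dim not in v.modulations]
        if on and off:
            family_results[dim] = inference.family_bms(
                lme, {f"{dim}_on": on, f"{dim}_off": off},
                names=names, n_samples=n_samples, seed=seed)

    weight_tests = {}
    mod_param = {"gain": "k_mg", "loss": "k_ml", "sigma": "k_msigma",
                 "additive": "k_m0"}
    full_idx = max(range(len(variants)),
                   key=lambda i: len(variants[i].modulations))
    full_spec = variants[full_idx]
    for dim in full_spec.modulations:
        pname = mod_param[dim]
        vals = [fits[a][full_idx].posterior_mean[pname]
                for a in range(n_agents)]
        if len(vals) >= 2:
            weight_tests[pname] = group_param_test(vals)

    return {"variants": variants, "names": names, "log_evidence": lme,
            "bms": bms, "families": family_results, "fits": fits,
            "weight_tests": weight_tests}


def restricted_trial_effect(
    table: pd.DataFrame,
    spec: ChoiceModelSpec,
    params: ChoiceParams,
    covariate,
    band: tuple[float, float] = (1.0 / 6.0, 5.0 / 6.0),
    n_bins: int = 3,
) -> dict:
    """Acceptance-rate swing across covariate bins, all trials vs a band.

    Trials are binned by covariate quantiles (tertiles by default); the
    effect size is the acceptance-rate difference between the top and bottom
    bins.  The restricted version keeps only trials whose model-predicted
    acceptance probability falls inside ``band`` — trials on which choice is
    not already pinned by the task factors.
    """
    cov = np.asarray(covariate, dtype=float)
    y = table["choice"].to_numpy(dtype=float)
    p = accept_probability(
        spec, params,
        table["gain"].to_numpy(dtype=float),
        table["loss"].to_numpy(dtype=float),
        table["size"].to_numpy(dtype=float),
        np.arange(1, len(table) + 1))

    def bin_diff(mask: np.ndarray):
        c, yy = cov[mask], y[mask]
        ok = ~np.isnan(c) & ~np.isnan(yy)
        c, yy = c[ok], yy[ok]
        if len(c) < n_bins or np.std(c) == 0:
            return None
        edges = np.quantile(c, np.linspace(0, 1, n_bins + 1))
        lo = yy[c <= edges[1]]
        hi = yy[c >= edges[-2]]
        if len(lo) == 0 or len(hi) == 0:
            return None
        return float(np.mean(hi) - np.mean(lo))

    all_trials = bin_diff(np.ones(len(y), dtype=bool))
    in_band = (p >= band[0]) & (p <= band[1])
    restricted = bin_diff(in_band) if in_band.any() else None
    return {"all_trials": all_trials, "restricted": restricted,
            "band": list(band), "n_restricted": int(in_band.sum()),
            "n_bins": n_bins}


def nonlinearity_check(tml, roi, degree: int = 3) -> dict:
    """Polynomial coupling check between mood level and one ROI baseline.

    Regresses the ROI signal on polynomial expansions of TML (orders 1..
    ``degree``) and, separately, compares the linear slopes estimated above
    and below the median TML (a purely linear symmetric coupling predicts
    equal slopes and null higher-order terms).
    """
    x = np.asarray(tml, dtype=float)
    y = np.asarray(roi, dtype=float)
    xc = x - np.mean(x)
    X = _design([xc**d for d in range(1, degree + 1)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    n, k = X.shape
    resid = y - X @ beta
    dof = n - k
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)

    med = np.median(x)
    lo, hi = x <= med, x > med

    def slope_se(mask):
        Xm = _design([x[mask]])
        bm, *_ = np.linalg.lstsq(Xm, y[mask], rcond=None)
        rm = y[mask] - Xm @ bm
        dfm = mask.sum() - 2
        s2m = float(rm @ rm) / max(dfm, 1)
        covm = s2m * np.linalg.inv(Xm.T @ Xm)
        return float(bm[1]), float(np.sqrt(covm[1, 1])), dfm

    b_lo, se_lo, df_lo = slope_se(lo)
    b_hi, se_hi, df_hi = slope_se(hi)
    z = (b_hi - b_lo) / np.hypot(se_lo, se_hi)
    p_diff = 2 * stats.norm.sf(abs(z))
    return {
        "coefficients": {f"order_{d}": float(beta[d])
                         for d in range(1, degree + 1)},
        "t_values": {f"order_{d}": float(tvals[d])
                     for d in range(1, degree + 1)},
        "p_values": {f"order_{d}": float(pvals[d])
                     for d in range(1, degree + 1)},
        "slope_below_median": b_lo,
        "slope_above_median": b_hi,
        "slope_difference": float(b_hi - b_lo),
        "slope_difference_p": float(p_diff),
    }
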