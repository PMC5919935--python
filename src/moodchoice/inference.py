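"""Approximate-Bayesian model inversion and random-effects model selection.

Single-agent fits use maximum a posteriori estimation with a Laplace
approximation to the model evidence,

    log p(y) ~= log p(y | theta_hat) + log p(theta_hat)
                + (d/2) log(2*pi) - (1/2) log |H|,

where H is the negative Hessian of the log joint at the mode.  Parameters
are optimised on an unconstrained transformed scale (log for positives,
scaled logit for unit-interval parameters) with independent Gaussian priors;
a multi-start quasi-Newton search guards against local optima.  This is the
usual trade-off between accuracy and complexity: the determinant term
penalises parameters the data constrain.  A BIC evidence is available as a
cruder fallback.

Group-level model selection treats the model identity as a random effect
across agents: a Dirichlet posterior over model frequencies is obtained by
the standard variational update, and exceedance probabilities (probability
that a model is the most frequent in the population) are estimated by Monte
Carlo sampling of the Dirichlet.  Family-level comparisons aggregate member
frequencies under an even prior across families.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma

from . import choice as choice_mod
from . import mood as mood_mod

__all__ = [
    "ParamSpec",
    "default_param_spec",
    "InversionResult",
    "BMSResult",
    "invert_model",
    "fit_mood_model",
    "fit_choice_model",
    "group_bms",
    "family_bms",
    "group_param_test",
    "recovery_study",
]

# transforms between the natural and unconstrained scales
_LOG_PARAMS = {"sigma", "R", "obs_sd"}
_LOGIT_PARAMS = {"gamma", "c_g", "c_l"}

DEFAULT_PRIOR_SD = 3.0
HESSIAN_STEP = 1e-4
N_STARTS = 8


def _to_natural(x: float, transform: str) -> float:
    if transform == "log":
        return math.exp(x)
    if transform == "logit01":
        return 1.0 / (1.0 + math.exp(-x))
    return x


def _default_transform(name: str) -> str:
    if name in _LOG_PARAMS:
        return "log"
    if name in _LOGIT_PARAMS:
        return "logit01"
    return "identity"


@dataclass
class ParamSpec:
    """One parameter of an inversion problem.

    ``prior_mean``/``prior_sd`` live on the transformed (unconstrained)
    scale.  A ``fixed`` value (natural scale) removes the parameter from the
    optimisation.
    """

    name: str
    transform: str = "identity"
    prior_mean: float = 0.0
    prior_sd: float = DEFAULT_PRIOR_SD
    fixed: float | None = None

    def __post_init__(self):
        if self.transform not in ("identity", "log", "logit01"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.prior_sd <= 0:
            raise ValueError("prior sd must be positive")


def default_param_spec(name: str, **overrides) -> ParamSpec:
    return ParamSpec(name=name, transform=_default_transform(name), **overrides)


@dataclass
class InversionResult:
    """Posterior summary for one agent x model fit."""

    param_names: list[str]
    posterior_mean: dict[str, float]  # natural scale, fixed params included
    x_map: np.ndarray  # transformed scale, free params only
    posterior_cov: np.ndarray  # transformed scale, free params only
    log_evidence: float
    log_joint: float
    log_lik: float
    converged: bool
    n_starts: int
    n_iter: int
    grad_norm: float
    method: str = "laplace"


@dataclass
class BMSResult:
    """Random-effects Bayesian model selection summary."""

    names: list[str]
    alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    n_samples: int
    seed: int
    families: dict | None = None

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.exceedance_probability))

    @property
    def best_name(self) -> str:
        return self.names[self.best_index]


def invert_model(
    loglik,
    param_specs: list[ParamSpec],
    seed: int = 0,
    n_starts: int = N_STARTS,
    max_restarts: int = 2,
    method: str = "laplace",
    n_obs: int | None = None,
) -> InversionResult:
    """MAP fit with Laplace (or BIC) model evidence.

    ``loglik`` maps a dict of natural-scale parameter values to a scalar
    log-likelihood.  Optimisation runs on the transformed scale with
    independent Gaussian priors, from ``n_starts`` prior-drawn starting
    points (the first start is the prior mean); the best log-joint wins,
    ties broken by the smaller parameter norm.  Non-convergence after
    restarts is flagged on the result, never silent.
    """
    free = [p for p in param_specs if p.fixed is None]
    fixed_vals = {p.name: float(p.fixed) for p in param_specs if p.fixed is not None}
    names = [p.name for p in free]
    d = len(free)
    rng = np.random.default_rng(seed)

    def natural(x: np.ndarray) -> dict[str, float]:
        vals = dict(fixed_vals)
        for p, xi in zip(free, x):
            vals[p.name] = _to_natural(float(xi), p.transform)
        return vals

    mu = np.array([p.prior_mean for p in free])
    sd = np.array([p.prior_sd for p in free])

    def neg_log_joint(x: np.ndarray) -> float:
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                ll = loglik(natural(x))
        except (OverflowError, FloatingPointError, ZeroDivisionError,
                ValueError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        lp = -0.5 * np.sum(((x - mu) / sd) ** 2) - np.sum(np.log(sd)) \
            - 0.5 * d * math.log(2 * math.pi)
        return -(ll + lp)

    if d == 0:
        ll = float(loglik(dict(fixed_vals)))
        return InversionResult(
            param_names=[], posterior_mean=dict(fixed_vals),
            x_map=np.zeros(0), posterior_cov=np.zeros((0, 0)),
            log_evidence=ll, log_joint=ll, log_lik=ll, converged=True,
            n_starts=0, n_iter=0, grad_norm=0.0, method=method)

    # two-stage multi-start: a short exploratory run from every start, then
    # a full polish of the most promising endpoints
    candidates: list[tuple] = []
    total_starts = 0
    for attempt in range(max_restarts + 1):
        starts = [mu.copy()] if attempt == 0 else []
        while len(starts) < n_starts:
            starts.append(mu + sd * rng.standard_normal(d))
        probes = []
        with warnings.catch_warnings():
            # cliff values (1e12) used for invalid regions trip benign
            # overflow warnings inside the finite-difference gradient
            warnings.simplefilter("ignore", RuntimeWarning)
            for x0 in starts:
                total_starts += 1
                res = optimize.minimize(
                    neg_log_joint, x0, method="L-BFGS-B",
                    options={"maxiter": 40, "ftol": 1e-10})
                if np.isfinite(res.fun):
                    probes.append((float(res.fun), res.x))
            probes.sort(key=lambda p: p[0])
            for _, xp in probes[:3]:
                res = optimize.minimize(
                    neg_log_joint, xp, method="L-BFGS-B",
                    options={"maxiter": 500, "ftol": 1e-10})
                if not np.isfinite(res.fun):
                    continue
                candidates.append((float(res.fun),
                                   float(np.linalg.norm(res.x)), res))
        if candidates and min(candidates, key=lambda c: c[:2])[2].success:
            break
    best = sorted(candidates, key=lambda c: c[:2])
    if not best:
        raise RuntimeError("model inversion failed from every start")
    if method == "bic":
        res = best[0][2]
        x_map = res.x
        post = natural(x_map)
        ll_map = float(loglik(post))
        if n_obs is None:
            raise ValueError("BIC evidence requires n_obs")
        log_evidence = ll_map - 0.5 * d * math.log(n_obs)
        cov = np.full((d, d), np.nan)
        log_joint = -float(res.fun)
        converged = bool(res.success)
    else:
        # a quasi-Newton run can stop on a saddle; prefer the best candidate
        # whose curvature is actually positive definite
        chosen = None
        for fun, _norm, res in best[:4]:
            H = _fd_hessian(neg_log_joint, res.x)
            H = 0.5 * (H + H.T)
            eigval, eigvec = np.linalg.eigh(H)
            if eigval[0] > -1e-6 * max(1.0, eigval[-1]):
                chosen = (res, eigval, eigvec, True)
                break
            if chosen is None:
                chosen = (res, eigval, eigvec, False)
        res, eigval, eigvec, curvature_ok = chosen
        x_map = res.x
        post = natural(x_map)
        ll_map = float(loglik(post))
        log_joint = -float(res.fun)
        converged = bool(res.success) and curvature_ok
        floor = max(1e-8, 1e-8 * abs(eigval[-1]))
        clamped = np.maximum(eigval, floor)
        logdet = float(np.sum(np.log(clamped)))
        cov = (eigvec / clamped) @ eigvec.T
        log_evidence = log_joint + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdet
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan

    return InversionResult(
        param_names=names, posterior_mean=post, x_map=x_map,
        posterior_cov=cov, log_evidence=float(log_evidence),
        log_joint=log_joint, log_lik=ll_map, converged=converged,
        n_starts=total_starts, n_iter=int(res.nit), grad_norm=grad_norm,
        method=method)


def _fd_hessian(f, x: np.ndarray, step: float = HESSIAN_STEP) -> np.ndarray:
    """Central finite-difference Hessian."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def _mood_loglik_factory(table, spec, interpolate, ev_choice, rating_column):
    y, mask = mood_mod.prepare_rating_target(
        table, interpolate=interpolate, rating_column=rating_column)
    n = len(table)
    ev_q = pos_fb = ev_c = None
    if spec.uses_quiz:
        ev_q = 2.0 * table["accuracy_mean"].to_numpy(dtype=float) - 1.0
        pos_fb = table["feedback"].to_numpy(dtype=float) > 0
    if spec.uses_choice:
        if ev_choice is None:
            raise ValueError("ev_choice series required for this mood model")
        ev_c = np.asarray(ev_choice, dtype=float)
    y_obs = y[mask]

    def loglik(vals: dict) -> float:
        params = mood_mod.MoodParams(**vals)
        tml = mood_mod._tml_arrays(spec, params, n, ev_q, pos_fb, ev_c)[0]
        return mood_mod.gaussian_loglik(y_obs - tml[mask], params.obs_sd)

    return loglik


def fit_mood_model(
    table: pd.DataFrame,
    spec: mood_mod.MoodModelSpec,
    seed: int = 0,
    interpolate: bool = True,
    rating_column: str = "mood_rating",
    ev_choice: np.ndarray | None = None,
    priors: dict[str, ParamSpec] | None = None,
    fixed: dict[str, float] | None = None,
    n_starts: int = N_STARTS,
    method: str = "laplace",
) -> InversionResult:
    """Invert one mood model on one agent's rating data."""
    names = spec.free_param_names()
    specs = _build_param_specs(names, priors, fixed)
    loglik = _mood_loglik_factory(table, spec, interpolate, ev_choice,
                                  rating_column)
    return invert_model(loglik, specs, seed=seed, n_starts=n_starts,
                        method=method, n_obs=len(table))


def fit_choice_model(
    table: pd.DataFrame,
    spec: choice_mod.ChoiceModelSpec,
    seed: int = 0,
    npm=None,
    priors: dict[str, ParamSpec] | None = None,
    fixed: dict[str, float] | None = None,
    n_starts: int = N_STARTS,
    method: str = "laplace",
) -> InversionResult:
    """Invert one choice model on one agent's accept/decline data."""
    names = spec.free_param_names()
    specs = _build_param_specs(names, priors, fixed)
    y = table["choice"].to_numpy(dtype=float)
    mask = ~np.isnan(y)
    g = table["gain"].to_numpy(dtype=float)
    l = table["loss"].to_numpy(dtype=float)
    s = table["size"].to_numpy(dtype=float)
    t = np.arange(1, len(table) + 1, dtype=float)
    y_obs = y[mask]
    eps = choice_mod.PROB_EPS

    def loglik(vals: dict) -> float:
        params = _choice_params_from_dict(vals, spec)
        p = choice_mod.accept_probability(spec, params, g, l, s, t, npm=npm)
        p = np.clip(p[mask], eps, 1.0 - eps)
        return float(np.sum(y_obs * np.log(p)
                            + (1.0 - y_obs) * np.log(1.0 - p)))

    return invert_model(loglik, specs, seed=seed, n_starts=n_starts,
                        method=method, n_obs=int(mask.sum()))


def _choice_params_from_dict(vals: dict, spec) -> choice_mod.ChoiceParams:
    weights = {k[2:]: v for k, v in vals.items() if k.startswith("w_")}
    scalar = {k: v for k, v in vals.items() if not k.startswith("w_")}
    return choice_mod.ChoiceParams(weights=weights, **scalar)


def _build_param_specs(names, priors, fixed) -> list[ParamSpec]:
    priors = priors or {}
    fixed = fixed or {}
    specs = []
    for n in names:
        if n in priors:
            ps = priors[n]
        else:
            ps = default_param_spec(n)
        if n in fixed:
            ps = ParamSpec(ps.name, ps.transform, ps.prior_mean, ps.prior_sd,
                           fixed=fixed[n])
        specs.append(ps)
    return specs


def group_bms(
    log_evidence,
    names: list[str] | None = None,
    alpha0=None,
    n_samples: int = 100_000,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> BMSResult:
    """Random-effects BMS over a [agents x models] log-evidence matrix.

    The Dirichlet posterior over model frequencies follows the standard
    variational update; exceedance probabilities are Monte-Carlo estimates
    over ``n_samples`` Dirichlet draws with a fixed seed.
    """
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2:
        raise ValueError("log_evidence must be [agents x models]")
    n, k = lme.shape
    if k < 2:
        raise ValueError("need at least two models")
    bad = np.argwhere(~np.isfinite(lme))
    if len(bad):
        a, m = bad[0]
        raise ValueError(f"non-finite log evidence for agent {a}, model {m}")
    if names is None:
        names = [f"model_{i}" for i in range(k)]
    alpha0 = np.full(k, 1.0) if alpha0 is None else np.asarray(alpha0, float)

    alpha = alpha0.copy()
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        log_u -= log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha

    ef = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(alpha, size=n_samples)
    xp = np.bincount(np.argmax(r, axis=1), minlength=k) / n_samples
    return BMSResult(names=list(names), alpha=alpha, expected_frequency=ef,
                     exceedance_probability=xp, n_samples=n_samples, seed=seed)


def family_bms(
    log_evidence,
    partition: dict[str, list[int]],
    names: list[str] | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
) -> BMSResult:
    """Family-level BMS over a partition of the model space.

    Families must be disjoint and cover all models.  Each family receives
    equal prior mass (member prior counts 1/|family|); family frequencies
    are sums of member frequencies, and family exceedance probabilities are
    computed from the same Dirichlet draws.
    """
    lme = np.asarray(log_evidence, dtype=float)
    k = lme.shape[1]
    seen: set[int] = set()
    for fam, members in partition.items():
        ms = set(members)
        if ms & seen:
            raise ValueError(f"family {fam!r} overlaps another family")
        seen |= ms
    if seen != set(range(k)):
        raise ValueError("partition must cover every model exactly once")

    alpha0 = np.empty(k)
    for members in partition.values():
        alpha0[list(members)] = 1.0 / len(members)
    model_level = group_bms(lme, names=names, alpha0=alpha0,
                            n_samples=n_samples, seed=seed)

    fam_names = list(partition)
    fam_alpha = np.array([model_level.alpha[list(partition[f])].sum()
                          for f in fam_names])
    fam_ef = fam_alpha / fam_alpha.sum()
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(model_level.alpha, size=n_samples)
    fam_r = np.stack([r[:, list(partition[f])].sum(axis=1) for f in fam_names],
                     axis=1)
    fam_xp = np.bincount(np.argmax(fam_r, axis=1),
                         minlength=len(fam_names)) / n_samples
    return BMSResult(
        names=fam_names, alpha=fam_alpha, expected_frequency=fam_ef,
        exceedance_probability=fam_xp, n_samples=n_samples, seed=seed,
        families={"partition": {f: list(m) for f, m in partition.items()},
                  "model_level": model_level})


def group_param_test(values) -> dict:
    """One-sample two-tailed t-test and Wilcoxon signed-rank across agents.

    Zero-variance input makes t undefined; this is reported, not raised.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two agents")
    out: dict = {"n": int(len(v)), "mean": float(np.mean(v))}
    if np.std(v, ddof=1) == 0:
        out.update(t=None, p_t=None, t_defined=False)
    else:
        t, p = stats.ttest_1samp(v, 0.0)
        out.update(t=float(t), p_t=float(p), t_defined=True)
    nz = v[v != 0]
    if len(nz) == 0:
        out.update(wilcoxon_stat=None, p_wilcoxon=None,
                   wilcoxon_defined=False)
    else:
        try:
            w, pw = stats.wilcoxon(v)
            out.update(wilcoxon_stat=float(w), p_wilcoxon=float(pw),
                       wilcoxon_defined=True)
        except ValueError:
            out.update(wilcoxon_stat=None, p_wilcoxon=None,
                       wilcoxon_defined=False)
    return out


def recovery_study(
    tables: list[pd.DataFrame],
    truths: list[dict],
    specs: list,
    fit_fn,
    generating_index: int,
    seed: int = 0,
    n_samples: int = 100_000,
) -> dict:
    """Parameter- and model-recovery report over a simulated cohort.

    ``fit_fn(table, spec, seed)`` must return an :class:`InversionResult`.
    Returns the evidence matrix, a model-level BMS, and truth-vs-estimate
    correlations/bias for each free parameter of the generating model.
    """
    if not 0 <= generating_index < len(specs):
        raise ValueError("generating model must be part of the model set")
    n_agents = len(tables)
    lme = np.empty((n_agents, len(specs)))
    fits: list[list[InversionResult]] = []
    for a, table in enumerate(tables):
        row = []
        for m, spec in enumerate(specs):
            fit = fit_fn(table, spec, seed + 1000 * a + m)
            lme[a, m] = fit.log_evidence
            row.append(fit)
        fits.append(row)
    bms = group_bms(lme, names=[getattr(s, "label", lambda: str(s))()
                                for s in specs],
                    n_samples=n_samples, seed=seed)
    gen_fits = [fits[a][generating_index] for a in range(n_agents)]
    param_report = {}
    for name in gen_fits[0].param_names:
        est = np.array([f.posterior_mean[name] for f in gen_fits])
        tru = np.array([t.get(name, np.nan) for t in truths], dtype=float)
        known = ~np.isnan(tru)
        entry = {"estimates": est.tolist(), "truth": tru.tolist(),
                 "bias": (float(np.mean(est[known] - tru[known]))
                          if known.any() else None)}
        if known.sum() >= 2 and np.std(tru[known]) > 0 \
                and np.std(est[known]) > 0:
            entry["correlation"] = float(
                np.corrcoef(tru[known], est[known])[0, 1])
        else:
            entry["correlation"] = None
        param_report[name] = entry
    return {
        "log_evidence": lme,
        "bms": bms,
        "winner_index": bms.best_index,
        "generating_index": generating_index,
        "fits": fits,
        "parameters": param_report,
    }
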