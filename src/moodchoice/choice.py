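"""Choice models: expected utility of a risky motor challenge, softmax choice.

An agent decides whether to accept a motor-precision challenge.  The prospect
has three dimensions: potential gain G, potential loss L (both in euros), and
target size S (window width, fraction of maximal force).  Subjective success
probability follows from a Gaussian model of force production centred on the
target with free width sigma:

    p_s = Phi((S/2)/sigma) - Phi(-(S/2)/sigma)

The normative family values acceptance as

    U(accept) = p_s * k_g * G^c_g - (1 - p_s) * k_l * L^c_l

optionally compared to U(decline) with gains and losses replaced by the fixed
0.5 EUR consolation stake; choice probability is a softmax of the utility
difference plus a time drift k_t*t and a constant bias k_0.  Descriptive
models replace the utility by a linear combination of any subset of
{G, L, S, GL, GS, LS, GLS}.  Enumerating 4 pseudo-normative + 2^7 descriptive
structures gives the 132-model space.

Neural-proxy-for-mood (NPM) variants let a per-trial scalar proxy modulate
parameters multiplicatively, k_g'(t) = k_g*(1 + k_mg*NPM(t)) (same for k_l
and sigma), and/or bias utility additively, U' = U + k_m0*NPM(t); the four
on/off switches give 16 modulated variants of any base model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "REGRESSORS",
    "MODULATIONS",
    "ChoiceModelSpec",
    "ChoiceParams",
    "prob_success",
    "utility_accept",
    "utility_decline",
    "descriptive_utility",
    "modulate_params",
    "accept_probability",
    "chosen_option_utility",
    "enumerate_choice_models",
    "enumerate_npm_models",
    "choice_loglik",
]

REGRESSORS = ("G", "L", "S", "GL", "GS", "LS", "GLS")
MODULATIONS = ("gain", "loss", "sigma", "additive")

DECLINE_STAKE = 0.5  # euros at stake when the challenge is declined
SIGMA_FLOOR = 1e-6  # lower clamp on the modulated sigma'
PROB_EPS = 1e-9  # clip for Bernoulli log-likelihood


@dataclass(frozen=True)
class ChoiceModelSpec:
    """Structure of one choice model.

    family: "normative" (expected utility) or "descriptive" (regression).
    include_decline_utility: normative only — subtract U(decline) computed at
        the 0.5 EUR stake instead of absorbing it into the bias k_0.
    curvature: normative only — power parameters c_g, c_l on gain and loss.
    regressors: descriptive only — subset of {G, L, S, GL, GS, LS, GLS}.
    modulations: subset of {gain, loss, sigma, additive} driven by the NPM.
    """

    family: str = "normative"
    include_decline_utility: bool = False
    curvature: bool = False
    regressors: tuple[str, ...] = ()
    modulations: tuple[str, ...] = ()

    def __post_init__(self):
        if self.family not in ("normative", "descriptive"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "normative" and self.regressors:
            raise ValueError("regressors are for the descriptive family only")
        if self.family == "descriptive" and (
            self.include_decline_utility or self.curvature
        ):
            raise ValueError(
                "decline utility / curvature are normative-family options"
            )
        bad = set(self.regressors) - set(REGRESSORS)
        if bad:
            raise ValueError(f"unknown regressors {sorted(bad)}")
        bad = set(self.modulations) - set(MODULATIONS)
        if bad:
            raise ValueError(f"unknown modulations {sorted(bad)}")
        object.__setattr__(self, "regressors", tuple(self.regressors))
        object.__setattr__(self, "modulations", tuple(self.modulations))

    def free_param_names(self) -> list[str]:
        names: list[str] = []
        if self.family == "normative":
            names += ["k_g", "k_l", "sigma"]
            if self.curvature:
                names += ["c_g", "c_l"]
        else:
            names += [f"w_{r}" for r in self.regressors]
        names += ["k_t", "k0"]
        mod_map = {"gain": "k_mg", "loss": "k_ml", "sigma": "k_msigma",
                   "additive": "k_m0"}
        names += [mod_map[m] for m in self.modulations]
        return names

    def label(self) -> str:
        if self.family == "descriptive":
            base = "desc[" + ",".join(self.regressors) + "]"
        else:
            base = "norm"
            if self.include_decline_utility:
                base += "+decl"
            if self.curvature:
                base += "+curv"
        if self.modulations:
            base += "|mod[" + ",".join(self.modulations) + "]"
        return base


@dataclass
class ChoiceParams:
    """Parameters of a choice model (superset; each spec uses a subset).

    k_g, k_l: weights on gain and loss.  sigma: subjective motor sd
    (fraction of maximal force).  k_t: linear drift with trial index.
    k0: constant bias.  c_g, c_l: curvatures in [0, 1].  weights: descriptive
    regressor weights keyed by regressor name.  k_mg, k_ml, k_msigma, k_m0:
    NPM modulation weights.
    """

    k_g: float = 1.0
    k_l: float = 1.0
    sigma: float = 0.1
    k_t: float = 0.0
    k0: float = 0.0
    c_g: float = 1.0
    c_l: float = 1.0
    weights: dict[str, float] = field(default_factory=dict)
    k_mg: float = 0.0
    k_ml: float = 0.0
    k_msigma: float = 0.0
    k_m0: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.c_g <= 1.0 and 0.0 <= self.c_l <= 1.0):
            raise ValueError("curvatures must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "weights"}
        d["weights"] = dict(self.weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChoiceParams":
        return cls(**d)


def prob_success(sigma, size):
    """Probability of landing the force peak inside the target window.

    The subjective force distribution is Gaussian around the target centre
    with sd ``sigma``; the window spans +/- size/2, so
    p_s = Phi((size/2)/sigma) - Phi(-(size/2)/sigma).
    Strictly increasing in size, strictly decreasing in sigma.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    z = np.asarray(size, dtype=float) / (2.0 * sigma)
    return norm.cdf(z) - norm.cdf(-z)


def utility_accept(params: ChoiceParams, gain, loss, p_s,
                   spec: ChoiceModelSpec, k_g=None, k_l=None):
    """Expected utility of accepting: p_s*k_g*G^c_g - (1-p_s)*k_l*L^c_l.

    ``k_g``/``k_l`` override the base weights (used for NPM-modulated,
    per-trial effective weights).  Curvatures apply only when the spec
    enables them.
    """
    kg = params.k_g if k_g is None else k_g
    kl = params.k_l if k_l is None else k_l
    g = np.asarray(gain, dtype=float)
    l = np.asarray(loss, dtype=float)
    if spec.curvature:
        g = g**params.c_g
        l = l**params.c_l
    p_s = np.asarray(p_s, dtype=float)
    return p_s * kg * g - (1.0 - p_s) * kl * l


def utility_decline(params: ChoiceParams, p_s, spec: ChoiceModelSpec,
                    k_g=None, k_l=None):
    """Utility of declining: the accept form at the fixed 0.5 EUR stakes.

    Returns 0 when the spec omits the decline utility (it is then absorbed
    into the constant bias k0).
    """
    if not spec.include_decline_utility:
        return np.zeros_like(np.asarray(p_s, dtype=float))
    return utility_accept(params, DECLINE_STAKE, DECLINE_STAKE, p_s, spec,
                          k_g=k_g, k_l=k_l)


def descriptive_utility(params: ChoiceParams, gain, loss, size,
                        spec: ChoiceModelSpec):
    """Linear-regression utility over the included prospect terms."""
    if spec.family != "descriptive":
        raise ValueError("descriptive_utility requires a descriptive spec")
    extra = set(params.weights) - set(spec.regressors)
    if extra:
        raise ValueError(f"weights given for excluded regressors {sorted(extra)}")
    g = np.asarray(gain, dtype=float)
    l = np.asarray(loss, dtype=float)
    s = np.asarray(size, dtype=float)
    terms = {"G": g, "L": l, "S": s, "GL": g * l, "GS": g * s, "LS": l * s,
             "GLS": g * l * s}
    u = np.zeros(np.broadcast(g, l, s).shape)
    for r in spec.regressors:
        u = u + params.weights.get(r, 0.0) * terms[r]
    return u


def modulate_params(params: ChoiceParams, npm, spec: ChoiceModelSpec):
    """Per-trial effective (k_g', k_l', sigma', additive term) under the NPM.

    Each active modulation scales its parameter by (1 + k_m * NPM(t)); the
    additive modulation contributes k_m0 * NPM(t) to the utility.  ``npm``
    may be a scalar, an array (one proxy for every active modulation), or a
    mapping from modulation name to its own series — the latter supports
    single-region variants where e.g. only k_g is driven by one region's
    baseline.  sigma' is clamped to a small positive floor.
    """
    def series(name):
        if isinstance(npm, dict):
            if name not in npm:
                raise ValueError(f"no proxy series supplied for modulation {name!r}")
            return np.asarray(npm[name], dtype=float)
        if npm is None:
            raise ValueError("npm series required when modulations are active")
        return np.asarray(npm, dtype=float)

    k_g = params.k_g
    k_l = params.k_l
    sigma = params.sigma
    additive = 0.0
    if "gain" in spec.modulations:
        k_g = params.k_g * (1.0 + params.k_mg * series("gain"))
    if "loss" in spec.modulations:
        k_l = params.k_l * (1.0 + params.k_ml * series("loss"))
    if "sigma" in spec.modulations:
        sigma = np.maximum(params.sigma * (1.0 + params.k_msigma * series("sigma")),
                           SIGMA_FLOOR)
    if "additive" in spec.modulations:
        additive = params.k_m0 * series("additive")
    return k_g, k_l, sigma, additive


def accept_probability(spec: ChoiceModelSpec, params: ChoiceParams,
                       gain, loss, size, t, npm=None):
    """Softmax acceptance probability for one or many prospects.

    p(accept) = 1 / (1 + exp(-(U_accept - U_decline + k_t*t + k0))), with
    NPM-modulated effective parameters when the spec requests them.
    Output is strictly inside (0, 1).
    """
    t = np.asarray(t, dtype=float)
    if spec.modulations and npm is None:
        raise ValueError("npm series required for a modulated spec")
    if spec.family == "descriptive":
        u = descriptive_utility(params, gain, loss, size, spec)
        if spec.modulations:
            k_g, k_l, sigma, additive = modulate_params(params, npm, spec)
            u = u + additive
    else:
        if spec.modulations:
            k_g, k_l, sigma, additive = modulate_params(params, npm, spec)
        else:
            k_g, k_l, sigma, additive = params.k_g, params.k_l, params.sigma, 0.0
        p_s = prob_success(sigma, size)
        u = (utility_accept(params, gain, loss, p_s, spec, k_g=k_g, k_l=k_l)
             - utility_decline(params, p_s, spec, k_g=k_g, k_l=k_l)
             + additive)
    x = u + params.k_t * t + params.k0
    # numerically stable logistic
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                   np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return out


def enumerate_choice_models() -> list[ChoiceModelSpec]:
    """The 132-model space: 4 pseudo-normative + 2^7 descriptive."""
    specs = [
        ChoiceModelSpec(family="normative", include_decline_utility=d,
                        curvature=c)
        for d, c in itertools.product((False, True), repeat=2)
    ]
    for r in range(len(REGRESSORS) + 1):
        for subset in itertools.combinations(REGRESSORS, r):
            specs.append(ChoiceModelSpec(family="descriptive",
                                         regressors=subset))
    return specs


def enumerate_npm_models(base: ChoiceModelSpec) -> list[ChoiceModelSpec]:
    """All 16 on/off combinations of the four NPM modulations of ``base``."""
    specs = []
    for r in range(len(MODULATIONS) + 1):
        for subset in itertools.combinations(MODULATIONS, r):
            specs.append(replace(base, modulations=subset))
    return specs


def chosen_option_utility(table: pd.DataFrame, spec: ChoiceModelSpec,
                          params: ChoiceParams, npm=None):
    """Utility of the option actually chosen, per trial.

    Accepted trials take U(accept); declined (or missing-choice) trials take
    the utility of playing for the fixed 0.5 EUR stakes.  This is the
    chosen-option expected value that can feed back into the mood model.
    For descriptive models the declined option is worth 0.
    """
    g = table["gain"].to_numpy(dtype=float)
    l = table["loss"].to_numpy(dtype=float)
    s = table["size"].to_numpy(dtype=float)
    y = table["choice"].to_numpy(dtype=float)
    accepted = y == 1.0
    if spec.family == "descriptive":
        ua = descriptive_utility(params, g, l, s, spec)
        ud = np.zeros_like(ua)
    else:
        if spec.modulations:
            k_g, k_l, sigma, _ = modulate_params(params, npm, spec)
        else:
            k_g, k_l, sigma = params.k_g, params.k_l, params.sigma
        p_s = prob_success(sigma, s)
        ua = utility_accept(params, g, l, p_s, spec, k_g=k_g, k_l=k_l)
        ud = utility_accept(params, DECLINE_STAKE, DECLINE_STAKE, p_s, spec,
                            k_g=k_g, k_l=k_l)
    return np.where(accepted, ua, ud)


def choice_loglik(table: pd.DataFrame, spec: ChoiceModelSpec,
                  params: ChoiceParams, npm=None) -> float:
    """Bernoulli log-likelihood of the observed accept/decline choices.

    Trials with a missing choice are skipped.  Probabilities are clipped
    away from {0, 1} by ``PROB_EPS`` before taking logs.
    """
    y = table["choice"].to_numpy(dtype=float)
    mask = ~np.isnan(y)
    if not np.all(np.isin(y[mask], (0.0, 1.0))):
        raise ValueError("choices must be 0 or 1")
    p = accept_probability(
        spec, params,
        table["gain"].to_numpy(dtype=float),
        table["loss"].to_numpy(dtype=float),
        table["size"].to_numpy(dtype=float),
        np.arange(1, len(table) + 1),
        npm=npm,
    )
    p = np.clip(np.asarray(p, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    y, p = y[mask], p[mask]
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
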