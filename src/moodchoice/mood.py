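"""Mood models: theoretical mood level (TML) from leaky integration of task events.

The core model writes momentary mood as a constant plus exponentially decaying
sums of quiz expected value, quiz reward prediction error, and chosen-option
utility, plus a linear time drift:

    TML(t) = w0 + wq1 * sum_j g^(t-j) EV_quiz(j)
                + wq2 * sum_j g^(t-j) RPE_quiz(j)
                + wp  * sum_j g^(t-j) EV_choice(j)
                + wt * t

with forgetting factor 0 <= g <= 1.  Structural options give an 18-member
family: event source (null / quiz only / choice only / both), asymmetric
coding of positive feedback (free magnitude R instead of 1), reciprocal
influence of mood on perceived feedback (F(t) = feedback + delta*TML(t-1)),
and a simplified single-weight variant (wf = wq1 = wq2, i.e. integration of
subjective feedback only).

Quiz expected value uses the cohort-mean accuracy: EV = 2*accuracy - 1, and
RPE = F - EV.  The decaying sums are linear recursions, evaluated here as IIR
filters; with the reciprocal term the mood feedback loop folds into a modified
decay on the RPE accumulator, so the whole trace stays vectorised.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "MoodModelSpec",
    "MoodParams",
    "MoodTrace",
    "code_feedback",
    "subjective_feedback",
    "compute_tml",
    "enumerate_mood_models",
    "mood_loglik",
    "interpolate_ratings",
    "prepare_rating_target",
    "gaussian_loglik",
]


@dataclass(frozen=True)
class MoodModelSpec:
    """Structural definition of one mood model.

    source: which task events drive mood — "null", "quiz_only",
        "choice_only", or "both".
    asymmetric: positive feedback coded as free R > 0 instead of 1.
    reciprocal: mood biases perceived feedback, F = feedback + delta*TML(t-1).
    simplified: single weight wf on subjective feedback (wf = wq1 = wq2).

    The three flags are only meaningful when quiz feedback is a source.
    """

    source: str = "quiz_only"
    asymmetric: bool = False
    reciprocal: bool = False
    simplified: bool = False

    def __post_init__(self):
        if self.source not in ("null", "quiz_only", "choice_only", "both"):
            raise ValueError(f"unknown mood source {self.source!r}")
        if self.source in ("null", "choice_only") and (
            self.asymmetric or self.reciprocal or self.simplified
        ):
            raise ValueError(
                "asymmetric/reciprocal/simplified require quiz feedback in source"
            )

    @property
    def uses_quiz(self) -> bool:
        return self.source in ("quiz_only", "both")

    @property
    def uses_choice(self) -> bool:
        return self.source in ("choice_only", "both")

    def free_param_names(self) -> list[str]:
        """Free parameters of this structure (observation noise included)."""
        names = ["omega0", "omega_t"]
        if self.uses_quiz:
            if self.simplified:
                names.append("omega_f")
            else:
                names += ["omega_q1", "omega_q2"]
        if self.uses_choice:
            names.append("omega_p")
        if self.uses_quiz or self.uses_choice:
            names.append("gamma")
        if self.asymmetric:
            names.append("R")
        if self.reciprocal:
            names.append("delta")
        names.append("obs_sd")
        return names

    def label(self) -> str:
        if self.source == "null":
            return "null"
        bits = [self.source]
        if self.simplified:
            bits.append("simpl")
        if self.asymmetric:
            bits.append("asym")
        if self.reciprocal:
            bits.append("recip")
        return "+".join(bits)


@dataclass
class MoodParams:
    """Parameters of a mood model (superset; each spec uses a subset).

    omega0: constant offset.
    omega_q1, omega_q2: weights on quiz EV and RPE decaying sums.
    omega_f: single feedback weight of the simplified variant.
    omega_p: weight on the chosen-option utility decaying sum.
    omega_t: linear time-on-task drift per trial.
    gamma: forgetting factor in [0, 1].
    R: magnitude coding a positive feedback under asymmetry (R > 0).
    delta: weight of previous-trial mood on perceived feedback.
    obs_sd: Gaussian observation noise of the ratings.
    """

    omega0: float = 0.0
    omega_q1: float = 0.0
    omega_q2: float = 0.0
    omega_f: float = 0.0
    omega_p: float = 0.0
    omega_t: float = 0.0
    gamma: float = 0.5
    R: float = 1.0
    delta: float = 0.0
    obs_sd: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.obs_sd <= 0:
            raise ValueError("obs_sd must be positive")

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "MoodParams":
        return cls(**d)


@dataclass
class MoodTrace:
    """Per-trial latent series produced by a mood model."""

    tml: np.ndarray
    f: np.ndarray
    ev_quiz: np.ndarray
    rpe_quiz: np.ndarray
    ev_choice: np.ndarray

    def __len__(self) -> int:
        return len(self.tml)

    def to_frame(self) -> pd.DataFrame:
        """Trace as columns, alignable with a trial table."""
        return pd.DataFrame({"tml": self.tml, "f": self.f,
                             "ev_quiz": self.ev_quiz,
                             "rpe_quiz": self.rpe_quiz,
                             "ev_choice": self.ev_choice})


def code_feedback(feedback, spec: MoodModelSpec, params: MoodParams):
    """Code objective feedback (+1/-1) on the mood scale.

    Positive feedback becomes R under the asymmetric option, 1 otherwise;
    negative feedback is always -1.
    """
    fb = np.asarray(feedback, dtype=float)
    if not np.all(np.isin(fb, (-1.0, 1.0))):
        raise ValueError("feedback values must be +1 or -1")
    pos = params.R if spec.asymmetric else 1.0
    return np.where(fb > 0, pos, -1.0)


def subjective_feedback(coded, tml_prev, params: MoodParams):
    """Perceived feedback F = coded + delta * TML(t-1).

    ``tml_prev`` is the mood carried from the previous trial, before the
    current update.  With delta = 0 perception is veridical.
    """
    return np.asarray(coded, dtype=float) + params.delta * np.asarray(
        tml_prev, dtype=float
    )


def _decaying_sum(x: np.ndarray, g: float) -> np.ndarray:
    """S(t) = g*S(t-1) + x(t), S(0) = 0, as an IIR filter."""
    return lfilter([1.0], [1.0, -g], x)


def _tml_arrays(spec: MoodModelSpec, params: MoodParams, n: int,
                ev_q: np.ndarray | None, pos_fb: np.ndarray | None,
                ev_c: np.ndarray | None) -> tuple[np.ndarray, ...]:
    """Numpy core of the TML recursion.

    ``pos_fb`` is a boolean mask of positive-feedback trials.  The
    reciprocal loop F(t) = coded(t) + delta*TML(t-1) makes the RPE
    accumulator obey S2(t) = (gamma + delta*wq2)*S2(t-1) + u(t) with a
    drive u(t) assembled from the other (mood-independent) accumulators,
    so everything reduces to three linear filters.
    """
    t = np.arange(1, n + 1, dtype=float)
    zeros = np.zeros(n)
    base = params.omega0 + params.omega_t * t

    if spec.source == "null":
        return base, zeros, zeros, zeros, zeros

    g = params.gamma
    if spec.uses_quiz:
        coded = np.where(pos_fb, params.R if spec.asymmetric else 1.0, -1.0)
        if spec.simplified:
            wq1 = wq2 = params.omega_f
        else:
            wq1, wq2 = params.omega_q1, params.omega_q2
    else:
        ev_q = zeros
        coded = zeros
        wq1 = wq2 = 0.0
    if spec.uses_choice:
        wp = params.omega_p
    else:
        ev_c = zeros
        wp = 0.0

    s_ev = _decaying_sum(ev_q, g) if spec.uses_quiz else zeros
    s_evc = _decaying_sum(ev_c, g) if spec.uses_choice else zeros

    if spec.uses_quiz:
        delta = params.delta if spec.reciprocal else 0.0
        # TML(t-1) = base(t-1) + wq1*s_ev(t-1) + wq2*s2(t-1) + wp*s_evc(t-1)
        prev = np.empty(n)
        prev[0] = 0.0
        prev[1:] = base[:-1] + wq1 * s_ev[:-1] + wp * s_evc[:-1]
        drive = coded - ev_q + delta * prev
        s_rpe_eff = lfilter([1.0], [1.0, -(g + delta * wq2)], drive)
        tml = base + wq1 * s_ev + wq2 * s_rpe_eff + wp * s_evc
        tml_prev = np.concatenate(([0.0], tml[:-1]))
        f = coded + delta * tml_prev
        rpe = f - ev_q
    else:
        tml = base + wp * s_evc
        f = zeros
        rpe = zeros
    return tml, f, ev_q, rpe, ev_c


def compute_tml(
    table: pd.DataFrame,
    spec: MoodModelSpec,
    params: MoodParams,
    ev_choice: np.ndarray | None = None,
) -> MoodTrace:
    """Compute the TML trajectory for one agent.

    ``table`` needs columns ``feedback`` and ``accuracy_mean`` when quiz
    feedback is a source; ``ev_choice`` (chosen-option utility per trial,
    from the choice model) is required when choice events are a source.
    """
    n = len(table)
    ev_q = pos_fb = ev_c = None
    if spec.uses_quiz:
        if "accuracy_mean" not in table or table["accuracy_mean"].isna().any():
            raise ValueError(
                "accuracy_mean required per trial when quiz feedback drives mood"
            )
        fb = table["feedback"].to_numpy(dtype=float)
        if not np.all(np.isin(fb, (-1.0, 1.0))):
            raise ValueError("feedback values must be +1 or -1")
        ev_q = 2.0 * table["accuracy_mean"].to_numpy(dtype=float) - 1.0
        pos_fb = fb > 0
    if spec.uses_choice:
        if ev_choice is None:
            raise ValueError("ev_choice series required when source includes choice")
        ev_c = np.asarray(ev_choice, dtype=float)
        if len(ev_c) != n:
            raise ValueError("ev_choice length must match the trial table")
    return MoodTrace(*_tml_arrays(spec, params, n, ev_q, pos_fb, ev_c))


def enumerate_mood_models() -> list[MoodModelSpec]:
    """The 18-member mood model family.

    One null model, one choice-only model, and the 16 combinations of
    source in {quiz_only, both} x simplified x asymmetric x reciprocal.
    """
    specs = [MoodModelSpec(source="null"), MoodModelSpec(source="choice_only")]
    for source, simpl, asym, recip in itertools.product(
        ("quiz_only", "both"), (False, True), (False, True), (False, True)
    ):
        specs.append(
            MoodModelSpec(
                source=source,
                simplified=simpl,
                asymmetric=asym,
                reciprocal=recip,
            )
        )
    assert len({s for s in specs}) == len(specs)
    return specs


def interpolate_ratings(ratings) -> np.ndarray:
    """One rating per trial by linear interpolation of the sparse ratings.

    Endpoints are held constant before the first and after the last rated
    trial; rated values are preserved exactly.  Requires >= 2 ratings.
    """
    r = np.asarray(pd.Series(ratings, dtype=float))
    idx = np.flatnonzero(~np.isnan(r))
    if len(idx) < 2:
        raise ValueError("need at least two rated trials to interpolate")
    x = np.arange(len(r), dtype=float)
    out = np.interp(x, idx.astype(float), r[idx])
    out[idx] = r[idx]
    return out


def prepare_rating_target(
    table: pd.DataFrame,
    interpolate: bool = True,
    rating_column: str = "mood_rating",
    zscore: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Observation vector and mask used to fit ratings.

    Returns ``(y, mask)`` where ``y`` is the per-trial (interpolated,
    z-scored) rating series and ``mask`` marks the trials entering the
    likelihood.  Precomputing this once makes repeated likelihood
    evaluations during optimisation cheap.
    """
    raw = table[rating_column].to_numpy(dtype=float)
    rated = ~np.isnan(raw)
    if interpolate and rated.sum() >= 2:
        y = interpolate_ratings(raw)
        mask = np.ones(len(y), dtype=bool)
    else:
        y = raw.copy()
        mask = rated
    if zscore and mask.any():
        mu, sd = np.nanmean(y[mask]), np.nanstd(y[mask])
        y = (y - mu) / sd if sd > 0 else y - mu
    return y, mask


def gaussian_loglik(resid: np.ndarray, sd: float) -> float:
    """Sum of iid Normal(0, sd) log-densities of the residuals.

    Overflowing residuals (e.g. from an explosive parameter draw during
    optimisation) yield -inf rather than a warning.
    """
    if sd <= 0 or sd * sd == 0 or not math.isfinite(sd):
        return -math.inf
    n = len(resid)
    with np.errstate(over="ignore"):
        ss = float(np.sum(resid**2))
    return float(-0.5 * n * math.log(2 * math.pi) - n * math.log(sd)
                 - 0.5 * ss / sd**2)


def mood_loglik(
    table: pd.DataFrame,
    spec: MoodModelSpec,
    params: MoodParams,
    ev_choice: np.ndarray | None = None,
    interpolate: bool = True,
    rating_column: str = "mood_rating",
    zscore: bool = True,
) -> float:
    """Gaussian log-likelihood of (z-scored) mood ratings given the TML.

    With ``interpolate`` (the default analysis) sparse ratings are first
    linearly interpolated to one point per trial; otherwise only rated
    trials contribute.  Ratings are z-scored before fitting unless
    ``zscore`` is disabled.
    """
    if params.obs_sd <= 0:
        raise ValueError("obs_sd must be positive")
    y, mask = prepare_rating_target(table, interpolate=interpolate,
                                    rating_column=rating_column, zscore=zscore)
    if mask.sum() == 0:
        return 0.0
    trace = compute_tml(table, spec, params, ev_choice=ev_choice)
    return gaussian_loglik(y[mask] - trace.tml[mask], params.obs_sd)
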