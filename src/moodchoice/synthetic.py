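"""Synthetic cohorts for the interleaved quiz / motor-challenge task.

Emulates the task design the models were built for: sessions of 32 trials in
which quiz difficulty and feedback bias create episodes of good and bad mood
(the 7 first and 7 last trials of each session are always medium difficulty
and unbiased, feedback is always positive after a correct answer, and a wrong
answer yields a positive feedback with the session's bias proportion, between
0 and 50%); choice prospects with gain and loss levels of 1-5 EUR and target
sizes spanning a configured window-width range, pseudo-randomised so the
three dimensions stay mutually orthogonal and orthogonal to quiz difficulty;
sparse mood/confidence ratings every third trial; and per-trial region-of-
interest (ROI) baseline proxies linearly coupled to the latent mood level
(vmPFC positively, anterior insula negatively, both riding on a shared
global signal).

Ground-truth mood and choice parameters are drawn per agent from a
population distribution, making parameter- and model-recovery studies fully
self-contained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .choice import ChoiceModelSpec, ChoiceParams, accept_probability, \
    chosen_option_utility
from .mood import MoodModelSpec, MoodParams, compute_tml

__all__ = [
    "TaskConfig",
    "AgentGroundTruth",
    "DIFFICULTY_ACCURACY",
    "DIFFICULTY_BIAS",
    "TRIAL_COLUMNS",
    "gen_quiz_schedule",
    "gen_prospects",
    "simulate_agent",
    "gen_cohort",
    "default_truth_distribution",
    "draw_ground_truth",
]

# cohort-mean correct rates per difficulty level; any monotone spread works
DIFFICULTY_ACCURACY = {"easy": 0.80, "medium": 0.60, "hard": 0.35}
# biased-feedback proportion per difficulty: the easier the questions, the
# more biased the feedback
DIFFICULTY_BIAS = {"easy": 0.40, "medium": 0.20, "hard": 0.0}

TRIAL_COLUMNS = [
    "session", "trial", "difficulty", "accuracy_mean", "correct", "feedback",
    "gain", "loss", "size", "choice", "mood_rating", "confidence_rating",
    "vmpfc", "ains", "global",
]

_ORTHO_TOL = 0.1
_MAX_SHUFFLES = 500


@dataclass
class TaskConfig:
    """Design of one agent's task run.

    size_range gives the narrowest and widest target-window widths as
    fractions of maximal force (windows are centred on 0.25 of maximal
    force); n_size_levels evenly spaced widths are used.  bias_plan is one
    (difficulty, bias proportion) pair per session; when omitted, sessions
    alternate easy/hard with bias taken from DIFFICULTY_BIAS.
    """

    n_sessions: int = 8
    trials_per_session: int = 32
    gain_levels: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)
    loss_levels: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)
    size_range: tuple = (0.03, 0.32)
    n_size_levels: int = 5
    bias_plan: list | None = None
    edge_unbiased: int = 7
    rating_period: int = 3
    first_rated_trial: int = 2
    accuracy_means: dict = field(default_factory=lambda: dict(DIFFICULTY_ACCURACY))
    seed: int = 0

    def __post_init__(self):
        if any(g <= 0 for g in self.gain_levels):
            raise ValueError("gain levels must be positive")
        if any(l <= 0 for l in self.loss_levels):
            raise ValueError("loss levels must be positive")
        if not (0 < self.size_range[0] <= self.size_range[1]):
            raise ValueError("size range must be positive and ordered")
        if self.bias_plan is None:
            cycle = ["easy", "hard"]
            self.bias_plan = [
                (d, DIFFICULTY_BIAS[d])
                for d in (cycle[i % 2] for i in range(self.n_sessions))
            ]
        if len(self.bias_plan) != self.n_sessions:
            raise ValueError("bias_plan needs one entry per session")
        for d, b in self.bias_plan:
            if d not in self.accuracy_means:
                raise ValueError(f"unknown difficulty {d!r}")
            if not 0.0 <= b <= 0.5:
                raise ValueError(
                    f"biased-feedback proportion must lie in [0, 0.5], got {b}")

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    def size_levels(self) -> np.ndarray:
        return np.linspace(self.size_range[0], self.size_range[1],
                           self.n_size_levels)

    def rated_trials(self) -> np.ndarray:
        """1-based global indices of trials with a scheduled rating."""
        return np.arange(self.first_rated_trial, self.n_trials + 1,
                         self.rating_period)


@dataclass
class AgentGroundTruth:
    """Generating model and parameters for one simulated agent."""

    mood_spec: MoodModelSpec
    mood_params: MoodParams
    choice_spec: ChoiceModelSpec
    choice_params: ChoiceParams
    rating_noise_sd: float = 0.3
    confidence_trend: float = 0.0
    roi_coupling: dict = field(default_factory=lambda: dict(
        b_v=0.25, b_a=0.25, global_sd=0.5, roi_noise_sd=0.8))
    # which generated signal drives each active choice modulation, e.g.
    # {"gain": "vmpfc", "loss": "ains"}.  Values in {vmpfc, ains, npm}.
    # Modulation acts through the region's intrinsic activity (mood-coupled
    # plus idiosyncratic); the shared global signal is observation-level
    # nuisance and is added only to the recorded baseline.
    modulator_signals: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.rating_noise_sd < 0:
            raise ValueError("rating noise sd must be non-negative")
        for key in ("b_v", "b_a", "global_sd", "roi_noise_sd"):
            if self.roi_coupling[key] < 0:
                raise ValueError(f"roi_coupling[{key!r}] must be non-negative")
        for mod in self.choice_spec.modulations:
            sigs = self.modulator_signals or {}
            if mod not in sigs:
                raise ValueError(
                    f"modulator_signals must name a signal for {mod!r}")


def gen_quiz_schedule(config: TaskConfig, rng=None) -> pd.DataFrame:
    """Per-trial difficulty, cohort accuracy, correctness, and feedback.

    Edge trials (the first and last ``edge_unbiased`` of each session) are
    medium difficulty with zero bias; middle trials take the session's
    difficulty and bias.  Feedback is always +1 when correct; a wrong answer
    yields +1 with the bias proportion, else -1.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    t = 0
    for s, (difficulty, bias) in enumerate(config.bias_plan):
        for i in range(config.trials_per_session):
            t += 1
            edge = (i < config.edge_unbiased
                    or i >= config.trials_per_session - config.edge_unbiased)
            d = "medium" if edge else difficulty
            b = 0.0 if edge else bias
            acc = config.accuracy_means[d]
            correct = int(rng.random() < acc)
            if correct:
                fb = 1
            else:
                fb = 1 if rng.random() < b else -1
            rows.append((s, t, d, acc, correct, fb))
    return pd.DataFrame(rows, columns=["session", "trial", "difficulty",
                                       "accuracy_mean", "correct", "feedback"])


def _balanced_column(levels, n, rng) -> np.ndarray:
    reps = int(np.ceil(n / len(levels)))
    col = np.tile(np.asarray(levels, dtype=float), reps)[:n]
    rng.shuffle(col)
    return col


def gen_prospects(config: TaskConfig, accuracy_mean=None, rng=None
                  ) -> pd.DataFrame:
    """Balanced, mutually orthogonal gain / loss / size sequences.

    Each session tiles the configured levels and shuffles them; the whole
    schedule is re-shuffled until all pairwise correlations among the three
    dimensions (and with quiz difficulty, when ``accuracy_mean`` is given)
    fall below 0.1 in magnitude.  Schedules too short for a balanced design
    fall back to random draws with a warning.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_trials
    per = config.trials_per_session
    level_sets = (config.gain_levels, config.loss_levels,
                  config.size_levels())
    if n == 1:
        return pd.DataFrame({
            "gain": [float(rng.choice(config.gain_levels))],
            "loss": [float(rng.choice(config.loss_levels))],
            "size": [float(rng.choice(config.size_levels()))]})
    if per < max(len(ls) for ls in level_sets):
        warnings.warn("too few trials per session for a balanced design; "
                      "falling back to random draws")
        return pd.DataFrame({
            "gain": rng.choice(config.gain_levels, size=n),
            "loss": rng.choice(config.loss_levels, size=n),
            "size": rng.choice(config.size_levels(), size=n)})

    extra = (np.asarray(accuracy_mean, dtype=float)
             if accuracy_mean is not None else None)
    for _ in range(_MAX_SHUFFLES):
        cols = []
        for levels in level_sets:
            col = np.concatenate([
                _balanced_column(levels, per, rng)
                for _ in range(config.n_sessions)])
            cols.append(col)
        mat = np.column_stack(cols)
        check = mat if extra is None or np.std(extra) == 0 else \
            np.column_stack([mat, extra])
        r = np.corrcoef(check, rowvar=False)
        if np.max(np.abs(r[np.triu_indices_from(r, k=1)])) < _ORTHO_TOL:
            return pd.DataFrame(mat, columns=["gain", "loss", "size"])
    raise RuntimeError("could not find an orthogonal prospect schedule")


def simulate_agent(config: TaskConfig, truth: AgentGroundTruth
                   ) -> pd.DataFrame:
    """Forward-simulate one agent's full trial table.

    Mood follows the ground-truth mood model; sparse mood ratings are the
    latent mood plus Gaussian noise on the scheduled trials.  Confidence
    ratings carry no feedback dependence (noise plus an optional linear
    trend).  Choices are Bernoulli draws from the ground-truth choice
    model's acceptance probability.  ROI baselines at prospect onset are
    vmpfc = b_v*TML + global + noise and ains = -b_a*TML + global + noise,
    with the shared global signal recorded.  When the ground-truth choice
    model is NPM-modulated, the modulation acts through the ROI's intrinsic
    activity (the baseline minus the shared global nuisance).
    """
    rng = np.random.default_rng(truth.seed)
    table = gen_quiz_schedule(config, rng=rng)
    prospects = gen_prospects(
        config, accuracy_mean=table["accuracy_mean"].to_numpy(), rng=rng)
    table = pd.concat([table, prospects], axis=1)
    n = len(table)
    t_idx = np.arange(1, n + 1, dtype=float)

    if not truth.mood_spec.uses_choice:
        trace = compute_tml(table, truth.mood_spec, truth.mood_params)
        tml = trace.tml
    else:
        tml = None  # resolved after choices below

    cpl = truth.roi_coupling
    shared = rng.normal(0.0, cpl["global_sd"], size=n)
    roi_eps_v = rng.normal(0.0, cpl["roi_noise_sd"], size=n)
    roi_eps_a = rng.normal(0.0, cpl["roi_noise_sd"], size=n)

    def roi_intrinsic(tml_series):
        v = cpl["b_v"] * tml_series + roi_eps_v
        a = -cpl["b_a"] * tml_series + roi_eps_a
        return v, a

    def npm_map(v, a):
        if not truth.choice_spec.modulations:
            return None
        sigs = {"vmpfc": v, "ains": a, "npm": v - a}
        return {m: sigs[truth.modulator_signals[m]]
                for m in truth.choice_spec.modulations}

    if tml is not None:
        v_int, a_int = roi_intrinsic(tml)
        p = accept_probability(
            truth.choice_spec, truth.choice_params,
            table["gain"].to_numpy(), table["loss"].to_numpy(),
            table["size"].to_numpy(), t_idx, npm=npm_map(v_int, a_int))
        choices = (rng.random(n) < p).astype(float)
    else:
        # mood integrates chosen-option utility: draw choices from the
        # choice model (any ROI modulation here sees the mood-free part of
        # the baseline), then compute the mood trace the choices imply
        v_int0, a_int0 = roi_intrinsic(np.zeros(n))
        p = accept_probability(
            truth.choice_spec, truth.choice_params,
            table["gain"].to_numpy(), table["loss"].to_numpy(),
            table["size"].to_numpy(), t_idx, npm=npm_map(v_int0, a_int0))
        choices = (rng.random(n) < p).astype(float)
        tmp = table.copy()
        tmp["choice"] = choices
        ev_c = chosen_option_utility(tmp, truth.choice_spec,
                                     truth.choice_params)
        trace = compute_tml(table, truth.mood_spec, truth.mood_params,
                            ev_choice=ev_c)
        tml = trace.tml
        v_int, a_int = roi_intrinsic(tml)

    vmpfc = v_int + shared
    ains = a_int + shared
    table["choice"] = choices
    rated = config.rated_trials() - 1  # 0-based positions
    mood_rating = np.full(n, np.nan)
    conf_rating = np.full(n, np.nan)
    mood_rating[rated] = tml[rated] + rng.normal(
        0.0, truth.rating_noise_sd, size=len(rated))
    conf_rating[rated] = (truth.confidence_trend * t_idx[rated]
                          + rng.normal(0.0, max(truth.rating_noise_sd, 1e-12),
                                       size=len(rated)))
    table["mood_rating"] = mood_rating
    table["confidence_rating"] = conf_rating
    table["vmpfc"] = vmpfc
    table["ains"] = ains
    table["global"] = shared
    return table[TRIAL_COLUMNS]


BEST_MOOD_SPEC = MoodModelSpec(source="quiz_only", simplified=True,
                               asymmetric=True, reciprocal=True)
BEST_CHOICE_SPEC = ChoiceModelSpec(family="normative",
                                   include_decline_utility=True,
                                   curvature=False)


def default_truth_distribution() -> dict:
    """Population means and sds of the generating parameters.

    The generating mood model integrates subjective quiz feedback with
    exponential decay (single weight, asymmetric positive coding, reciprocal
    mood-on-feedback influence); the generating choice model is the
    expected-utility model with distinct gain/loss weights, no curvature,
    and an explicit decline utility.  Values give TML fluctuations of order
    one (z-scored rating scale), moderately loss-averse choices spread over
    the acceptance range, and a forgetting factor around 0.77.
    """
    return {
        "mood_spec": BEST_MOOD_SPEC,
        "choice_spec": BEST_CHOICE_SPEC,
        "mood": {
            "omega0": (0.0, 0.2),
            "omega_f": (0.5, 0.12),
            "omega_t": (-0.01, 0.004),
            "gamma": (0.77, 0.06),
            "R": (2.0, 0.4),
            "delta": (0.3, 0.08),
        },
        "choice": {
            "k_g": (1.0, 0.2),
            "k_l": (1.5, 0.3),
            "sigma": (0.12, 0.02),
            "k_t": (-0.003, 0.002),
            "k0": (0.5, 0.3),
        },
        "rating_noise_sd": 0.3,
        "confidence_trend": 0.0,
        "roi_coupling": dict(b_v=0.25, b_a=0.25, global_sd=0.5,
                             roi_noise_sd=0.8),
        "modulator_signals": None,
    }


_PARAM_BOUNDS = {
    "gamma": (0.02, 0.98),
    "R": (0.1, None),
    "sigma": (0.02, None),
    "obs_sd": (0.01, None),
    "c_g": (0.0, 1.0),
    "c_l": (0.0, 1.0),
}


def _draw_param(name, mean, sd, rng):
    if sd < 0:
        raise ValueError(f"population sd for {name!r} must be non-negative")
    v = rng.normal(mean, sd)
    lo, hi = _PARAM_BOUNDS.get(name, (None, None))
    if lo is not None:
        v = max(v, lo)
    if hi is not None:
        v = min(v, hi)
    return v


# ceiling on the effective mood decay gamma + delta*omega_f: the reciprocal
# feedback loop must stay stable or mood diverges over a session
_STABILITY_CAP = 0.95


def draw_ground_truth(dist: dict, seed: int) -> AgentGroundTruth:
    """Draw one agent's ground truth from the population distribution.

    The reciprocal mood-on-feedback loop amplifies the decaying feedback sum
    by delta times the feedback weight; draws are adjusted (delta shrunk) so
    the effective decay stays below one and simulated mood cannot explode.
    """
    rng = np.random.default_rng(seed)
    mood_vals = {k: _draw_param(k, m, s, rng)
                 for k, (m, s) in dist["mood"].items()}
    wf = mood_vals.get("omega_f",
                       max(abs(mood_vals.get("omega_q1", 0.0)),
                           abs(mood_vals.get("omega_q2", 0.0))))
    if "delta" in mood_vals and "gamma" in mood_vals and wf:
        headroom = _STABILITY_CAP - mood_vals["gamma"]
        cap = headroom / abs(wf)
        if abs(mood_vals["delta"]) > cap:
            mood_vals["delta"] = math.copysign(max(cap, 0.0),
                                               mood_vals["delta"])
    choice_vals = {k: _draw_param(k, m, s, rng)
                   for k, (m, s) in dist["choice"].items()}
    weights = {k[2:]: v for k, v in choice_vals.items() if k.startswith("w_")}
    choice_scalars = {k: v for k, v in choice_vals.items()
                      if not k.startswith("w_")}
    return AgentGroundTruth(
        mood_spec=dist["mood_spec"],
        mood_params=MoodParams(**mood_vals),
        choice_spec=dist["choice_spec"],
        choice_params=ChoiceParams(weights=weights, **choice_scalars),
        rating_noise_sd=dist.get("rating_noise_sd", 0.3),
        confidence_trend=dist.get("confidence_trend", 0.0),
        roi_coupling=dict(dist.get("roi_coupling")
                          or dict(b_v=0.25, b_a=0.25, global_sd=0.5,
                                  roi_noise_sd=0.8)),
        modulator_signals=dist.get("modulator_signals"),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def gen_cohort(config: TaskConfig, n_agents: int,
               truth_distribution: dict | None = None, seed: int = 0
               ) -> tuple[list[pd.DataFrame], list[AgentGroundTruth]]:
    """Simulate a cohort; fully reproducible from ``seed``.

    Each agent gets its own task randomisation (schedule seed derived from
    the cohort seed) and ground-truth parameters drawn from the population
    distribution.  Returns the trial tables and the ground-truth registry.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    dist = truth_distribution or default_truth_distribution()
    for group in ("mood", "choice"):
        for k, (m, s) in dist[group].items():
            if s < 0:
                raise ValueError(f"population sd for {k!r} must be >= 0")
    root = np.random.default_rng(seed)
    tables, truths = [], []
    for a in range(n_agents):
        agent_seed = int(root.integers(0, 2**31 - 1))
        truth = draw_ground_truth(dist, agent_seed)
        cfg = replace(config, seed=int(np.random.default_rng(agent_seed + 1)
                                       .integers(0, 2**31 - 1)))
        tables.append(simulate_agent(cfg, truth))
        truths.append(truth)
    return tables, truths
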