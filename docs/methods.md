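# Methods

`moodchoice` implements a complete analysis chain for an interleaved
quiz / risky-choice experiment: latent mood dynamics fitted to sparse
ratings, expected-utility models fitted to accept/decline choices,
approximate-Bayesian model comparison at the group level, and a trial-level
"neural proxy for mood" (NPM) analysis linking simulated region-of-interest
(ROI) baselines to choice parameters.  This note documents the models, the
synthetic study conditions, the numerical choices, and the known
limitations.

## Mood model family

The theoretical mood level integrates task events with exponential
forgetting:

    TML(t) = w0 + wq1 * sum_{j<=t} g^(t-j) EV_quiz(j)
                + wq2 * sum_{j<=t} g^(t-j) RPE_quiz(j)
                + wp  * sum_{j<=t} g^(t-j) EV_choice(j)
                + wt * t

with forgetting factor 0 <= g <= 1, quiz expected value EV = 2*accuracy - 1
(cohort-mean accuracy per difficulty level), prediction error
RPE = F - EV, and EV_choice the chosen-option utility from the choice
model.  Structural options: event source (null / quiz only / choice only /
both), asymmetric coding of positive feedback (magnitude R > 0 instead of
1), reciprocal mood-on-perception influence F(t) = feedback + delta *
TML(t-1) with TML(0) = 0, and a simplified single-weight variant
(wf = wq1 = wq2, algebraically equivalent to weighting subjective feedback
alone).  One null + one choice-only + 2 sources x 2^3 option combinations
give the 18-member family.  The summand is indexed by j (the only reading
that makes the expression an integration over time), and asymmetric coding
is applied to the objective feedback before the reciprocal term is added.

The decaying sums are linear recursions evaluated as IIR filters.  With the
reciprocal option the feedback loop substitutes into a modified decay
g + delta*wq2 on the RPE accumulator plus a drive term built from the other
(mood-independent) accumulators, so the whole trace remains vectorised; an
O(n^2) explicit sum serves as the test oracle.

Ratings are modelled as Gaussian observations of TML with free sd — the
standard observation model of variational-Laplace behavioural fitting.  Two
fitting targets are supported: the linearly interpolated, z-scored rating
series (one point per trial; the pipeline default) and the rated trials
only.  These are not interchangeable for validation purposes: linear
interpolation low-passes the target, so the best-fitting model of
interpolated data is a smoothed version of the generating model (inflated
decay, a preference for the more flexible separate-weight variants).  All
ground-truth recovery studies therefore fit rated trials only, which keeps
the generating model the likelihood maximiser.

### Identifiability of the reciprocal term

Within the simplified variant the reciprocal influence is structurally
confounded with the decay: substituting the loop gives an effective decay
g_eff = g + delta*wf plus a slow trend absorbed by w0 and wt.  Model
evidence therefore cannot separate the reciprocal model from its
non-reciprocal reduction at a larger g; what remains identifiable is the
family structure (quiz source, single weight, asymmetry) and the *sign* of
delta, which the MAP recovers through the prior geometry along the
g/delta ridge (the decay demanded by the data exceeds what the logistic
prior on g favours, so the posterior allocates the excess to delta > 0).
The recovery study checks exactly these identifiable quantities.

## Choice model family

Subjective success probability for a target window of width S (fraction of
maximal force, centred on 0.25) under Gaussian motor noise sigma:

    p_s = Phi((S/2)/sigma) - Phi(-(S/2)/sigma)

computed from normal CDFs; adaptive quadrature of the underlying integral
is the test oracle.  Normative utilities:

    U(accept)  = p_s * k_g * G^c_g - (1-p_s) * k_l * L^c_l
    U(decline) = same form at the fixed 0.5 EUR consolation stakes

with optional curvatures c in [0, 1] and an optional explicit decline
utility (otherwise absorbed into the bias k0); choice probability is
logistic in U(accept) - U(decline) + k_t*t + k0.  No separate softmax
temperature exists: the scale lives in k_g, k_l, k0.  Descriptive models
replace the utility with a linear combination of any subset of
{G, L, S, GL, GS, LS, GLS} on raw (unstandardised) values, keeping k_t and
k0.  4 pseudo-normative + 2^7 descriptive structures (the empty-regressor
model included) give 132 models.

NPM modulation scales parameters per trial, k_g'(t) = k_g*(1 +
k_mg*NPM(t)) (likewise k_l, sigma), and/or adds k_m0*NPM(t) to the
utility; sigma' is floored at 1e-6 since a strong negative modulation
could otherwise flip its sign.  The four switches give 16 variants of any
base model.  A modulator may be a single series or a mapping from
modulation dimension to its own series (used for region-specific variants).

## Inference

Single-agent fits maximise the log joint on an unconstrained scale (log
transform for sigma, R, and the observation sd; scaled logit for g, c_g,
c_l; identity otherwise) with independent Gaussian priors, mean 0 and sd 3
on the transformed scale.  The optimiser is L-BFGS-B with a two-stage
multi-start: eight starts (prior mean plus prior draws), a 40-iteration
exploratory run from each, then full polishing of the three best
endpoints; ties break toward the smaller parameter norm.  Model evidence
uses the Laplace approximation, log p(y) ~= log joint at the mode +
(d/2) log 2*pi - (1/2) log |H|, with H the central finite-difference
Hessian (step 1e-4).  Quasi-Newton runs can halt on saddles, so candidates
are screened by their Hessian spectrum and the best positive-definite one
wins; eigenvalues are floored at 1e-8 (relative) before the determinant,
and a fit whose curvature check fails is flagged, never silently accepted.
A BIC evidence is available behind a flag.  The linear-Gaussian special
case (null mood model, known noise sd) is checked against the exact
conjugate marginal likelihood, where the Laplace approximation is exact.

Group-level model selection treats model identity as a random effect: the
standard variational Dirichlet update yields posterior frequency counts,
and exceedance probabilities come from 10^5 seeded Dirichlet draws.
Family comparisons follow the even-prior convention (each member model
gets prior count 1/|family| so families start with equal mass) and sum
member frequencies inside the same draws.  Classical (not protected)
exceedance probabilities are reported.  A known limitation of the
variational update: with completely uninformative evidence and uneven
family sizes the fixed point drifts toward the family with the larger
per-member prior count; with any real evidence differences this is
irrelevant, but family results on flat evidence matrices should not be
over-read.  Parameter-level group inference reports both the one-sample
two-tailed t-test and the Wilcoxon signed-rank test.

## Synthetic study conditions

The generator reproduces the task design the models were built for: 8
sessions of 32 trials (256 trials); the first and last 7 trials of each
session are medium difficulty and unbiased; middle trials take the
session's difficulty and feedback bias; feedback is always positive after
a correct answer and positive with the session's bias proportion (0-0.5)
after a wrong one.  Difficulty accuracies (easy 0.80 / medium 0.60 / hard
0.35) and the difficulty-to-bias map (0.40 / 0.20 / 0) are free design
values chosen once: any monotone spread works for recovery, and only these
enter EV_quiz.  Prospects tile gain and loss levels (1-5 EUR) and five
target widths (0.03-0.32 of maximal force) per session, reshuffling until
all pairwise correlations among the three dimensions and quiz difficulty
are below 0.1.  Ratings occur every third trial starting at trial 2;
confidence ratings are generated with no feedback dependence (noise plus
an optional time trend) so the confidence-null comparison has a true null.

Ground-truth parameters are drawn per agent from a population
distribution.  The generating mood model is the single-weight asymmetric
reciprocal quiz model with population means wf = 0.5, g = 0.77, R = 2.0,
delta = 0.3, wt = -0.01, w0 = 0, rating noise sd 0.3; delta is shrunk per
agent where needed to keep the effective decay g + delta*wf below 0.95,
because an explosive mood loop is not a plausible participant and destroys
every downstream analysis.  The generating choice model is the
expected-utility model with explicit decline utility and population means
k_g = 1.0, k_l = 1.5 (mild loss aversion), sigma = 0.12, k_t = -0.003,
k0 = 0.5, giving acceptance rates spread over the mid-range.

ROI baselines are per-trial scalars: vmpfc = b_v*TML + global + noise and
ains = -b_a*TML + global + noise with b_v = b_a = 0.25, shared global sd
0.5, idiosyncratic sd 0.8.  The weak mood coupling is deliberate: it
matches the regime of trial-level imaging baselines (small regression
weights, noise-dominated), and it is what makes region-specific modulation
recovery a well-posed experiment — with strongly mood-dominated baselines
the two regions' signals become collinear and no analysis could attribute
a modulation to one region.  When the ground-truth choice model is
NPM-modulated, the modulation acts through the region's intrinsic activity
(baseline minus the shared global nuisance); the global signal is
observation-level noise, which the analysis side removes by
orthogonalization, mirroring the whole-brain-mean correction of the
original analysis chain.  The modulation signs follow the mood story: the
gain weight rises with vmPFC activity (k_mg > 0) and the loss weight rises
with aIns activity (k_ml > 0 on aIns, equivalently negative on the NPM,
in which aIns enters with a negative weight).

What the generator does not emulate: BOLD dynamics (no hemodynamics, no
autocorrelation), motor execution (success enters only through p_s),
question content, session-level non-stationarities other than the linear
drift, and rating discretisation (ratings are continuous).  Passing
recovery tests therefore show the chain is correct and well-posed under
its own assumptions, not that real data meet those assumptions.

## Reference studies and problem sizes

The validation studies run at sizes chosen to finish comfortably on a
single core while keeping the group-level tests well powered: mood-model
recovery at 23 agents x 256 trials (the reference cohort), the confidence
null at 10 agents, and the modulation analyses at 16 agents.

Within the 16 NPM variants, model- and family-level selection is not a
robust readout on cohorts of this size: a sigma modulation raises or
lowers the success probability for every prospect and thereby mimics a
concordant gain+loss modulation through the mean-utility channel with one
parameter fewer, so the complexity penalty lets the mimic win at some
seeds.  The dimension-specific signatures that separate the variants
(gain-, loss-, and size-interactions) are second-order at 256 trials.  The
robust readouts are the weight-level group tests on the fully modulated
model (k_mg positive, k_ml negative on the NPM, sigma and additive null)
and the region-specific comparison, where the two proxies are distinct
signals; the acceptance script reports those.  `scripts/acceptance.py` re-runs all of
them from scratch and writes the resulting numbers as JSON.

## Known limitations

* The reciprocal mood parameter is sign- but not scale-identified in the
  simplified model (see above); reported delta magnitudes depend on the
  rating z-scoring and the g prior.
* Laplace evidence is a local approximation; multimodal posteriors are
  handled only through multi-start and curvature screening.
* The NPM weights are fitted per agent by default; a group-level fit is
  available but the two modes are not averaged.
* k0 and a constant decline utility trade off in the best choice model;
  both are retained, so their individual values should not be interpreted.
* Descriptive-model interaction terms use raw products, so their weights
  are scale-dependent.
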