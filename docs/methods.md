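# Methods

This note documents the models implemented in `selfother`, the
assumptions and numerical choices behind them, and what the synthetic
cohorts can and cannot establish.

## False belief task generation

The environment is a Bernoulli parameter drifting as a bounded random
walk: step size 0.025 per sampling trial, mirror-reflected at 0 and 1
(x → −x at the lower bound, x → 2 − x at the upper). Two walks are
drawn per sequence — one feeding the subject's "privileged" samples,
one feeding the other agent's misleading "decoy" samples — and a pair
is accepted only if |Pearson r| < 0.1 between the walks. Walk starting
points are uniform on [0.2, 0.8] so early trials are not dominated by
boundary reflections; step direction is equiprobable up/down. Both
conventions are configurable.

Trial-type schedules are exact seeded permutations of the per-context
counts: Hi-Share training 112 privileged / 112 decoy / 224 shared (50%
shared), Lo-Share training 196 / 196 / 56 (12.5% shared), and testing
148 of each type (one third shared). Privileged outcomes are Bernoulli
draws from the first walk, decoy outcomes from the second, shared
outcomes from a fair coin. Probes (a Self or Other report on the
probability scale) follow after every 4–9 sampling trials, gap drawn
uniformly with both endpoints included; Self and Other probes are
balanced to within one and randomly ordered. Probes are modelled as
separate report events attached to the preceding sampling trial.

Candidate sequences are screened with a leak-free reference learner
(learning rate 0.1, no decay, no leak): a sequence is accepted when the
cross-agent belief/PE-magnitude correlations |r(B_self, |PE_other|)|
and |r(B_other, |PE_self|)| are both below 0.1. Two other pairs are
deliberately *not* screened, because they are properties of the design
rather than of a particular draw: with half of all trials shared, both
agents' beliefs are driven by the same shared outcomes, so the
belief–belief correlation of a leak-free learner is structurally ~0.6
in Hi-Share training; and the two PE-magnitude series have disjoint
structural zeros (self-PEs vanish on decoy trials, other-PEs on
privileged trials), which forces a correlation between their
magnitudes whenever shared trials are rare. Rejection sampling retries
with fresh substreams up to 1,000 times (acceptance rates are roughly
0.45 in Hi-Share and 0.64 in Lo-Share training).

## The Self-Other leak learning family

Both agents' beliefs update in parallel each sampling trial:

    B[t+1] = B[t] + α·PE_own + δ·(0.5 − B[t]) + λ·PE_other

Own-agent prediction errors are zeroed on trials carrying no
information for that agent (decoy trials for Self, privileged trials
for Other). Beliefs start at 0.5 (the decay attractor) and are clipped
to [0, 1] after the full update. When the learning rate is split by
trial class, the "shared" α applies on shared trials and the
"non-shared" α on privileged and decoy trials; when a single δ or λ is
present it is shared across agents, and two-parameter variants split
by agent. The model grid crosses four α structures (single / by agent
/ by trial class / by both) × two τ structures (single / by agent) ×
{0, 1, 2} δ × {0, 1, 2} λ = 72 variants, labelled M1–M72 in that
nesting order. The grid reproduces the family's stated degrees of
freedom; the id ↔ structure map is deterministic and importable, but
individual ids are this package's own convention.

The leak:learning-rate ratio λ/α (agent-matched α averaged over trial
classes when split) is the behavioural index of Self-Other mergence.
Simulations show the binned Self-Other belief correlation rises
monotonically with λ *within the λ < α regime*; beyond λ ≈ α each
agent's belief is driven more by the other agent's stream than its own
and the correlation falls again. Tests therefore probe monotonicity on
a λ grid below the learning rate.

## Response likelihood and fitting

Probe reports are modelled as Beta-distributed with mode equal to the
probed agent's current model belief and variance equal to that agent's
temperature τ. Writing s = a + b, the mode constraint gives
a = 1 + m(s − 2), b = 1 + (1 − m)(s − 2), and the variance
a·b / (s²(s + 1)) decreases strictly in s from 1/12 (the a = b → 1
limit, independent of the mode) toward 0; the shape solve is therefore
a monotone one-dimensional root find, implemented as vectorised
bisection to relative tolerance below 1e−12. τ is bounded above by
0.999 × 1/12. Reports and beliefs are clipped to [1e−4, 1 − 1e−4]
before evaluation.

Subjects are fit by maximum likelihood in a transformed unconstrained
space (scaled logistic for rates onto (1e−4, 1 − 1e−4) and for τ onto
(1e−6, 0.999/12)) with L-BFGS-B, finite-difference gradients,
convergence tolerance 1e−6 on the NLL, and multi-restart (one neutral
start at α-like values 0.15 / τ 0.01 plus Gaussian-perturbed restarts;
10 by default, fewer in the scaled-down suites). BIC is
k·ln(n_probes) + 2·NLL; model comparison sums BIC over subjects and
takes the minimum.

## Recovery suites

Parameter recovery follows the two-stage estimate → simulate → refit
design: a cohort's behaviour is first fit, responses are re-simulated
from each subject's *fitted* parameters, the model is refit, and the
between-subjects Spearman ρ(fitted, recovered) is reported per
parameter. At the study's cohort size (40 subjects, the Hi-Share
training probe schedule of ~68 probes) the generating leak model
yields ρ ≈ 0.8 (α), 0.96 (τ), 0.65 (δ), 0.65 (λ). δ and λ are
intrinsically the weaker-identified parameters at a single session's
probe count: under the narrow ground-truth spreads of the generator
(δ ∈ [0, 0.1], λ ∈ [0.02, 0.15]) the one-stage ρ against generator
draws is lower (~0.47), which is an information limit, not an
optimiser failure (fitted NLL beats the truth's NLL for every
subject).

Model recovery simulates from each candidate (each subject's
parameters under that candidate), fits all candidates, tallies
lowest-BIC winners into p(fit|sim), and inverts by Bayes' rule with a
uniform model prior to p(sim|fit); with a uniform prior the inversion
is exactly column normalisation. Leak effects near λ ≈ 0.05 sit at the
BIC detection floor for ~68 probes (2·ΔNLL ≈ ln 68), so per-subject
winner tallies from leak-generated data split roughly evenly while
no-leak data almost never prefer the leak model — the confusion matrix
is diagonally dominant and the summed-BIC comparison recovers the
generating class.

## P(share) tracker

The perceived probability of a shared trial updates by a delta rule
P[t+1] = P[t] + η(S − P[t]), S ∈ {0, 1}, applied on every sampling
trial. Starting values are the true training-session shared rates
(0.125 Lo-Share, 0.5 Hi-Share); the learning-rate grid is
{0.01, 0.025, 0.05, 0.075, 0.1}. Regressor tables carry P and |S − P|
per trial and are z-scored (mean 0, sd 1) by default. Smaller η yields
smoother, lower-variance traces.

## Hierarchical discounting

The 60-question battery pairs immediate rewards of £1–£9 against
larger delayed rewards of £2–£10 at delays of 1, 7, 14, 28, 42, 56 or
84 days; the generator draws a reproducible pseudo-random battery
constrained so every magnitude and every delay appears. Values follow
V_later = V / (1 + k·D^S) (S = 1 recovers the one-parameter
hyperbola), choices a softmax with inverse temperature β. Parameters
live in log space with independent Gaussian group priors. The EM loop
alternates subject MAP estimates (BFGS; Laplace variances from the
inverse finite-difference Hessian diagonal, floored at 1e−8 when not
positive definite) with prior updates (mean of MAPs; variance the mean
of squared deviation plus subject variance, floored at 1e−6), to
convergence at 1e−4 on both hyperparameters (cap 200 iterations).

iBIC approximates each subject's evidence by Monte-Carlo integration
over the fitted prior (1,000 draws) and penalises the prior means and
variances against the total choice count. Detecting the
time-perception exponent S is a group-level question: with realistic
heterogeneity (σ(log S) = 0.35) the two-parameter model wins the iBIC
comparison reliably at 40 subjects but not at 20 — the comparison
stages therefore run at the full cohort size of 40.

The model-free area under the discounting curve estimates an
indifference point per delay from a ridge-logistic fit of choice
against the sooner/later amount ratio (pinned at 1 or 0 when a delay's
choices are one-sided, with a choice-rate fallback when the fitted
slope is not decreasing) and integrates by trapezoid over normalised
delay with value 1 at zero delay. AUC rank-correlates around −0.95
with the aggregate measure log(kS) on synthetic cohorts.

## LOSO classification

Subjects are labelled high/low discounters by a median split on
log(kS) (the subject at the median goes to "low"). A logistic
regression on z-scored features is trained with every subject held out
once; performance is the median hold-out cross-entropy
−[y·ln p + (1 − y)·ln(1 − p)]. Inference permutes the labels (5,000
permutations by default) and recomputes the median each time; p-values
are two-sided with add-one correction. To make this tractable the
logistic solver is a small batched Newton (IRLS) with an L2 ridge of
1e−3 on the coefficients (which also keeps separable folds
well-posed); all permutations of a fold are solved simultaneously. The
same solver underlies the feature-set comparison (null distribution of
median cross-entropy differences under shared label permutations).

## Synthetic cohorts

Ground-truth learning parameters are uniform: α ∈ [0.05, 0.3],
τ ∈ [0.005, 0.05], δ ∈ [0, 0.1], and, in the Hi-Share context only,
λ ∈ [0.02, 0.15] — the Lo-Share generator omits λ, mirroring the
contexts' distinct generative regimes. Discounting parameters are
log-Gaussian: log k ~ N(−3.5, 0.9²) (median k ≈ 0.03/day, spanning
shallow to steep discounters), log S ~ N(0, 0.35²) (time-perception
exponents roughly 0.5–2), log β ~ N(0.7, 0.4²) (choice consistency
typical of fitted intertemporal data). A coupling knob plants a rank
correlation between the leak factor λ:α and log(kS) through a Gaussian
copula (latent Pearson 2·sin(πρ/6)): the λ:α ratio is drawn uniform on
[0.1, 1.5] from one latent coordinate (λ = ratio·α), log k from the
other. Because λ alone is a diluted proxy for the coupled ratio and
median-split LOSO has modest power, the planted-association detection
checks use a strong plant (ρ = −0.8) at 40 subjects.

Perspective-taking data come from an Euler–Maruyama diffusion
(dt = 0.5 ms, unit noise; the scale is absorbed into drift and
boundary as in standard DDM conventions), upper boundary = correct
response, per-trial drift drawn from one of twelve cell means
(avatar × perspective × congruency) with shared variance, and
subject-level Gaussian non-decision time, relative start point and
boundary separation. Defaults (congruent drift 2.0, incongruent 1.4,
boundary 1.8, non-decision 450 ms) give ~92% accuracy, ~1.0 s mean RT,
a ~100 ms congruency effect and a negligible fraction outside the
500–3000 ms validity window; trials outside it (or not absorbed within
10 s) are flagged, never silently dropped. Transfer effects are
(transfer − baseline) drift changes minus the same change on arrow
trials.

## What the synthetic tests do and do not show

The cohorts obey the package's own generative assumptions exactly:
probe reports really are Beta around the model belief, choices really
are softmax-hyperbolic. Passing recovery and model-selection tests
therefore demonstrates correctness and identifiability of the
machinery under the design's trial counts and realistic parameter
ranges — not that human behaviour follows these models, and not any of
the neural claims the behavioural models feed into (no BOLD, myelin or
decoding data are simulated). Sequence screening, probe scheduling and
trial counts match the task design, so statistical power at a given
cohort size transfers approximately, but sources of real-data
misfit — lapses, scale-use biases on the probability slider, session
effects — are absent by construction.

## Scaled problem sizes

The test suite and the acceptance script run every stochastic check at
an explicit, fixed problem size chosen as the smallest that gives the
relevant comparison stable margins: cohorts of 40 for parameter
recovery, iBIC and LOSO (the study cohort size), 14 subjects for the
model-recovery confusion, 3–4 optimiser restarts, and 600–1,000
permutations. All sizes are plain function arguments; nothing is gated
on environment variables or markers.
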