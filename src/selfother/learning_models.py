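"""The Self-Other leak family of Rescorla-Wagner learning models.

Two beliefs are tracked in parallel: the subject's own belief about a
drifting Bernoulli parameter and a simulation of another agent's
(false) belief.  Each belief B updates as

    B_{t+1} = B_t + alpha * PE_own + delta * (0.5 - B_t) + lambda * PE_other_agent

where PE_own is the agent's own prediction error (zeroed on trials
carrying no information for that agent), delta decays beliefs towards
chance, and lambda leaks the *other* agent's prediction error into the
update — the model's operationalisation of Self-Other mergence.
Beliefs are clipped to [0, 1] after the full update.

The model family crosses four parameter-sharing structures for the
learning rate alpha (single / by agent / by trial class / by both), two
for the response temperature tau, and 0/1/2 memory-decay (delta) and
leak (lambda) parameters: 4 x 2 x 3 x 3 = 72 variants.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .fbt_design import DECOY, PRIVILEGED, SHARED, Trial, TrialSequence

__all__ = [
    "ParamSet",
    "ModelSpec",
    "BeliefState",
    "enumerate_model_space",
    "compute_pes",
    "update_beliefs",
    "run_trajectory",
    "self_other_correlation",
    "leak_ratio",
]

AGENTS = ("self", "other")
TRIAL_CLASSES = ("nonshared", "shared")

ALPHA_STRUCTURES = ("single", "by_agent", "by_trial_class", "by_both")
TAU_STRUCTURES = ("single", "by_agent")

_ALPHA_NAMES = {
    "single": ("alpha",),
    "by_agent": ("alpha_self", "alpha_other"),
    "by_trial_class": ("alpha_nonshared", "alpha_shared"),
    "by_both": ("alpha_self_nonshared", "alpha_self_shared",
                "alpha_other_nonshared", "alpha_other_shared"),
}
_TAU_NAMES = {"single": ("tau",), "by_agent": ("tau_self", "tau_other")}


@dataclass(frozen=True)
class ModelSpec:
    """One variant of the learning-model family: its parameter-sharing
    structure and a stable id label."""

    alpha_structure: str
    tau_structure: str
    n_delta: int
    n_lambda: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.alpha_structure not in ALPHA_STRUCTURES:
            raise ValueError(f"bad alpha_structure {self.alpha_structure!r}")
        if self.tau_structure not in TAU_STRUCTURES:
            raise ValueError(f"bad tau_structure {self.tau_structure!r}")
        if self.n_delta not in (0, 1, 2) or self.n_lambda not in (0, 1, 2):
            raise ValueError("n_delta and n_lambda must be 0, 1 or 2")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = list(_ALPHA_NAMES[self.alpha_structure])
        names += list(_TAU_NAMES[self.tau_structure])
        if self.n_delta == 1:
            names += ["delta"]
        elif self.n_delta == 2:
            names += ["delta_self", "delta_other"]
        if self.n_lambda == 1:
            names += ["lambda"]
        elif self.n_lambda == 2:
            names += ["lambda_self", "lambda_other"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def has_lambda(self) -> bool:
        return self.n_lambda > 0

    def to_json(self) -> str:
        return json.dumps({
            "id": self.id, "alpha_structure": self.alpha_structure,
            "tau_structure": self.tau_structure,
            "n_delta": self.n_delta, "n_lambda": self.n_lambda})

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        return cls(**d)


@dataclass(frozen=True)
class ParamSet:
    """Fully resolved parameters for one agent pair.

    ``alpha`` is keyed by (agent, trial class); ``tau`` by agent;
    ``delta`` and ``lam`` by agent (0.0 when the owning spec has no
    such parameter).
    """

    alpha: dict
    tau: dict
    delta: dict = field(default_factory=lambda: {"self": 0.0, "other": 0.0})
    lam: dict = field(default_factory=lambda: {"self": 0.0, "other": 0.0})

    @classmethod
    def from_values(cls, spec: ModelSpec, values: dict) -> "ParamSet":
        """Expand a dict of the spec's free parameters into resolved form."""
        missing = set(spec.param_names) - set(values)
        if missing:
            raise ValueError(f"missing parameters {sorted(missing)}")
        v = values
        st = spec.alpha_structure
        if st == "single":
            alpha = {(a, c): v["alpha"] for a in AGENTS for c in TRIAL_CLASSES}
        elif st == "by_agent":
            alpha = {(a, c): v[f"alpha_{a}"] for a in AGENTS for c in TRIAL_CLASSES}
        elif st == "by_trial_class":
            alpha = {(a, c): v[f"alpha_{c}"] for a in AGENTS for c in TRIAL_CLASSES}
        else:
            alpha = {(a, c): v[f"alpha_{a}_{c}"] for a in AGENTS for c in TRIAL_CLASSES}
        if spec.tau_structure == "single":
            tau = {a: v["tau"] for a in AGENTS}
        else:
            tau = {a: v[f"tau_{a}"] for a in AGENTS}
        if spec.n_delta == 0:
            delta = {a: 0.0 for a in AGENTS}
        elif spec.n_delta == 1:
            delta = {a: v["delta"] for a in AGENTS}
        else:
            delta = {a: v[f"delta_{a}"] for a in AGENTS}
        if spec.n_lambda == 0:
            lam = {a: 0.0 for a in AGENTS}
        elif spec.n_lambda == 1:
            lam = {a: v["lambda"] for a in AGENTS}
        else:
            lam = {a: v[f"lambda_{a}"] for a in AGENTS}
        ps = cls(alpha=alpha, tau=tau, delta=delta, lam=lam)
        ps.validate()
        return ps

    def validate(self) -> None:
        for d, lo, hi, what in ((self.alpha, 0.0, 1.0, "alpha"),
                                (self.delta, 0.0, 1.0, "delta"),
                                (self.lam, 0.0, 1.0, "lambda")):
            for k, x in d.items():
                if not lo <= x <= hi:
                    raise ValueError(f"{what}[{k}]={x} outside [{lo}, {hi}]")
        for k, x in self.tau.items():
            if x <= 0:
                raise ValueError(f"tau[{k}]={x} must be positive")


@dataclass(frozen=True)
class BeliefState:
    """Beliefs and the prediction errors that produced them."""

    b_self: float = 0.5
    b_other: float = 0.5
    pe_self: float = 0.0
    pe_other: float = 0.0


def enumerate_model_space() -> list[ModelSpec]:
    """All 72 model variants in a stable order, labelled M1..M72.

    The grid is the Cartesian product of 4 alpha structures, 2 tau
    structures and {0, 1, 2} delta and lambda parameters, enumerated
    in that nesting order.
    """
    specs = []
    grid = itertools.product(ALPHA_STRUCTURES, TAU_STRUCTURES, (0, 1, 2), (0, 1, 2))
    for i, (a, t, nd, nl) in enumerate(grid, start=1):
        specs.append(ModelSpec(alpha_structure=a, tau_structure=t,
                               n_delta=nd, n_lambda=nl, id=f"M{i}"))
    return specs


def compute_pes(state: BeliefState, trial: Trial) -> tuple[float, float]:
    """Prediction errors for Self and Other on one trial.

    Self-attributed PEs are zero on decoy trials (the subject knows the
    sample is false); Other-attributed PEs are zero on privileged
    trials (the other agent never sees the sample).
    """
    pe_self = trial.outcome - state.b_self if trial.trial_type in (PRIVILEGED, SHARED) else 0.0
    pe_other = trial.outcome - state.b_other if trial.trial_type in (DECOY, SHARED) else 0.0
    return pe_self, pe_other


def update_beliefs(state: BeliefState, trial: Trial, params: ParamSet,
                   spec: ModelSpec | None = None) -> BeliefState:
    """One parallel belief update for Self and Other, clipped to [0, 1]."""
    pe_s, pe_o = compute_pes(state, trial)
    cls = "shared" if trial.trial_type == SHARED else "nonshared"
    b_s = (state.b_self
           + params.alpha[("self", cls)] * pe_s
           + params.delta["self"] * (0.5 - state.b_self)
           + params.lam["self"] * pe_o)
    b_o = (state.b_other
           + params.alpha[("other", cls)] * pe_o
           + params.delta["other"] * (0.5 - state.b_other)
           + params.lam["other"] * pe_s)
    return BeliefState(b_self=min(1.0, max(0.0, b_s)),
                       b_other=min(1.0, max(0.0, b_o)),
                       pe_self=pe_s, pe_other=pe_o)


def run_trajectory(sequence: TrialSequence, params: ParamSet,
                   spec: ModelSpec | None = None,
                   initial_belief: float = 0.5) -> list[BeliefState]:
    """Belief states after each sampling trial, starting from 0.5/0.5."""
    state = BeliefState(b_self=initial_belief, b_other=initial_belief)
    out = []
    for trial in sequence.trials:
        state = update_beliefs(state, trial, params, spec)
        out.append(state)
    return out


def _trajectory_arrays(sequence: TrialSequence, params: ParamSet,
                       initial_belief: float = 0.5
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: (b_self, b_other) arrays over the sequence.

    Scalar-arithmetic recurrence equivalent to :func:`run_trajectory`;
    used inside likelihood evaluation where list-of-dataclass overhead
    matters.
    """
    a_sn = params.alpha[("self", "nonshared")]
    a_ss = params.alpha[("self", "shared")]
    a_on = params.alpha[("other", "nonshared")]
    a_os = params.alpha[("other", "shared")]
    d_s, d_o = params.delta["self"], params.delta["other"]
    l_s, l_o = params.lam["self"], params.lam["other"]
    b_s = b_o = initial_belief
    n = len(sequence)
    bs = np.empty(n)
    bo = np.empty(n)
    for t, trial in enumerate(sequence.trials):
        ttype = trial.trial_type
        out = trial.outcome
        if ttype == SHARED:
            pe_s = out - b_s
            pe_o = out - b_o
            a_s, a_o = a_ss, a_os
        elif ttype == PRIVILEGED:
            pe_s = out - b_s
            pe_o = 0.0
            a_s, a_o = a_sn, a_on
        else:
            pe_s = 0.0
            pe_o = out - b_o
            a_s, a_o = a_sn, a_on
        b_s = b_s + a_s * pe_s + d_s * (0.5 - b_s) + l_s * pe_o
        b_o = b_o + a_o * pe_o + d_o * (0.5 - b_o) + l_o * pe_s
        if b_s < 0.0:
            b_s = 0.0
        elif b_s > 1.0:
            b_s = 1.0
        if b_o < 0.0:
            b_o = 0.0
        elif b_o > 1.0:
            b_o = 1.0
        bs[t] = b_s
        bo[t] = b_o
    return bs, bo


def self_other_correlation(trajectory: list[BeliefState],
                           n_bins: int = 1) -> np.ndarray:
    """Pearson r between Self and Other beliefs within contiguous bins.

    A bin with zero variance in either belief yields NaN (flagged as
    undefined rather than silently zero).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(trajectory) < 2 * n_bins:
        raise ValueError("trajectory too short for the requested bins")
    bs = np.array([s.b_self for s in trajectory])
    bo = np.array([s.b_other for s in trajectory])
    out = np.empty(n_bins)
    for i, (xs, ys) in enumerate(zip(np.array_split(bs, n_bins),
                                     np.array_split(bo, n_bins))):
        if np.std(xs) == 0 or np.std(ys) == 0:
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(xs, ys)[0, 1]
    return out


def leak_ratio(params: ParamSet, spec: ModelSpec) -> dict:
    """lambda:alpha ratio per agent and their mean.

    When alpha is split by trial class the agent's alpha is averaged
    over classes before forming the ratio.
    """
    if spec.n_lambda == 0:
        raise ValueError("model has no leak parameter")
    ratios = {}
    for agent in AGENTS:
        a_bar = np.mean([params.alpha[(agent, c)] for c in TRIAL_CLASSES])
        ratios[agent] = params.lam[agent] / a_bar
    ratios["mean"] = float(np.mean([ratios[a] for a in AGENTS]))
    return ratios
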