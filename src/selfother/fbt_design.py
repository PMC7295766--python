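"""Trial-sequence generation for the probabilistic false belief task (FBT).

A subject tracks a drifting Bernoulli parameter while simultaneously
simulating another agent's (false) estimate of it.  Sequences are built
from two bounded-reflected random walks (one feeding the subject's
"privileged" samples, one feeding the other agent's misleading "decoy"
samples), a trial-type schedule fixed by the social context, Bernoulli
outcomes, and intermittent Self/Other probes.  Candidate sequences are
screened so that a leak-free learner produces uncorrelated Self- and
Other-attributed belief/PE trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RandomWalk",
    "Trial",
    "TrialSequence",
    "SCHEDULE_COUNTS",
    "WALK_STEP",
    "generate_random_walk",
    "walks_uncorrelated",
    "build_schedule",
    "assign_outcomes",
    "insert_probes",
    "screen_sequence",
    "generate_sequence",
    "sequence_to_csv",
    "sequence_from_csv",
]

# Trial-type labels
PRIVILEGED = "privileged"
SHARED = "shared"
DECOY = "decoy"
TRIAL_TYPES = (PRIVILEGED, SHARED, DECOY)

#: Step magnitude of the bounded random walks housing the Bernoulli parameter.
WALK_STEP = 0.025

#: Exact trial-type counts for each (context, session) pair.
SCHEDULE_COUNTS: dict[tuple[str, str], dict[str, int]] = {
    ("hi_share", "train"): {PRIVILEGED: 112, DECOY: 112, SHARED: 224},
    ("lo_share", "train"): {PRIVILEGED: 196, DECOY: 196, SHARED: 56},
    ("hi_share", "test"): {PRIVILEGED: 148, DECOY: 148, SHARED: 148},
    ("lo_share", "test"): {PRIVILEGED: 148, DECOY: 148, SHARED: 148},
}

#: Inclusive bounds on the number of sampling trials between consecutive probes.
PROBE_GAP = (4, 9)

#: |Pearson r| threshold below which two trajectories count as uncorrelated.
UNCORRELATED_THRESHOLD = 0.1

#: Learning rate of the leak-free screening learner.
SCREEN_LEARNING_RATE = 0.1


@dataclass(frozen=True)
class RandomWalk:
    """A probability random walk reflected at the boundaries 0 and 1."""

    values: np.ndarray
    step: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Trial:
    """One sampling trial, optionally followed by a probe event."""

    index: int
    trial_type: str
    outcome: int
    is_probe: bool = False
    probe_agent: str = "none"

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")
        if self.is_probe != (self.probe_agent in ("self", "other")):
            raise ValueError("probe_agent must be self/other iff is_probe")


@dataclass
class TrialSequence:
    """An ordered FBT trial sequence with its generating walks."""

    trials: list[Trial]
    walk_self: RandomWalk
    walk_decoy: RandomWalk
    context: str = "hi_share"
    session: str = "train"

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def trial_types(self) -> np.ndarray:
        return np.array([t.trial_type for t in self.trials])

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials], dtype=float)

    @property
    def probe_agents(self) -> np.ndarray:
        return np.array([t.probe_agent for t in self.trials])

    def n_probes(self) -> int:
        return int(sum(t.is_probe for t in self.trials))


def generate_random_walk(n_trials: int, step: float = WALK_STEP,
                         seed: int | np.random.Generator | None = None,
                         start: float | None = None) -> RandomWalk:
    """Generate a reflected random walk on [0, 1].

    Each step moves the value up or down by ``step`` with equal
    probability; a step that would exit [0, 1] is mirror-reflected
    (x -> -x at 0, x -> 2 - x at 1).  ``start`` defaults to a uniform
    draw in [0.2, 0.8], away from immediate boundary reflection.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < step < 0.5:
        raise ValueError("step must lie in (0, 0.5)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if start is None:
        start = rng.uniform(0.2, 0.8)
    if not 0.0 <= start <= 1.0:
        raise ValueError("start must lie in [0, 1]")
    values = np.empty(n_trials)
    values[0] = start
    if n_trials > 1:
        directions = rng.choice([-1.0, 1.0], size=n_trials - 1)
        x = start
        for t, d in enumerate(directions, start=1):
            x = x + d * step
            if x < 0.0:
                x = -x
            elif x > 1.0:
                x = 2.0 - x
            values[t] = x
    return RandomWalk(values=values, step=step)


def walks_uncorrelated(walk_a: RandomWalk, walk_b: RandomWalk,
                       threshold: float = UNCORRELATED_THRESHOLD) -> bool:
    """True iff |Pearson r| between the two walks is below ``threshold``."""
    a, b = np.asarray(walk_a.values), np.asarray(walk_b.values)
    if len(a) != len(b):
        raise ValueError("walks must have equal length")
    if len(a) < 3:
        raise ValueError("walks must have length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant walk")
    r = np.corrcoef(a, b)[0, 1]
    return bool(abs(r) < threshold)


def build_schedule(context: str, session: str,
                   seed: int | np.random.Generator | None = None) -> list[str]:
    """A seeded random permutation of the exact trial-type counts for
    the given (context, session) pair."""
    key = (context, session)
    if key not in SCHEDULE_COUNTS:
        raise ValueError(f"unknown context/session pair {key!r}")
    counts = SCHEDULE_COUNTS[key]
    labels = np.array([t for t, n in counts.items() for _ in range(n)])
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rng.shuffle(labels)
    return list(labels)


def assign_outcomes(schedule: Sequence[str], walk_self: RandomWalk,
                    walk_decoy: RandomWalk,
                    seed: int | np.random.Generator | None = None,
                    context: str = "hi_share",
                    session: str = "train") -> TrialSequence:
    """Draw Bernoulli outcomes for a schedule.

    Privileged outcomes come from the subject's walk, decoy outcomes
    from the decoy walk, and shared outcomes from an unbiased coin.
    """
    n = len(schedule)
    if len(walk_self) < n or len(walk_decoy) < n:
        raise ValueError("walks shorter than the schedule")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    trials = []
    for t, ttype in enumerate(schedule):
        if ttype == PRIVILEGED:
            p = walk_self.values[t]
        elif ttype == DECOY:
            p = walk_decoy.values[t]
        elif ttype == SHARED:
            p = 0.5
        else:
            raise ValueError(f"unknown trial type {ttype!r}")
        trials.append(Trial(index=t, trial_type=ttype, outcome=int(u[t] < p)))
    return TrialSequence(trials=trials, walk_self=walk_self,
                         walk_decoy=walk_decoy, context=context, session=session)


def insert_probes(sequence: TrialSequence,
                  seed: int | np.random.Generator | None = None) -> TrialSequence:
    """Attach Self/Other probes after every 4-9 sampling trials.

    Inter-probe gaps are drawn uniformly from {4, ..., 9}; probe agents
    are balanced (equal Self and Other counts, +-1 when odd) in random
    order.  Probes are separate report events following the flagged
    sampling trial; the flagged trial's stimulus is unchanged.
    """
    n = len(sequence)
    if n < 10:
        raise ValueError("sequence must have >= 10 trials")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = PROBE_GAP
    positions = []
    pos = -1
    while True:
        pos += int(rng.integers(lo, hi + 1))
        if pos >= n:
            break
        positions.append(pos)
    n_probes = len(positions)
    agents = np.array(["self", "other"] * (n_probes // 2 + 1))[:n_probes]
    rng.shuffle(agents)
    probe_at = dict(zip(positions, agents))
    trials = [
        Trial(index=t.index, trial_type=t.trial_type, outcome=t.outcome,
              is_probe=t.index in probe_at,
              probe_agent=probe_at.get(t.index, "none"))
        for t in sequence.trials
    ]
    return TrialSequence(trials=trials, walk_self=sequence.walk_self,
                         walk_decoy=sequence.walk_decoy,
                         context=sequence.context, session=sequence.session)


def _screen_trajectories(sequence: TrialSequence,
                         learning_rate: float) -> dict[str, np.ndarray]:
    """Self/Other beliefs and |PE|s of the leak-free screening learner."""
    b_s = b_o = 0.5
    bs, bo, ps, po = [], [], [], []
    for t in sequence.trials:
        pe_s = t.outcome - b_s if t.trial_type in (PRIVILEGED, SHARED) else 0.0
        pe_o = t.outcome - b_o if t.trial_type in (DECOY, SHARED) else 0.0
        b_s = min(1.0, max(0.0, b_s + learning_rate * pe_s))
        b_o = min(1.0, max(0.0, b_o + learning_rate * pe_o))
        bs.append(b_s)
        bo.append(b_o)
        ps.append(abs(pe_s))
        po.append(abs(pe_o))
    return {"b_self": np.array(bs), "b_other": np.array(bo),
            "pe_self": np.array(ps), "pe_other": np.array(po)}


def screen_sequence(sequence: TrialSequence,
                    learning_rate: float = SCREEN_LEARNING_RATE,
                    threshold: float = UNCORRELATED_THRESHOLD) -> bool:
    """Accept a sequence iff a leak-free learner (no decay, no leak,
    the given learning rate) yields cross-agent decorrelation between
    beliefs and PE magnitudes: |r(b_self, |PE_other|)| and
    |r(b_other, |PE_self|)| both below the threshold.

    The belief-belief and |PE|-|PE| pairs are deliberately not
    screened: shared outcomes drive both agents' beliefs together (the
    mergence pressure the manipulation creates) and the PE magnitudes
    have disjoint structural zeros, so those correlations are
    properties of the trial-type proportions, not of a particular
    sequence draw.
    """
    tr = _screen_trajectories(sequence, learning_rate)
    pairs = [("b_self", "pe_other"), ("b_other", "pe_self")]
    for x, y in pairs:
        a, b = tr[x], tr[y]
        if np.std(a) == 0 or np.std(b) == 0:
            return False
        if abs(np.corrcoef(a, b)[0, 1]) >= threshold:
            return False
    return True


def generate_sequence(context: str, session: str, seed: int,
                      max_attempts: int = 1000,
                      with_probes: bool = True) -> TrialSequence:
    """Generate an accepted FBT trial sequence by rejection sampling.

    Repeats walk generation (requiring uncorrelated walks), outcome
    assignment and screening with fresh seeded streams until
    :func:`screen_sequence` accepts, up to ``max_attempts``.
    """
    ss = np.random.SeedSequence(seed)
    for _ in range(max_attempts):
        rng = np.random.default_rng(ss.spawn(1)[0])
        schedule = build_schedule(context, session, rng)
        n = len(schedule)
        wa = generate_random_walk(n, seed=rng)
        wb = generate_random_walk(n, seed=rng)
        try:
            if not walks_uncorrelated(wa, wb):
                continue
        except ValueError:
            continue
        seq = assign_outcomes(schedule, wa, wb, rng, context=context, session=session)
        if not screen_sequence(seq):
            continue
        if with_probes:
            seq = insert_probes(seq, rng)
        return seq
    raise RuntimeError(
        f"no acceptable sequence in {max_attempts} attempts for "
        f"({context}, {session}); consider relaxing the screen threshold")


def sequence_to_frame(sequence: TrialSequence) -> pd.DataFrame:
    n = len(sequence)
    return pd.DataFrame({
        "index": [t.index for t in sequence.trials],
        "trial_type": [t.trial_type for t in sequence.trials],
        "outcome": [t.outcome for t in sequence.trials],
        "is_probe": [int(t.is_probe) for t in sequence.trials],
        "probe_agent": [t.probe_agent for t in sequence.trials],
        "p_self": sequence.walk_self.values[:n],
        "p_decoy": sequence.walk_decoy.values[:n],
    })


def sequence_to_csv(sequence: TrialSequence, path) -> None:
    """Serialise a TrialSequence to CSV (UTF-8, one header line)."""
    sequence_to_frame(sequence).to_csv(path, index=False)


def sequence_from_csv(path, context: str = "hi_share",
                      session: str = "train",
                      step: float = WALK_STEP) -> TrialSequence:
    """Load a TrialSequence written by :func:`sequence_to_csv`."""
    df = pd.read_csv(path)
    trials = [
        Trial(index=int(r.index), trial_type=str(r.trial_type),
              outcome=int(r.outcome), is_probe=bool(r.is_probe),
              probe_agent=str(r.probe_agent))
        for r in df.itertuples(index=False)
    ]
    return TrialSequence(
        trials=trials,
        walk_self=RandomWalk(df["p_self"].to_numpy(), step),
        walk_decoy=RandomWalk(df["p_decoy"].to_numpy(), step),
        context=context, session=session)
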