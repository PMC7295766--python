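"""Visual perspective-taking transfer task: design and DDM simulation.

The task crosses perspective (Self/Other) x congruency x correct
response (yes/no) x avatar (lo_share / hi_share / arrow) x avatar gaze
(left/right) into a balanced 2 x 2 x 2 x 3 x 2 design (48 cells; 8
repeats per cell gives the full 384-trial task).  Response time and
accuracy are generated by a forward drift-diffusion simulation whose
drift rate is drawn per trial from one of twelve Gaussian
distributions, one per avatar x perspective x congruency cell, with a
shared drift variance; non-decision time, start point and boundary
separation are drawn from subject-level Gaussians.  Training effects
are quantified as drift-rate change scores corrected by the change on
arrow trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PTTrial", "DDMParams", "build_pt_design", "simulate_ddm_trial",
           "simulate_dataset", "corrected_change", "RT_BOUNDS_MS"]

PERSPECTIVES = ("self", "other")
CONDITIONS = ("congruent", "incongruent")
RESPONSES = ("yes", "no")
AVATARS = ("lo_share", "hi_share", "arrow")
GAZES = ("left", "right")

#: Valid response-time window in ms; responses outside are flagged excluded.
RT_BOUNDS_MS = (500.0, 3000.0)

#: Euler-Maruyama step, seconds (0.5 ms); diffusion coefficient fixed at 1.
DEFAULT_DT = 0.0005
MAX_DECISION_TIME = 10.0


@dataclass(frozen=True)
class PTTrial:
    perspective: str
    condition: str
    correct_response: str
    avatar: str
    gaze: str


def _default_drift_means() -> dict:
    # congruent scenes are processed faster than incongruent ones
    return {(a, p, c): (2.0 if c == "congruent" else 1.4)
            for a in AVATARS for p in PERSPECTIVES for c in CONDITIONS}


@dataclass
class DDMParams:
    """Subject-level diffusion parameters.

    ``drift_means`` is keyed by (avatar, perspective, condition) — the
    twelve per-cell mean drift rates; ``drift_var`` is the shared
    between-trial drift variance.  Start point is a fraction of the
    boundary separation.  Times are in seconds.
    """

    drift_means: dict = field(default_factory=_default_drift_means)
    drift_var: float = 0.3
    ndt_mean: float = 0.45
    ndt_var: float = 0.001
    start_mean: float = 0.5
    start_var: float = 0.002
    boundary_mean: float = 1.8
    boundary_var: float = 0.01

    def __post_init__(self) -> None:
        if self.boundary_mean <= 0:
            raise ValueError("boundary separation must be positive")
        if self.ndt_mean < 0:
            raise ValueError("non-decision time must be non-negative")
        for name in ("drift_var", "ndt_var", "start_var", "boundary_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.drift_means) != 12:
            raise ValueError("expected 12 drift-rate cells "
                             "(avatar x perspective x condition)")


def build_pt_design(repeats_per_cell: int = 8,
                    seed: int | np.random.Generator | None = None
                    ) -> list[PTTrial]:
    """Balanced, shuffled trial list: every design cell exactly
    ``repeats_per_cell`` times (default 8 -> 384 trials)."""
    if repeats_per_cell < 1:
        raise ValueError("repeats_per_cell must be >= 1")
    cells = list(itertools.product(PERSPECTIVES, CONDITIONS, RESPONSES,
                                   AVATARS, GAZES))
    trials = [PTTrial(p, c, r, a, g)
              for (p, c, r, a, g) in cells for _ in range(repeats_per_cell)]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def simulate_ddm_trial(params: DDMParams, trial: PTTrial,
                       dt: float = DEFAULT_DT,
                       seed: int | np.random.Generator | None = None):
    """Forward-simulate one trial; returns (response, rt_ms, excluded).

    The diffusion starts at start_fraction x boundary and runs between
    absorbing boundaries at 0 and the boundary separation with unit
    diffusion coefficient; crossing the upper boundary produces a
    correct response.  RT adds the non-decision time.  ``excluded``
    flags RTs outside [500, 3000] ms; no crossing within 10 s is
    reported as (None, nan, True) (censored).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v = rng.normal(params.drift_means[(trial.avatar, trial.perspective,
                                       trial.condition)],
                   np.sqrt(params.drift_var))
    a = max(rng.normal(params.boundary_mean, np.sqrt(params.boundary_var)), 0.1)
    zfrac = np.clip(rng.normal(params.start_mean, np.sqrt(params.start_var)),
                    0.05, 0.95)
    ndt = max(rng.normal(params.ndt_mean, np.sqrt(params.ndt_var)), 0.0)
    x = zfrac * a
    sqdt = np.sqrt(dt)
    n_max = int(MAX_DECISION_TIME / dt)
    block = 2000
    t_steps = 0
    while t_steps < n_max:
        m = min(block, n_max - t_steps)
        path = x + np.cumsum(v * dt + sqdt * rng.standard_normal(m))
        hit = (path >= a) | (path <= 0.0)
        if hit.any():
            i = int(np.argmax(hit))
            correct = path[i] >= a
            rt_ms = ((t_steps + i + 1) * dt + ndt) * 1000.0
            if correct:
                response = trial.correct_response
            else:
                response = "no" if trial.correct_response == "yes" else "yes"
            excluded = not (RT_BOUNDS_MS[0] <= rt_ms <= RT_BOUNDS_MS[1])
            return response, float(rt_ms), excluded
        x = path[-1]
        t_steps += m
    return None, float("nan"), True


def simulate_dataset(params: DDMParams, design: list[PTTrial],
                     dt: float = DEFAULT_DT, seed: int = 0) -> pd.DataFrame:
    """Simulate a full session; one row per trial.

    Columns: perspective, condition, avatar, gaze, response, RT_ms,
    excluded, correct.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trial in design:
        response, rt, excl = simulate_ddm_trial(params, trial, dt=dt, seed=rng)
        rows.append({"perspective": trial.perspective,
                     "condition": trial.condition,
                     "avatar": trial.avatar, "gaze": trial.gaze,
                     "response": response, "RT_ms": rt,
                     "excluded": excl,
                     "correct": response == trial.correct_response})
    return pd.DataFrame(rows)


def corrected_change(v_baseline: float, v_transfer: float,
                     arrow_baseline: float, arrow_transfer: float) -> float:
    """Drift-rate change from baseline to transfer, with the change on
    arrow trials (non-specific repeat effects) subtracted out."""
    return (v_transfer - v_baseline) - (arrow_transfer - arrow_baseline)
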