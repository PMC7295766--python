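"""Rescorla-Wagner tracker of the probability of a 'shared' trial.

The perceived probability P of encountering a shared trial updates as
P_{t+1} = P_t + eta (S - P_t), where S is 1 on shared trials and 0 on
privileged and decoy trials.  The trace and its prediction-error
magnitude |S - P_t| serve as model-based regressors (e.g. design-matrix
columns for a GLM); they are optionally z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fbt_design import SHARED, TrialSequence

__all__ = ["ShareTrace", "ETA_GRID", "DEFAULT_P0", "update_pshare",
           "trace_sequence", "make_regressors"]

#: Learning rates at which the regressors are generated.
ETA_GRID = (0.01, 0.025, 0.05, 0.075, 0.1)

#: Initial P(share): the true shared-trial rates experienced in training.
DEFAULT_P0 = {"lo_share": 0.125, "hi_share": 0.5}


@dataclass
class ShareTrace:
    p: np.ndarray          # P(share) before seeing each trial's S
    pe_mag: np.ndarray     # |S - P_t| per trial
    eta: float
    p0: float


def update_pshare(p: float, shared: int, eta: float) -> float:
    """One delta-rule step of P(share) towards the share indicator."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    return p + eta * (shared - p)


def trace_sequence(sequence: TrialSequence, eta: float,
                   p0: float | None = None) -> ShareTrace:
    """Full P(share) trace over a trial sequence.

    ``p0`` defaults to the training-session shared-trial rate of the
    sequence's context (0.125 for lo_share, 0.5 for hi_share).
    """
    if p0 is None:
        p0 = DEFAULT_P0[sequence.context]
    s = (sequence.trial_types == SHARED).astype(float)
    n = len(s)
    p = np.empty(n)
    pe = np.empty(n)
    x = float(p0)
    for t in range(n):
        p[t] = x
        pe[t] = abs(s[t] - x)
        x = update_pshare(x, s[t], eta)
    return ShareTrace(p=p, pe_mag=pe, eta=eta, p0=float(p0))


def make_regressors(trace: ShareTrace, zscore: bool = True) -> pd.DataFrame:
    """Regressor table with columns P and PE_mag, optionally z-scored."""
    if len(trace.p) < 2:
        raise ValueError("trace must have length >= 2")
    p, pe = trace.p.copy(), trace.pe_mag.copy()
    if zscore:
        for name, col in (("P", p), ("PE_mag", pe)):
            sd = col.std(ddof=0)
            if sd == 0:
                raise ValueError(f"zero variance in regressor {name}")
            col -= col.mean()
            col /= sd
    return pd.DataFrame({"trial": np.arange(len(p)), "P": p, "PE_mag": pe})
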