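"""Parameter- and model-recovery suites.

Parameter recovery simulates responses from each subject's fitted (or
ground-truth) parameters, refits the model, and reports the
between-subjects Spearman rank correlation per parameter.  Model
recovery simulates from each candidate model, fits all candidates to
every simulated dataset, tabulates best-fitting (lowest BIC) winners
into p(fit|sim), and inverts it by Bayes' rule with a uniform model
prior into p(sim|fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .fbt_design import TrialSequence
from .learning_models import ModelSpec, ParamSet
from .model_fitting import FitResult, fit_subject

__all__ = ["RecoveryMatrix", "parameter_recovery", "model_recovery",
           "posterior_sim_given_fit"]


@dataclass
class RecoveryMatrix:
    """Model-recovery confusion matrices (rows: simulating model;
    columns: best-fitting model)."""

    p_fit_given_sim: np.ndarray
    p_sim_given_fit: np.ndarray
    model_ids: list[str]

    def to_frame(self, which: str = "p_sim_given_fit") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.model_ids, columns=self.model_ids)


def _simulate_reports(params: ParamSet, sequence: TrialSequence,
                      rng: np.random.Generator) -> np.ndarray:
    # local import to avoid a module cycle with synthetic_cohort
    from .synthetic_cohort import simulate_fbt_responses
    return simulate_fbt_responses(params, sequence, rng)


def parameter_recovery(spec: ModelSpec, subject_values: list[dict],
                       sequences: list[TrialSequence], seed: int,
                       n_restarts: int = 5) -> dict[str, float]:
    """Spearman rho between generating and recovered parameter values.

    ``subject_values`` holds each subject's free-parameter dict for
    ``spec``; ``sequences`` the corresponding trial sequences (recycled
    if fewer than subjects).  A constant generating vector makes rho
    undefined and is reported as NaN.
    """
    n = len(subject_values)
    if n < 5:
        raise ValueError("need >= 5 subjects for rank correlations")
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(n)]
    recovered = []
    for i, values in enumerate(subject_values):
        seq = sequences[i % len(sequences)]
        params = ParamSet.from_values(spec, values)
        reports = _simulate_reports(params, seq, rngs[i])
        fit = fit_subject(seq, reports, spec, n_restarts=n_restarts,
                          seed=int(ss.generate_state(1)[0] % (2**31)) + i)
        recovered.append(fit.values)
    out = {}
    for name in spec.param_names:
        true = np.array([v[name] for v in subject_values])
        rec = np.array([v[name] for v in recovered])
        if np.all(true == true[0]) or np.all(rec == rec[0]):
            out[name] = float("nan")
        else:
            out[name] = float(spearmanr(true, rec).statistic)
    return out


def model_recovery(specs: list[ModelSpec], subject_values: list[list[dict]],
                   sequences: list[TrialSequence], seed: int,
                   n_restarts: int = 5,
                   max_nonconverged_frac: float = 0.2) -> RecoveryMatrix:
    """Confusion analysis across candidate model variants.

    ``subject_values[j][i]`` gives subject i's parameters under
    simulating spec j.  For each simulating spec, responses are
    generated per subject, every candidate spec is fit, and the
    proportion of subjects for which each candidate has the lowest BIC
    forms one row of p(fit|sim).
    """
    if len(specs) < 2:
        raise ValueError("need >= 2 model specs")
    k = len(specs)
    n = len(subject_values[0])
    ss = np.random.SeedSequence(seed)
    counts = np.zeros((k, k))
    n_fits = n_bad = 0
    for j, sim_spec in enumerate(specs):
        for i in range(n):
            seq = sequences[i % len(sequences)]
            params = ParamSet.from_values(sim_spec, subject_values[j][i])
            rng = np.random.default_rng(ss.spawn(1)[0])
            reports = _simulate_reports(params, seq, rng)
            bics = []
            for fit_spec in specs:
                fit = fit_subject(seq, reports, fit_spec,
                                  n_restarts=n_restarts,
                                  seed=int(ss.generate_state(1)[0] % (2**31)))
                n_fits += 1
                n_bad += not fit.converged
                bics.append(fit.bic)
            counts[j, np.argmin(bics)] += 1
    if n_bad > max_nonconverged_frac * n_fits:
        raise RuntimeError(
            f"{n_bad}/{n_fits} fits failed to converge (> "
            f"{max_nonconverged_frac:.0%})")
    p_fit_given_sim = counts / counts.sum(axis=1, keepdims=True)
    p_sim_given_fit = posterior_sim_given_fit(p_fit_given_sim)
    return RecoveryMatrix(p_fit_given_sim=p_fit_given_sim,
                          p_sim_given_fit=p_sim_given_fit,
                          model_ids=[s.id for s in specs])


def posterior_sim_given_fit(p_fit_given_sim: np.ndarray,
                            prior: np.ndarray | None = None) -> np.ndarray:
    """Bayes inversion of p(fit|sim) into p(sim|fit).

    p(sim|fit) = p(fit|sim) p(sim) / sum_sim p(fit|sim) p(sim); the
    default prior over simulating models is uniform.  A column with
    zero mass (a model never winning) yields NaN in that column.
    """
    p = np.asarray(p_fit_given_sim, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("p_fit_given_sim must be square")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of p_fit_given_sim must sum to 1")
    k = p.shape[0]
    if prior is None:
        prior = np.full(k, 1.0 / k)
    prior = np.asarray(prior, dtype=float)
    if not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must sum to 1")
    joint = p * prior[:, None]
    col_mass = joint.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = joint / col_mass[None, :]
    out[:, col_mass == 0] = np.nan
    return out
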