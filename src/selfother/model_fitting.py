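"""Maximum-likelihood fitting of the learning-model family.

Probe reports on the continuous probability scale are modelled with a
Beta distribution whose *mode* is the model-derived belief of the
probed agent and whose *variance* is that agent's temperature tau.
Subjects are fit independently by maximum likelihood (multi-restart
bounded quasi-Newton in a transformed unconstrained space) and models
are compared by the sum of per-subject BIC values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, expit, logit

from .fbt_design import TrialSequence
from .learning_models import ModelSpec, ParamSet, _trajectory_arrays

__all__ = [
    "FitResult",
    "TAU_MAX",
    "beta_shapes_from_mode_variance",
    "response_loglik",
    "negative_loglik",
    "fit_subject",
    "compare_models",
    "group_parameters_for_fmri",
]

#: Reports and beliefs are clipped to this open interval before Beta evaluation.
REPORT_CLIP = 1e-4

#: Supremum of the variance of a unimodal Beta (a, b > 1) is 1/12 (the
#: a = b = 1 limit), independent of the mode; tau is constrained below it.
VARIANCE_SUP = 1.0 / 12.0
TAU_MAX = 0.999 * VARIANCE_SUP
TAU_MIN = 1e-6

# Bounds (native space) for rate parameters during fitting.
RATE_MIN, RATE_MAX = 1e-4, 1.0 - 1e-4


def beta_shapes_from_mode_variance(mode, variance):
    """Shape parameters (a, b) of the Beta with the given mode and variance.

    With s = a + b, the mode constraint gives a = 1 + mode (s - 2) and
    b = 1 + (1 - mode)(s - 2); the variance a b / (s^2 (s + 1)) is then
    strictly decreasing in s, from 1/12 as s -> 2+ towards 0, so the
    system reduces to a monotone 1-D root find in s (bisection to
    relative tolerance < 1e-12).  Accepts scalars or arrays.

    Raises ValueError when the pair is infeasible (mode outside (0, 1)
    or variance >= 1/12, the unimodal-Beta variance bound).
    """
    m = np.asarray(mode, dtype=float)
    v = np.asarray(variance, dtype=float)
    scalar = m.ndim == 0 and v.ndim == 0
    m, v = np.atleast_1d(m), np.atleast_1d(v)
    m, v = np.broadcast_arrays(m, v)
    if np.any((m <= 0) | (m >= 1)):
        raise ValueError("mode must lie strictly inside (0, 1)")
    if np.any(v <= 0):
        raise ValueError("variance must be positive")
    if np.any(v >= VARIANCE_SUP):
        raise ValueError(
            f"variance must be below the unimodal-Beta bound 1/12 "
            f"(got max {v.max():.6g})")

    def var_of_s(s):
        a = 1.0 + m * (s - 2.0)
        b = 1.0 + (1.0 - m) * (s - 2.0)
        return a * b / (s * s * (s + 1.0))

    lo = np.full_like(v, 2.0 + 1e-12)
    # upper bracket: var ~ m(1-m)/s for large s, so s = m(1-m)/v + 3 overshoots
    hi = np.maximum(m * (1.0 - m) / v + 3.0, 4.0)
    grow = var_of_s(hi) > v
    while np.any(grow):  # pragma: no cover - bracket is analytic, loop is a safety net
        hi[grow] *= 2.0
        grow = var_of_s(hi) > v
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        high_side = var_of_s(mid) > v
        lo = np.where(high_side, mid, lo)
        hi = np.where(high_side, hi, mid)
    s = 0.5 * (lo + hi)
    a = 1.0 + m * (s - 2.0)
    b = 1.0 + (1.0 - m) * (s - 2.0)
    if scalar:
        return float(a[0]), float(b[0])
    return a, b


def response_loglik(report, belief, tau):
    """Log Beta density of a probe report given the model belief and tau.

    Report and belief are clipped to [1e-4, 1 - 1e-4] before evaluation.
    Accepts scalars or arrays (broadcast)."""
    x = np.clip(np.asarray(report, dtype=float), REPORT_CLIP, 1.0 - REPORT_CLIP)
    mu = np.clip(np.asarray(belief, dtype=float), REPORT_CLIP, 1.0 - REPORT_CLIP)
    a, b = beta_shapes_from_mode_variance(mu, tau)
    ll = (np.asarray(a) - 1.0) * np.log(x) + (np.asarray(b) - 1.0) * np.log1p(-x) \
        - betaln(a, b)
    return ll if np.ndim(ll) else float(ll)


@dataclass
class FitResult:
    """Per-subject maximum-likelihood fit of one model variant."""

    spec_id: str
    params: ParamSet
    values: dict
    nll: float
    n_probes: int
    bic: float
    converged: bool
    n_restarts_used: int = 0


def negative_loglik(values: dict, spec: ModelSpec, sequence: TrialSequence,
                    reports: np.ndarray) -> float:
    """Summed negative log-likelihood of the probe reports under the model."""
    params = ParamSet.from_values(spec, values)
    return _nll_resolved(params, sequence, reports,
                         *_probe_index_arrays(sequence))


def _probe_index_arrays(sequence: TrialSequence):
    """Probe trial indices (in trial order) and a Self-probe mask."""
    probe_idx = np.array([t.index for t in sequence.trials if t.is_probe],
                         dtype=int)
    is_self = np.array([t.probe_agent == "self" for t in sequence.trials
                        if t.is_probe], dtype=bool)
    return probe_idx, is_self


def _nll_resolved(params: ParamSet, sequence: TrialSequence,
                  reports: np.ndarray, probe_idx: np.ndarray,
                  is_self: np.ndarray) -> float:
    rep = np.asarray(reports, dtype=float)
    if len(rep) != len(probe_idx):
        raise ValueError("reports length does not match probe count")
    bs, bo = _trajectory_arrays(sequence, params)
    beliefs = np.where(is_self, bs[probe_idx], bo[probe_idx])
    taus = np.where(is_self, params.tau["self"], params.tau["other"])
    ll = response_loglik(rep, beliefs, np.clip(taus, TAU_MIN, TAU_MAX))
    return -float(np.sum(ll))


def _transform_to_native(z: np.ndarray, names: tuple[str, ...]) -> dict:
    """Unconstrained optimisation space -> native parameters.

    Rates (alpha, delta, lambda) map through a logistic onto
    (RATE_MIN, RATE_MAX); temperatures map onto (TAU_MIN, TAU_MAX).
    """
    out = {}
    for name, x in zip(names, z):
        p = expit(x)
        if name.startswith("tau"):
            out[name] = float(TAU_MIN + p * (TAU_MAX - TAU_MIN))
        else:
            out[name] = float(RATE_MIN + p * (RATE_MAX - RATE_MIN))
    return out


def _transform_from_native(values: dict, names: tuple[str, ...]) -> np.ndarray:
    z = []
    for name in names:
        x = values[name]
        if name.startswith("tau"):
            p = (x - TAU_MIN) / (TAU_MAX - TAU_MIN)
        else:
            p = (x - RATE_MIN) / (RATE_MAX - RATE_MIN)
        z.append(logit(np.clip(p, 1e-9, 1 - 1e-9)))
    return np.array(z)


def fit_subject(sequence: TrialSequence, reports: np.ndarray, spec: ModelSpec,
                n_restarts: int = 10, seed: int | None = None,
                tol: float = 1e-6, maxiter: int = 300) -> FitResult:
    """Fit one subject's probe reports to one model variant by MLE.

    Runs ``n_restarts`` L-BFGS-B optimisations from random starting
    points in the transformed (unconstrained) space plus one neutral
    start, keeping the best.  Deterministic given ``seed``.
    """
    names = spec.param_names
    k = len(names)
    reports = np.asarray(reports, dtype=float)
    probe_idx, is_self = _probe_index_arrays(sequence)
    n_probes = len(probe_idx)
    if n_probes < k:
        import warnings
        warnings.warn(f"fewer probes ({n_probes}) than free parameters ({k})",
                      stacklevel=2)

    def objective(z):
        values = _transform_to_native(z, names)
        try:
            params = ParamSet.from_values(spec, values)
            return _nll_resolved(params, sequence, reports, probe_idx, is_self)
        except (ValueError, FloatingPointError):
            return 1e10

    rng = np.random.default_rng(seed)
    neutral = _transform_from_native(
        {n: (0.01 if n.startswith("tau") else 0.15) for n in names}, names)
    starts = [neutral] + [rng.normal(0.0, 1.5, size=k) + neutral
                          for _ in range(max(0, n_restarts - 1))]
    best = None
    n_ok = 0
    for z0 in starts:
        res = minimize(objective, z0, method="L-BFGS-B",
                       options={"ftol": tol, "maxiter": maxiter})
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        return FitResult(spec_id=spec.id, params=None, values={},
                         nll=np.inf, n_probes=n_probes, bic=np.inf,
                         converged=False, n_restarts_used=len(starts))
    values = _transform_to_native(best.x, names)
    params = ParamSet.from_values(spec, values)
    nll = float(best.fun)
    bic = k * np.log(n_probes) + 2.0 * nll
    return FitResult(spec_id=spec.id, params=params, values=values, nll=nll,
                     n_probes=n_probes, bic=float(bic), converged=n_ok > 0,
                     n_restarts_used=len(starts))


def compare_models(fits: dict[str, list[FitResult]]):
    """Select the model with minimum summed BIC across subjects.

    ``fits`` maps spec id -> list of per-subject FitResults.  Returns
    (winning spec id, BIC table as a DataFrame with one row per model).
    Raises if any model is missing subjects present for another.
    """
    if not fits:
        raise ValueError("empty fit grid")
    n_subjects = {sid: len(v) for sid, v in fits.items()}
    if len(set(n_subjects.values())) > 1:
        raise ValueError(f"incomplete fit grid: subject counts {n_subjects}")
    rows = []
    for sid, results in fits.items():
        rows.append({"spec_id": sid,
                     "summed_bic": float(sum(r.bic for r in results)),
                     "summed_nll": float(sum(r.nll for r in results)),
                     "n_subjects": len(results)})
    table = pd.DataFrame(rows).sort_values("summed_bic").reset_index(drop=True)
    return str(table.loc[0, "spec_id"]), table


def group_parameters_for_fmri(fits_session_a: list[FitResult],
                              fits_session_b: list[FitResult],
                              spec: ModelSpec) -> dict:
    """Group-level parameters: per-subject session mean, then
    across-subject median, per free parameter."""
    if len(fits_session_a) != len(fits_session_b):
        raise ValueError("sessions have different subject counts")
    names = spec.param_names
    med = {}
    for name in names:
        session_means = [0.5 * (fa.values[name] + fb.values[name])
                         for fa, fb in zip(fits_session_a, fits_session_b)]
        med[name] = float(np.median(session_means))
    return med
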