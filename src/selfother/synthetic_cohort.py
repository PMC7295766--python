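"""Ground-truth synthetic subjects for all three tasks.

Each subject carries belief-learning parameters per social context
(Self-Other leak lambda present in the Hi-Share context and absent in
the Lo-Share context by default), hyperbolic-discounting parameters
(k, S, beta with k and S log-Gaussian across subjects), and diffusion
parameters for the perspective-taking task.  An optional coupling knob
plants a rank correlation between the behavioural leak factor
(lambda:alpha) and the aggregate discounting measure log(kS) via a
Gaussian copula, emulating the association between Self-Other mergence
and shallow discounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fbt_design import TrialSequence
from .learning_models import ModelSpec, ParamSet
from .model_fitting import TAU_MAX, beta_shapes_from_mode_variance, REPORT_CLIP
from .learning_models import _trajectory_arrays
from .model_fitting import _probe_index_arrays
from .discounting import choice_probability, discounted_value
from .transfer_task import DDMParams

__all__ = ["CohortConfig", "SyntheticSubject", "sample_cohort",
           "simulate_fbt_responses", "simulate_itc_choices"]


@dataclass
class CohortConfig:
    """Sampling ranges for ground-truth parameters.

    Learning parameters are uniform on the stated ranges; discounting
    parameters are Gaussian in log space.  ``coupling`` is the target
    Spearman correlation between lambda:alpha and log(kS) (0 disables
    the copula and draws lambda independently).
    """

    alpha_range: tuple = (0.05, 0.3)
    tau_range: tuple = (0.005, 0.05)
    delta_range: tuple = (0.0, 0.1)
    lambda_range: tuple = (0.02, 0.15)      # Hi-Share only
    leak_ratio_range: tuple = (0.1, 1.5)    # lambda:alpha when coupled
    log_k: tuple = (-3.5, 0.9)              # mean, sd
    log_s: tuple = (0.0, 0.35)
    log_beta: tuple = (0.7, 0.4)
    coupling: float = 0.0

    def validate(self) -> None:
        for name in ("alpha_range", "tau_range", "delta_range",
                     "lambda_range", "leak_ratio_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} lower bound exceeds upper")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [-1, 1]")
        if self.tau_range[1] >= TAU_MAX:
            raise ValueError("tau_range exceeds the feasible Beta variance")


@dataclass
class SyntheticSubject:
    """Ground-truth parameters for one simulated subject."""

    subject_id: int
    fbt_params: dict            # context -> free-parameter dict
    itc_params: dict            # k, S, beta (native space)
    ddm_params: DDMParams
    seeds: dict = field(default_factory=dict)

    @property
    def log_kS(self) -> float:
        return float(np.log(self.itc_params["k"] * self.itc_params["S"]))


def default_specs() -> dict[str, ModelSpec]:
    """Generating model variants: with leak in Hi-Share, without in
    Lo-Share (single alpha/tau, one decay; one leak where present)."""
    return {
        "hi_share": ModelSpec("single", "single", 1, 1, id="gen_leak"),
        "lo_share": ModelSpec("single", "single", 1, 0, id="gen_noleak"),
    }


def sample_cohort(n: int, config: CohortConfig | None = None,
                  seed: int = 0) -> list[SyntheticSubject]:
    """Draw ``n`` ground-truth subjects.

    With ``config.coupling`` nonzero, the lambda:alpha ratio and log k
    are drawn from a Gaussian copula whose latent Pearson correlation
    2 sin(pi rho / 6) targets Spearman rho = coupling between the leak
    factor and log(kS).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    subjects = []
    if config.coupling != 0.0:
        c = 2.0 * np.sin(np.pi * config.coupling / 6.0)
        cov = np.array([[1.0, c], [c, 1.0]])
        z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    for i in range(n):
        alpha = rng.uniform(*config.alpha_range)
        tau = rng.uniform(*config.tau_range)
        delta = rng.uniform(*config.delta_range)
        if config.coupling != 0.0:
            u_ratio, u_k = norm.cdf(z[i, 0]), z[i, 1]
            lo, hi = config.leak_ratio_range
            lam = float(np.clip((lo + (hi - lo) * u_ratio) * alpha, 1e-3, 0.5))
            log_k = config.log_k[0] + config.log_k[1] * u_k
        else:
            lam = rng.uniform(*config.lambda_range)
            log_k = rng.normal(*config.log_k)
        log_s = rng.normal(*config.log_s)
        log_beta = rng.normal(*config.log_beta)
        fbt = {
            "hi_share": {"alpha": alpha, "tau": tau, "delta": delta,
                         "lambda": lam},
            "lo_share": {"alpha": alpha, "tau": tau, "delta": delta},
        }
        itc = {"k": float(np.exp(log_k)), "S": float(np.exp(log_s)),
               "beta": float(np.exp(log_beta))}
        subjects.append(SyntheticSubject(
            subject_id=i, fbt_params=fbt, itc_params=itc,
            ddm_params=DDMParams(),
            seeds={"fbt": int(rng.integers(2**31)),
                   "itc": int(rng.integers(2**31)),
                   "ddm": int(rng.integers(2**31))}))
    return subjects


def simulate_fbt_responses(params: ParamSet, sequence: TrialSequence,
                           seed: int | np.random.Generator | None = None
                           ) -> np.ndarray:
    """Sample probe reports from the model's own Beta response
    distribution (mode = current belief of the probed agent, variance =
    that agent's tau, truncated to the feasible range with a warning)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bs, bo = _trajectory_arrays(sequence, params)
    probe_idx, is_self = _probe_index_arrays(sequence)
    beliefs = np.where(is_self, bs[probe_idx], bo[probe_idx])
    taus = np.where(is_self, params.tau["self"], params.tau["other"])
    if np.any(taus >= TAU_MAX):
        import warnings
        warnings.warn("tau exceeds the feasible Beta variance; truncated",
                      stacklevel=2)
        taus = np.minimum(taus, TAU_MAX)
    mu = np.clip(beliefs, REPORT_CLIP, 1.0 - REPORT_CLIP)
    a, b = beta_shapes_from_mode_variance(mu, taus)
    return rng.beta(a, b)


def simulate_itc_choices(itc_params: dict, battery: pd.DataFrame,
                         seed: int | np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Bernoulli choices over a question battery under hyperbolic
    discounting with a softmax choice rule; returns the battery with a
    ``choice`` column (1 = later)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v_later = discounted_value(battery["later_amt"].to_numpy(dtype=float),
                               battery["delay_days"].to_numpy(dtype=float),
                               itc_params["k"], itc_params.get("S", 1.0))
    p_later = choice_probability(battery["sooner_amt"].to_numpy(dtype=float),
                                 v_later, itc_params["beta"])
    out = battery.copy()
    out["choice"] = (rng.random(len(battery)) < p_later).astype(int)
    return out
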