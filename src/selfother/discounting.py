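"""Hierarchical hyperbolic discounting and its downstream analyses.

Intertemporal choices between an immediate reward and a larger delayed
reward are modelled with hyperbolic discounting,

    V_later = V / (1 + k D)          (one-parameter)
    V_later = V / (1 + k D**S)       (two-parameter, Stevens' power-law
                                      time perception exponent S)

and a softmax choice rule P_later = 1 / (1 + exp(beta (V_sooner -
V_later))).  Parameters live in log space with an empirical Gaussian
group prior fit by expectation-maximisation: E-steps compute subject
MAP estimates with Laplace variances, M-steps update the prior mean
(mean of MAPs) and variance ((1/N) sum[(m_j - mu)^2 + sigma_j^2]).
Models are compared by an integrated BIC (iBIC) whose per-subject
evidence is Monte-Carlo integrated over the fitted prior.

The module also provides the model-free area under the discounting
curve (AUC), the aggregate discounting measure log(kS), and a
leave-one-subject-out (LOSO) logistic classification of high versus low
discounters with permutation-based inference on the median hold-out
cross-entropy, -[y ln p + (1 - y) ln(1 - p)].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

__all__ = [
    "DELAYS_DAYS",
    "DiscountFit",
    "LosoResult",
    "generate_battery",
    "discounted_value",
    "choice_probability",
    "choice_loglik",
    "map_estimate",
    "update_prior",
    "em_fit",
    "ibic_score",
    "discounting_auc",
    "cross_entropy",
    "median_split_labels",
    "loso_classify",
    "compare_feature_sets",
]

#: The seven delays of the choice battery, in days.
DELAYS_DAYS = (1, 7, 14, 28, 42, 56, 84)

N_QUESTIONS = 60
SOONER_RANGE = (1, 9)    # immediate rewards, pounds
LATER_RANGE = (2, 10)    # delayed rewards, pounds

PRIOR_VARIANCE_FLOOR = 1e-6
EM_TOL = 1e-4
EM_MAX_ITER = 200

_MODELS = {"hyper1": ("log_k", "log_beta"),
           "hyper2": ("log_k", "log_s", "log_beta")}


# ---------------------------------------------------------------------------
# battery and choice model

def generate_battery(seed: int = 0) -> pd.DataFrame:
    """A reproducible 60-question battery (sooner_amt, later_amt,
    delay_days).

    Pseudo-random subject to coverage constraints: every sooner
    magnitude 1-9, every later magnitude 2-10 and all seven delays
    appear at least once, and later > sooner on every question.
    """
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        delays = np.resize(np.array(DELAYS_DAYS), N_QUESTIONS).copy()
        rng.shuffle(delays)
        sooner = np.resize(np.arange(SOONER_RANGE[0], SOONER_RANGE[1] + 1),
                           N_QUESTIONS).copy()
        rng.shuffle(sooner)
        later = rng.integers(sooner + 1, LATER_RANGE[1] + 1)
        if set(np.unique(later)) >= set(range(LATER_RANGE[0], LATER_RANGE[1] + 1)):
            return pd.DataFrame({"sooner_amt": sooner, "later_amt": later,
                                 "delay_days": delays})
    raise RuntimeError("battery coverage constraints not met")  # pragma: no cover


def discounted_value(V, D, k, S=1.0):
    """Hyperbolically discounted value V / (1 + k D**S)."""
    V, D, k, S = (np.asarray(x, dtype=float) for x in (V, D, k, S))
    if np.any(V < 0) or np.any(D < 0) or np.any(k < 0) or np.any(S < 0):
        raise ValueError("V, D, k and S must be non-negative")
    with np.errstate(invalid="ignore"):
        dpow = np.where(D > 0, np.power(D, S), 0.0)
    out = V / (1.0 + k * dpow)
    return float(out) if out.ndim == 0 else out


def choice_probability(v_sooner, v_later, beta):
    """Softmax probability of choosing the later option."""
    if np.any(np.asarray(beta) < 0):
        raise ValueError("beta must be non-negative")
    out = expit(np.asarray(beta) * (np.asarray(v_later, dtype=float)
                                    - np.asarray(v_sooner, dtype=float)))
    return float(out) if np.ndim(out) == 0 else out


def _unpack(theta: np.ndarray, model: str):
    if model == "hyper1":
        return np.exp(theta[..., 0]), 1.0, np.exp(theta[..., 1])
    return np.exp(theta[..., 0]), np.exp(theta[..., 1]), np.exp(theta[..., 2])


def choice_loglik(theta: np.ndarray, choices: pd.DataFrame,
                  model: str = "hyper2") -> float:
    """Log-likelihood of one subject's choices at log-space parameters.

    ``theta`` may be a single parameter vector or a (K, p) batch, in
    which case a length-K array is returned.  ``choices['choice']`` is
    1 for the later option.
    """
    theta = np.asarray(theta, dtype=float)
    batch = theta.ndim == 2
    k, S, beta = _unpack(theta, model)
    D = choices["delay_days"].to_numpy(dtype=float)
    later = choices["later_amt"].to_numpy(dtype=float)
    sooner = choices["sooner_amt"].to_numpy(dtype=float)
    y = choices["choice"].to_numpy(dtype=float)
    if batch:
        k, S, beta = (np.atleast_1d(x)[:, None] for x in (k, S, beta))
    vl = later / (1.0 + k * np.power(D, S))
    z = beta * (vl - sooner)              # logit of P(later)
    ll = y * log_expit(z) + (1.0 - y) * log_expit(-z)
    ll = ll.sum(axis=-1)
    return ll if batch else float(ll)


# ---------------------------------------------------------------------------
# MAP-EM hierarchy

def _neg_log_posterior(theta, choices, model, prior_mean, prior_var):
    nll = -choice_loglik(theta, choices, model)
    pen = 0.5 * np.sum((theta - prior_mean) ** 2 / prior_var)
    return nll + pen


def _fd_hessian(f, x, h=1e-4):
    p = len(x)
    H = np.empty((p, p))
    fx = f(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)) / (4 * h * h)
    return H, fx


def map_estimate(choices: pd.DataFrame, prior_mean: np.ndarray,
                 prior_var: np.ndarray, model: str = "hyper2",
                 x0: np.ndarray | None = None):
    """Subject-level MAP estimate with Laplace variances.

    Minimises the negative log posterior in log space (quasi-Newton);
    the posterior variance of each parameter is the corresponding
    diagonal element of the inverse finite-difference Hessian at the
    MAP (floored at 1e-8 when the Hessian is not positive definite).
    Returns (map, variances, converged).
    """
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_var = np.asarray(prior_var, dtype=float)
    f = lambda th: _neg_log_posterior(th, choices, model, prior_mean, prior_var)
    x0 = prior_mean.copy() if x0 is None else np.asarray(x0, dtype=float)
    res = minimize(f, x0, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    H, _ = _fd_hessian(f, res.x)
    try:
        cov = np.linalg.inv(H)
        var = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        var = np.full(len(res.x), np.nan)
    bad = ~np.isfinite(var) | (var <= 0)
    if np.any(bad):
        var[bad] = 1e-8
    return res.x, var, bool(np.isfinite(res.fun))


def update_prior(maps: np.ndarray, variances: np.ndarray):
    """M-step: prior mean = mean of MAPs; prior variance averages the
    squared deviation from the mean plus each subject's Laplace
    variance, floored at 1e-6."""
    m = np.atleast_2d(np.asarray(maps, dtype=float))
    s2 = np.atleast_2d(np.asarray(variances, dtype=float))
    mu = m.mean(axis=0)
    var = ((m - mu) ** 2 + s2).mean(axis=0)
    return mu, np.maximum(var, PRIOR_VARIANCE_FLOOR)


@dataclass
class DiscountFit:
    """Hierarchical fit of one discounting model to a cohort."""

    model: str
    maps: np.ndarray            # (n_subjects, n_params), log space
    variances: np.ndarray       # Laplace variances, same shape
    prior_mean: np.ndarray
    prior_var: np.ndarray
    ibic: float
    n_iterations: int
    converged: bool
    param_names: tuple = ()

    @property
    def log_kS(self) -> np.ndarray:
        """Aggregate discounting measure log(k S) per subject."""
        if self.model == "hyper1":
            return self.maps[:, 0]
        return self.maps[:, 0] + self.maps[:, 1]

    def to_dict(self) -> dict:
        return {"model": self.model, "param_names": list(self.param_names),
                "maps": self.maps.tolist(),
                "variances": self.variances.tolist(),
                "prior_mean": self.prior_mean.tolist(),
                "prior_var": self.prior_var.tolist(),
                "ibic": self.ibic, "n_iterations": self.n_iterations,
                "converged": self.converged,
                "log_kS": self.log_kS.tolist()}


def ibic_score(cohort: list[pd.DataFrame], prior_mean, prior_var,
               model: str = "hyper2", n_samples: int = 1000,
               seed: int = 0) -> float:
    """Integrated BIC for the hierarchical model.

    The per-subject evidence integral over the group prior is
    Monte-Carlo approximated with ``n_samples`` prior draws; the
    hyperparameter penalty counts the prior means and variances against
    the total number of choices.
    """
    rng = np.random.default_rng(seed)
    p = len(_MODELS[model])
    theta = rng.normal(np.asarray(prior_mean), np.sqrt(np.asarray(prior_var)),
                       size=(n_samples, p))
    total_log_ev = 0.0
    n_obs = 0
    for choices in cohort:
        ll = choice_loglik(theta, choices, model)
        total_log_ev += float(np.logaddexp.reduce(ll) - np.log(n_samples))
        n_obs += len(choices)
    n_hyper = 2 * p
    return -2.0 * total_log_ev + n_hyper * np.log(n_obs)


def em_fit(cohort: list[pd.DataFrame], model: str = "hyper2",
           seed: int = 0, tol: float = EM_TOL,
           max_iter: int = EM_MAX_ITER,
           ibic_samples: int = 1000) -> DiscountFit:
    """Empirical-Bayes MAP-EM fit of a discounting model to a cohort.

    Alternates subject MAP estimation (E) and prior updates (M) until
    the largest change in prior mean and variance falls below ``tol``.
    """
    if len(cohort) < 2:
        raise ValueError("need >= 2 subjects")
    names = _MODELS[model]
    p = len(names)
    mu = np.zeros(p)
    mu[0] = np.log(0.03)            # typical k around 0.03 / day
    var = np.full(p, 4.0)           # broad initial prior, sd 2 in log space
    maps = np.tile(mu, (len(cohort), 1))
    variances = np.ones_like(maps)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for j, choices in enumerate(cohort):
            maps[j], variances[j], _ = map_estimate(
                choices, mu, var, model=model, x0=maps[j])
        new_mu, new_var = update_prior(maps, variances)
        delta = max(np.max(np.abs(new_mu - mu)), np.max(np.abs(new_var - var)))
        mu, var = new_mu, new_var
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"EM did not converge in {max_iter} iterations")
    ibic = ibic_score(cohort, mu, var, model=model, n_samples=ibic_samples,
                      seed=seed)
    return DiscountFit(model=model, maps=maps, variances=variances,
                       prior_mean=mu, prior_var=var, ibic=float(ibic),
                       n_iterations=it, converged=converged, param_names=names)


# ---------------------------------------------------------------------------
# model-free discounting measure

def discounting_auc(choices: pd.DataFrame) -> float:
    """Area under the empirical discounting curve, normalised to [0, 1].

    For each delay, the indifference point (subjective value of the
    delayed reward as a fraction of its face amount) is estimated from
    a logistic fit of choice against the sooner/later amount ratio;
    delays where the subject always chose one option pin the point at 1
    (always later) or 0 (always sooner).  The curve (prepending value 1
    at zero delay) is integrated by trapezoid over delay / max delay.
    """
    delays = np.sort(choices["delay_days"].unique())
    points = []
    for d in delays:
        sub = choices[choices["delay_days"] == d]
        ratio = (sub["sooner_amt"] / sub["later_amt"]).to_numpy(dtype=float)
        y = sub["choice"].to_numpy(dtype=float)
        if y.min() == 1.0:
            points.append(1.0)
            continue
        if y.max() == 0.0:
            points.append(0.0)
            continue
        X = np.column_stack([np.ones_like(ratio), ratio])
        w = _batched_irls(X, y[None, :], ridge=1e-3)[0]
        if w[1] >= -1e-8:   # non-decreasing fit: fall back to choice rate
            points.append(float(np.clip(y.mean(), 0.0, 1.0)))
        else:
            points.append(float(np.clip(-w[0] / w[1], 0.0, 1.0)))
    x = np.concatenate([[0.0], delays]) / delays.max()
    v = np.concatenate([[1.0], points])
    return float(np.trapezoid(v, x))


# ---------------------------------------------------------------------------
# LOSO classification with permutation inference

def cross_entropy(y, p) -> np.ndarray:
    """Binary cross-entropy -[y ln p + (1 - y) ln(1 - p)]."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    y = np.asarray(y, dtype=float)
    out = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(out) if out.ndim == 0 else out


def median_split_labels(log_kS: np.ndarray) -> np.ndarray:
    """High-discounter labels from a median split on log(kS); subjects
    at the median are assigned to the low group."""
    x = np.asarray(log_kS, dtype=float)
    return (x > np.median(x)).astype(int)


def _batched_irls(X: np.ndarray, Y: np.ndarray, ridge: float = 1e-3,
                  n_iter: int = 30) -> np.ndarray:
    """Ridge-penalised logistic regression, batched over label vectors.

    ``X`` is (n, p) including any intercept column; ``Y`` is (B, n).
    Returns coefficients (B, p).  The small L2 penalty keeps the Newton
    updates well-posed under separable data.
    """
    B, n = Y.shape
    p = X.shape[1]
    W = np.zeros((B, p))
    I = np.eye(p)
    for _ in range(n_iter):
        mu = expit(W @ X.T)                      # (B, n)
        grad = (mu - Y) @ X + ridge * W          # (B, p)
        s = mu * (1.0 - mu)                      # (B, n)
        H = np.einsum("bn,ni,nj->bij", s, X, X) + ridge * I
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        W -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    return W


@dataclass
class LosoResult:
    """LOSO classification performance and its permutation null."""

    median_ce: float
    fold_ce: np.ndarray
    p_value: float
    null_median_ce: np.ndarray
    labels: np.ndarray
    chance_ce: float = float(np.log(2.0))


def _loso_ce_matrix(X: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    """Hold-out cross-entropy for every label vector (row of Y) and
    every leave-one-subject-out fold."""
    B, n = Y.shape
    ce = np.empty((B, n))
    for i in range(n):
        mask = np.arange(n) != i
        W = _batched_irls(X[mask], Y[:, mask], ridge=ridge)
        p_i = expit(W @ X[i])
        ce[:, i] = cross_entropy(Y[:, i], p_i)
    return ce


def loso_classify(features: np.ndarray, log_kS: np.ndarray,
                  n_permutations: int = 5000, seed: int = 0,
                  ridge: float = 1e-3) -> LosoResult:
    """Predict high/low discounter labels by LOSO logistic regression.

    Features are z-scored; performance is the median hold-out
    cross-entropy across folds.  The two-sided p-value compares it with
    a null distribution of medians obtained by refitting under
    ``n_permutations`` random permutations of the labels.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and len(np.asarray(log_kS)) > 1:
        X = X.T
    n = X.shape[0]
    if n < 10:
        raise ValueError("need >= 10 subjects")
    y = median_split_labels(log_kS)
    frac = y.mean()
    if not 0.4 <= frac <= 0.6:
        warnings.warn(f"class imbalance {frac:.2f} beyond 60/40", stacklevel=2)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xz = np.column_stack([np.ones(n), (X - X.mean(axis=0)) / sd])
    rng = np.random.default_rng(seed)
    Y = np.empty((n_permutations + 1, n), dtype=float)
    Y[0] = y
    for b in range(1, n_permutations + 1):
        Y[b] = rng.permutation(y)
    ce = _loso_ce_matrix(Xz, Y, ridge)
    med = np.median(ce, axis=1)
    obs, null = med[0], med[1:]
    p_lo = (1 + np.sum(null <= obs)) / (n_permutations + 1)
    p_hi = (1 + np.sum(null >= obs)) / (n_permutations + 1)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return LosoResult(median_ce=float(obs), fold_ce=ce[0], p_value=float(p),
                      null_median_ce=null, labels=y)


def compare_feature_sets(features_a: np.ndarray, features_b: np.ndarray,
                         log_kS: np.ndarray, n_permutations: int = 5000,
                         seed: int = 0, ridge: float = 1e-3):
    """Permutation test on the difference in LOSO median cross-entropy
    between two feature sets (shared label permutations).

    Returns (observed difference a - b, two-sided p-value).
    """
    y = median_split_labels(log_kS)
    n = len(y)
    rng = np.random.default_rng(seed)
    Y = np.empty((n_permutations + 1, n), dtype=float)
    Y[0] = y
    for b in range(1, n_permutations + 1):
        Y[b] = rng.permutation(y)
    meds = []
    for F in (features_a, features_b):
        X = np.atleast_2d(np.asarray(F, dtype=float))
        if X.shape[0] == 1 and n > 1:
            X = X.T
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xz = np.column_stack([np.ones(n), (X - X.mean(axis=0)) / sd])
        meds.append(np.median(_loso_ce_matrix(Xz, Y, ridge), axis=1))
    diff = meds[0] - meds[1]
    obs, null = diff[0], diff[1:]
    p_lo = (1 + np.sum(null <= obs)) / (n_permutations + 1)
    p_hi = (1 + np.sum(null >= obs)) / (n_permutations + 1)
    return float(obs), float(min(1.0, 2.0 * min(p_lo, p_hi)))
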