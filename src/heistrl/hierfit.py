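"""Hierarchical EM fitting with Laplace evidence and subject-level LOOcv.

Subject parameters are random effects drawn from a diagonal Gaussian over
transformed parameters (logit for alpha and w, log for beta).  The E-step
finds each subject's MAP estimate by maximising choice log-likelihood plus
the Gaussian log prior; the M-step re-estimates the group mean and variance
from the MAP estimates plus the posterior-covariance correction
``var_k = mean_i(theta_ik^2 + Sigma_i,kk) - mean_i(theta_ik)^2``.  Model
evidence per subject is the Laplace approximation

    log p(data | group) ~= -obj(theta*) + (d/2) log(2 pi) - 1/2 log det H

with H the Hessian of the negative log posterior at the MAP.  Subject-level
leave-one-out cross-validation refits the group prior without each subject
and scores that subject's negative Laplace evidence under the held-out prior
(lower is better); models are compared by a paired t-test on the scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .learner import ModelParams, encode_trials, log_likelihood

N_PARAMS = 3
VAR_FLOOR = 1e-6
#: group variances are kept within [VAR_FLOOR, VAR_CAP]; transformed
#: parameters live in a [-8, 8] box, so a prior sd above 4 is already
#: effectively flat and only destabilises the moment updates
VAR_CAP = 16.0
HESSIAN_EIG_FLOOR = 1e-6
HESSIAN_STEP = 1e-4
#: box on transformed parameters during optimisation; sigmoid(8) ~ 0.99966,
#: exp(8) ~ 2981 — beyond behavioural resolution, prevents runaway MAPs for
#: near-deterministic subjects from blowing up the group variance
THETA_BOUND = 8.0


@dataclass
class GroupPrior:
    """Diagonal Gaussian over transformed parameters (logit a, log b, logit w)."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(N_PARAMS))
    var: np.ndarray = field(default_factory=lambda: np.full(N_PARAMS, 4.0))

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.clip(np.asarray(self.var, dtype=float), VAR_FLOOR, VAR_CAP)
        if self.mean.shape != (N_PARAMS,) or self.var.shape != (N_PARAMS,):
            raise ValueError("GroupPrior mean/var must be 3-vectors")

    def mean_natural(self) -> ModelParams:
        return natural_params(self.mean)


@dataclass
class SubjectFit:
    map_params_transformed: np.ndarray
    map_params_natural: ModelParams
    hessian: np.ndarray
    log_marginal: float
    converged: bool = True
    loocv_score: Optional[float] = None


@dataclass
class ModelComparisonResult:
    score_differences: np.ndarray
    t: float
    dof: int
    p: float
    n_a_better: int
    n_b_better: int


def transform_params(params: ModelParams) -> np.ndarray:
    """Map natural parameters to unconstrained space (logit, log, logit)."""
    if params.alpha in (0.0, 1.0) or params.w in (0.0, 1.0) or params.beta == 0.0:
        raise ValueError(
            "boundary parameter values map to infinity under the transform; "
            "nudge them strictly inside their bounds"
        )
    return np.array([logit(params.alpha), np.log(params.beta), logit(params.w)])


#: cap on |log beta| to keep exp() finite during optimisation
LOG_BETA_CAP = 25.0


def natural_params(theta: Sequence[float]) -> ModelParams:
    """Inverse of :func:`transform_params`."""
    theta = np.asarray(theta, dtype=float)
    beta = float(np.exp(np.clip(theta[1], -LOG_BETA_CAP, LOG_BETA_CAP)))
    return ModelParams(alpha=float(expit(theta[0])), beta=beta, w=float(expit(theta[2])))


def _make_objective(encoded: dict, prior: GroupPrior, variant: str):
    """Negative log posterior over transformed parameters (hot path)."""
    from ._kernels import loglik_kernel

    flexible = variant == "flexible"
    cond, ctx = encoded["cond"], encoded["ctx"]
    free, missed = encoded["free"], encoded["missed"]
    choice_dark, state_heist, gain = encoded["choice_dark"], encoded["state_heist"], encoded["gain"]
    mean, var = prior.mean, prior.var
    log_norm = 0.5 * np.sum(np.log(2.0 * np.pi * var))

    def obj(theta):
        alpha = expit(theta[0])
        beta = np.exp(min(max(theta[1], -LOG_BETA_CAP), LOG_BETA_CAP))
        w = expit(theta[2])
        ll = loglik_kernel(
            cond, ctx, free, missed, choice_dark, state_heist, gain, alpha, beta, w, flexible
        )
        lp = -0.5 * np.sum((theta - mean) ** 2 / var) - log_norm
        return -(ll + lp)

    return obj


def _numerical_hessian(f, x: np.ndarray, step: float = HESSIAN_STEP) -> np.ndarray:
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def _regularize_hessian(H: np.ndarray) -> np.ndarray:
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    vals = np.maximum(vals, HESSIAN_EIG_FLOOR)
    return vecs @ np.diag(vals) @ vecs.T


def subject_map(
    trials_or_encoded,
    prior: GroupPrior,
    variant: str = "flexible",
    n_restarts: int = 3,
    seed: int = 0,
    x0: Optional[np.ndarray] = None,
) -> SubjectFit:
    """MAP estimate, Hessian and Laplace evidence for one subject.

    ``n_restarts`` optimisation starts are taken at the prior mean plus
    seeded Gaussian perturbations; ``x0`` adds a warm start (used by the EM
    loop, which passes ``n_restarts=0`` after its first sweep).
    """
    encoded = trials_or_encoded if isinstance(trials_or_encoded, dict) else encode_trials(trials_or_encoded)
    obj = _make_objective(encoded, prior, variant)
    rng = np.random.default_rng(seed)
    starts = [] if x0 is None else [np.asarray(x0, dtype=float)]
    if n_restarts > 0 or not starts:
        starts.append(prior.mean.copy())
    while len(starts) < n_restarts + (x0 is not None):
        starts.append(prior.mean + rng.standard_normal(N_PARAMS) * np.sqrt(prior.var))
    bounds = [(-THETA_BOUND, THETA_BOUND)] * N_PARAMS
    best = None
    converged = False

    def attempt(s):
        nonlocal best, converged
        res = optimize.minimize(
            obj, np.clip(s, -THETA_BOUND, THETA_BOUND), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    for s in starts:
        attempt(s)
    # the flexible model's likelihood is close to symmetric under w <-> 1-w
    # when the cross-context coupling (~ w^2 * alpha) is weak, so the
    # optimum can sit on a mirrored mode; probe the reflection explicitly
    if variant == "flexible":
        mirrored = best.x.copy()
        mirrored[2] = -mirrored[2]
        attempt(mirrored)
    theta = best.x
    H = _regularize_hessian(_numerical_hessian(obj, theta))
    sign, logdet = np.linalg.slogdet(H)
    log_marginal = -best.fun + 0.5 * N_PARAMS * np.log(2.0 * np.pi) - 0.5 * logdet
    return SubjectFit(
        map_params_transformed=theta,
        map_params_natural=natural_params(theta),
        hessian=H,
        log_marginal=float(log_marginal),
        converged=converged,
    )


def em_fit(
    cohort: Sequence[pd.DataFrame],
    variant: str = "flexible",
    tol: float = 1e-4,
    max_iter: int = 200,
    n_restarts: int = 3,
    seed: int = 0,
    init_prior: Optional[GroupPrior] = None,
):
    """Alternate subject MAP fits with group moment updates until the summed
    Laplace evidence stabilises.  Returns ``(GroupPrior, [SubjectFit])``."""
    if len(cohort) < 2:
        raise ValueError("em_fit needs at least 2 subjects")
    encoded = [t if isinstance(t, dict) else encode_trials(t) for t in cohort]
    prior = init_prior if init_prior is not None else GroupPrior()
    warm: List[Optional[np.ndarray]] = [None] * len(encoded)
    prev_total = -np.inf
    fits: List[SubjectFit] = []
    for it in range(max_iter):
        restarts = n_restarts if it == 0 else min(n_restarts, 2)
        fits = [
            subject_map(enc, prior, variant, n_restarts=restarts, seed=seed + 1000 * i, x0=warm[i])
            for i, enc in enumerate(encoded)
        ]
        warm = [f.map_params_transformed for f in fits]
        total = sum(f.log_marginal for f in fits)
        thetas = np.stack([f.map_params_transformed for f in fits])
        post_var = np.stack([np.diag(np.linalg.inv(f.hessian)) for f in fits])
        mean = thetas.mean(axis=0)
        var = np.maximum((thetas**2 + post_var).mean(axis=0) - mean**2, VAR_FLOOR)
        moved = max(np.abs(mean - prior.mean).max(), np.abs(var - prior.var).max())
        prior = GroupPrior(mean=mean, var=var)
        if np.isfinite(prev_total) and (abs(total - prev_total) < tol or moved < 1e-4):
            break
        prev_total = total
    else:
        warnings.warn("EM reached max_iter without meeting the evidence tolerance")
    return prior, fits


def loocv_scores(
    cohort: Sequence[pd.DataFrame],
    variant: str = "flexible",
    tol: float = 1e-3,
    max_iter: int = 50,
    n_restarts: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Held-out negative Laplace log evidence per subject (lower is better).

    For each subject the group prior is re-estimated by EM on the remaining
    subjects (warm-started from the full-cohort fit, which keeps the
    procedure independent of subject ordering) and the held-out subject is
    scored under that prior.
    """
    if len(cohort) < 3:
        raise ValueError("loocv_scores needs at least 3 subjects")
    encoded = [t if isinstance(t, dict) else encode_trials(t) for t in cohort]
    full_prior, _ = em_fit(
        encoded, variant, tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed
    )
    scores = np.empty(len(encoded))
    for i in range(len(encoded)):
        rest = encoded[:i] + encoded[i + 1 :]
        prior_i, _ = em_fit(
            rest,
            variant,
            tol=tol,
            max_iter=max_iter,
            n_restarts=n_restarts,
            seed=seed,
            init_prior=full_prior,
        )
        fit = subject_map(encoded[i], prior_i, variant, n_restarts=n_restarts, seed=seed + 7 * i)
        scores[i] = -fit.log_marginal
    return scores


def compare_models(scores_a: np.ndarray, scores_b: np.ndarray) -> ModelComparisonResult:
    """Two-sided paired t-test on per-subject scores plus win counts."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("scores must be equal-length 1-d arrays")
    if len(a) < 2:
        raise ValueError("need at least 2 paired scores")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return ModelComparisonResult(d, 0.0, len(d) - 1, 1.0, 0, 0)
        raise ValueError("degenerate paired comparison: constant nonzero score difference")
    t, p = stats.ttest_rel(a, b)
    return ModelComparisonResult(
        score_differences=d,
        t=float(t),
        dof=len(d) - 1,
        p=float(p),
        n_a_better=int(np.sum(d < 0)),
        n_b_better=int(np.sum(d > 0)),
    )
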