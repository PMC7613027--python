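"""Dual-learner transition model: belief mixing, valuation, choice and update.

The agent maintains two sets of beliefs about the probability ``p`` that the
dark door leads to the heist state: a context-specific estimate per context
(four entries) and a context-independent estimate per condition (one shared
across the condition's two contexts).  At choice time the two are mixed,

    p_hat = w_eff * p_independent + (1 - w_eff) * p_specific[context],

where the effective weight ``w_eff`` equals ``w`` in the dependent condition
(and everywhere under the *fixed* variant) and ``1 - w`` in the independent
condition under the *flexible* variant.  Door values are ``q_dark = r*p_hat``
and ``q_light = r*(1 - p_hat)`` with r = +1 on gain and -1 on loss trials,
and the dark door is chosen with softmax probability
``1 / (1 + exp(beta*(q_light - q_dark)))``.  After the transition a state
prediction error ``delta = x - p_hat`` (x = 1 when dark->heist or
light->neutral) updates both learners:

    p_independent += w_eff * alpha * delta
    p_specific    += (1 - w_eff) * alpha * delta

with each estimate clamped to [0, 1].  Beliefs start at 0.5 and are never
reset between blocks.  Only free, non-missed trials contribute to the choice
likelihood, but beliefs update on every non-missed trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .task import CONTEXT_CONDITION
from ._kernels import loglik_kernel

VARIANTS = ("fixed", "flexible")

#: extra columns run_model adds to a TrialTable
TRAJECTORY_COLUMNS = [
    "p_hat",
    "q_dark",
    "q_light",
    "choice_prob_dark",
    "delta",
    "abs_delta",
    "loglik_contribution",
]


@dataclass
class ModelParams:
    """Learning rate, softmax inverse temperature and mixing weight."""

    alpha: float
    beta: float
    w: float

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")


@dataclass
class BeliefState:
    """Context-specific and context-independent transition estimates."""

    p_specific: dict = field(default_factory=lambda: {1: 0.5, 2: 0.5, 3: 0.5, 4: 0.5})
    p_independent: dict = field(
        default_factory=lambda: {"dependent": 0.5, "independent": 0.5}
    )

    def copy(self) -> "BeliefState":
        return BeliefState(dict(self.p_specific), dict(self.p_independent))


def effective_weight(w: float, condition: str, variant: str) -> float:
    """Mixing/update weight for this condition: reverses under flexible/independent."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if condition not in ("dependent", "independent"):
        raise ValueError(f"unknown condition {condition!r}")
    if variant == "flexible" and condition == "independent":
        return 1.0 - w
    return w


def _check_context(condition: str, context: int) -> None:
    if CONTEXT_CONDITION.get(context) != condition:
        raise ValueError(f"context {context} does not belong to condition {condition!r}")


def combined_estimate(
    beliefs: BeliefState, params: ModelParams, condition: str, context: int, variant: str
) -> float:
    """Mix the two learners' estimates into a single p_hat."""
    _check_context(condition, context)
    w_eff = effective_weight(params.w, condition, variant)
    return w_eff * beliefs.p_independent[condition] + (1.0 - w_eff) * beliefs.p_specific[context]


def action_values_and_choice_prob(p_hat: float, valence: str, beta: float):
    """Door values and softmax probability of choosing the dark door."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    if beta < 0.0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    r = 1.0 if valence == "gain" else -1.0
    q_dark = r * p_hat
    q_light = r * (1.0 - p_hat)
    p_dark = float(expit(beta * (q_dark - q_light)))
    return q_dark, q_light, p_dark


def state_prediction_error(choice: str, state: str, p_hat: float) -> float:
    """delta = x - p_hat with x = 1 for dark->heist or light->neutral."""
    if choice == "missed":
        raise ValueError("no prediction error on missed trials")
    x = 1.0 if (choice == "dark") == (state == "heist") else 0.0
    return x - p_hat


def update_beliefs(
    beliefs: BeliefState,
    delta: float,
    params: ModelParams,
    condition: str,
    context: int,
    variant: str,
) -> BeliefState:
    """Apply the weighted prediction-error update; clamp each estimate to [0, 1]."""
    _check_context(condition, context)
    w_eff = effective_weight(params.w, condition, variant)
    out = beliefs.copy()
    out.p_independent[condition] = float(
        np.clip(beliefs.p_independent[condition] + w_eff * params.alpha * delta, 0.0, 1.0)
    )
    out.p_specific[context] = float(
        np.clip(beliefs.p_specific[context] + (1.0 - w_eff) * params.alpha * delta, 0.0, 1.0)
    )
    return out


def _outcome_positive(state: str, valence: str) -> bool:
    # positive: +1 on gain trials (heist) or 0 on loss trials (neutral)
    return (state == "heist") == (valence == "gain")


def run_model(
    trials: pd.DataFrame,
    params: ModelParams,
    variant: str = "flexible",
    mode: str = "likelihood",
    rng: Optional[np.random.Generator] = None,
    valence_update: str = "both",
) -> pd.DataFrame:
    """Run the learner over a TrialTable.

    ``mode='likelihood'`` replays observed choices/states and records the
    log-likelihood of free-trial choices; ``mode='simulate'`` samples choices
    (forced trials take the presented door, which the generator draws as a
    fair coin) and transitions against the trial's ``p_true``.

    ``valence_update='positive_only'`` is a simulation-only analysis agent
    that updates beliefs only after positive outcomes (+1 on gain, 0 on loss
    trials); the default updates after every non-missed trial.

    Returns a copy of ``trials`` with choices/states/outcomes filled (simulate
    mode) plus the trajectory columns p_hat, q_dark, q_light,
    choice_prob_dark, delta, abs_delta and loglik_contribution.
    """
    if mode not in ("likelihood", "simulate"):
        raise ValueError(f"mode must be 'likelihood' or 'simulate', got {mode!r}")
    if valence_update not in ("both", "positive_only"):
        raise ValueError(f"unknown valence_update {valence_update!r}")
    idx = trials["trial_index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError("trials must be sorted by trial_index")
    if mode == "simulate" and rng is None:
        rng = np.random.default_rng()

    out = trials.copy().reset_index(drop=True)
    n = len(out)
    cols = {name: np.full(n, np.nan) for name in TRAJECTORY_COLUMNS}
    choices = out["choice"].astype(object).to_numpy()
    states = out["state"].astype(object).to_numpy()
    outcomes = out["outcome"].to_numpy(dtype=float)

    beliefs = BeliefState()
    for i, row in enumerate(out.itertuples(index=False)):
        condition, context, valence = row.condition, int(row.context), row.valence
        if mode == "likelihood":
            choice = row.choice
            if pd.isna(choice):
                raise ValueError("likelihood mode requires choices to be filled")
            if choice == "missed":
                cols["loglik_contribution"][i] = 0.0
                continue
            state = row.state
            if pd.isna(state):
                raise ValueError("likelihood mode requires states to be filled")

        p_hat = combined_estimate(beliefs, params, condition, context, variant)
        q_dark, q_light, p_dark = action_values_and_choice_prob(p_hat, valence, params.beta)

        if mode == "simulate":
            if row.trial_type == "forced":
                choice = row.door_presented
            else:
                choice = "dark" if rng.random() < p_dark else "light"
            from .task import sample_step

            state, outcome = sample_step(choice, float(row.p_true), valence, rng)
            choices[i], states[i], outcomes[i] = choice, state, outcome

        ll = 0.0
        if row.trial_type == "free":
            p_choice = p_dark if choice == "dark" else 1.0 - p_dark
            ll = float(np.log(max(p_choice, 1e-300)))

        delta = state_prediction_error(choice, state, p_hat)
        if valence_update == "both" or _outcome_positive(state, valence):
            beliefs = update_beliefs(beliefs, delta, params, condition, context, variant)

        cols["p_hat"][i] = p_hat
        cols["q_dark"][i] = q_dark
        cols["q_light"][i] = q_light
        cols["choice_prob_dark"][i] = p_dark
        cols["delta"][i] = delta
        cols["abs_delta"][i] = abs(delta)
        cols["loglik_contribution"][i] = ll

    if mode == "simulate":
        out["choice"] = choices
        out["state"] = states
        out["outcome"] = outcomes
    for name, arr in cols.items():
        out[name] = arr
    return out


# ---------------------------------------------------------------------------
# fast likelihood path used by the hierarchical fitter


def encode_trials(trials: pd.DataFrame) -> dict:
    """Pack a TrialTable with observed choices into integer arrays for the
    compiled likelihood kernel."""
    idx = trials["trial_index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError("trials must be sorted by trial_index")
    choice = trials["choice"].astype(object)
    if choice.isna().any():
        raise ValueError("likelihood evaluation requires choices to be filled")
    missed = (choice == "missed").to_numpy()
    state = trials["state"].astype(object)
    if (state.isna() & ~missed).any():
        raise ValueError("likelihood evaluation requires states to be filled")
    return dict(
        cond=(trials["condition"] == "independent").to_numpy(np.int64),
        ctx=trials["context"].to_numpy(np.int64) - 1,
        free=(trials["trial_type"] == "free").to_numpy(np.int64),
        missed=missed.astype(np.int64),
        choice_dark=(choice == "dark").to_numpy(np.int64),
        state_heist=(state == "heist").fillna(False).to_numpy(np.int64),
        gain=(trials["valence"] == "gain").to_numpy(np.int64),
    )


def log_likelihood(
    encoded: dict, params: ModelParams, variant: str = "flexible"
) -> float:
    """Summed log-likelihood of free-trial choices (compiled fast path)."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    return float(
        loglik_kernel(
            encoded["cond"],
            encoded["ctx"],
            encoded["free"],
            encoded["missed"],
            encoded["choice_dark"],
            encoded["state_heist"],
            encoded["gain"],
            params.alpha,
            params.beta,
            params.w,
            variant == "flexible",
        )
    )
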