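"""Trial-history behavioural statistics for the heist task.

Choices are recoded into a valence-free frame: on a gain trial, evidence from
a past transition counts +1 toward choosing the dark door if that transition
suggested the dark door reaches the heist state (dark->heist or
light->neutral observed) and -1 otherwise; the coding is reversed when the
current trial is a loss trial.  Each of the previous five trials contributes
to a "Same" or "Other" column according to whether it shared the current
trial's context.  ``differential_evidence`` is the mean of the Same columns
minus the mean of the Other columns, and the key group-level statistic is
the differential_evidence x condition interaction in a logistic regression
(condition coded +1 dependent, -1 independent).

The module also provides agent-cohort simulation, an agent-based permutation
null for the interaction (fixed-model agents with w ~ U(0,1)), and the
outcome-valence consistency analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .learner import ModelParams, run_model
from .task import TaskConfig, generate_trial_table

ORDINALS = ["one", "two", "three", "four", "five", "six", "seven", "eight", "nine", "ten"]


class BehavFitError(RuntimeError):
    """Raised when a choice-history regression is singular or separated."""


def lag_columns(n_lags: int = 5) -> List[str]:
    same = [f"{ORDINALS[k]}BackSame" for k in range(n_lags)]
    other = [f"{ORDINALS[k]}BackOther" for k in range(n_lags)]
    return same + other


def _transition_evidence(choice: str, state: str) -> int:
    # +1 when the transition points at the dark door reaching the heist state
    return 1 if (choice == "dark") == (state == "heist") else -1


def build_history_regressors(trials: pd.DataFrame, n_lags: int = 5) -> pd.DataFrame:
    """Evidence matrix for free, non-missed trials.

    One row per current free trial; lag columns hold signed transition
    evidence from 1..n_lags trials back within the same block (0 when the lag
    crosses a block boundary, lands on a missed trial, or belongs to the
    other routing column).  Lags are routed to Same/Other by context match.
    """
    if n_lags < 1 or n_lags > len(ORDINALS):
        raise ValueError(f"n_lags must be in 1..{len(ORDINALS)}")
    cols = lag_columns(n_lags)
    rows = []
    for subject, sub in trials.groupby("subject", sort=False):
        idx = sub["trial_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValueError("trials must be time-ordered within subject")
        sub = sub.reset_index(drop=True)
        block_id = sub["session"].astype(str) + "/" + sub["block"].astype(str)
        choice = sub["choice"].astype(object).to_numpy()
        state = sub["state"].astype(object).to_numpy()
        for t in range(len(sub)):
            if sub.at[t, "trial_type"] != "free":
                continue
            if pd.isna(choice[t]) or choice[t] == "missed":
                continue
            rec = dict.fromkeys(cols, 0)
            loss = sub.at[t, "valence"] == "loss"
            for k in range(1, n_lags + 1):
                j = t - k
                if j < 0 or block_id[j] != block_id[t]:
                    continue
                if pd.isna(choice[j]) or choice[j] == "missed":
                    continue
                ev = _transition_evidence(choice[j], state[j])
                if loss:
                    ev = -ev
                col = "Same" if sub.at[j, "context"] == sub.at[t, "context"] else "Other"
                rec[f"{ORDINALS[k - 1]}Back{col}"] = ev
            rec.update(
                subject=subject,
                trial_index=sub.at[t, "trial_index"],
                context=sub.at[t, "context"],
                condition=sub.at[t, "condition"],
                Condition=1 if sub.at[t, "condition"] == "dependent" else -1,
                response=1 if choice[t] == "dark" else 0,
            )
            rows.append(rec)
    em = pd.DataFrame(
        rows, columns=cols + ["subject", "trial_index", "context", "condition", "Condition", "response"]
    )
    if len(em):
        em["differential_evidence"] = differential_evidence(em, n_lags)
    else:
        em["differential_evidence"] = pd.Series(dtype=float)
    return em


def differential_evidence(em: pd.DataFrame, n_lags: int = 5) -> pd.Series:
    """Mean Same-column evidence minus mean Other-column evidence per trial."""
    same = [f"{ORDINALS[k]}BackSame" for k in range(n_lags)]
    other = [f"{ORDINALS[k]}BackOther" for k in range(n_lags)]
    missing = [c for c in same + other if c not in em.columns]
    if missing:
        raise ValueError(f"missing lag columns: {missing}")
    return em[same].mean(axis=1) - em[other].mean(axis=1)


def _design(em: pd.DataFrame, spec: str, n_lags: int) -> Tuple[pd.DataFrame, List[str]]:
    if spec == "ten_lag_per_condition":
        terms = lag_columns(n_lags)
        X = em[terms].astype(float)
    elif spec == "differential_interaction":
        X = pd.DataFrame(
            {
                "differential_evidence": em["differential_evidence"].astype(float),
                "Condition": em["Condition"].astype(float),
            }
        )
        X["differential_evidence:Condition"] = X["differential_evidence"] * X["Condition"]
        terms = list(X.columns)
    else:
        raise ValueError(f"unknown model spec {spec!r}")
    X.insert(0, "Intercept", 1.0)
    return X, ["Intercept"] + terms


def fit_choice_history_model(
    em: pd.DataFrame,
    spec: str = "ten_lag_per_condition",
    n_lags: int = 5,
    backend: str = "cluster_robust",
) -> pd.DataFrame:
    """Logistic regression of choice on history evidence.

    Backends: ``cluster_robust`` (logistic GLM with subject-clustered
    standard errors; the default), ``mixed`` (Bayesian logistic GLMM with a
    random intercept per subject), and ``ridge`` (L2-penalised logistic
    regression; coefficients only, robust to perfect separation).

    Returns a coefficient table with columns term, estimate, se, ci_low,
    ci_high, p.
    """
    if not len(em):
        raise ValueError("empty evidence matrix")
    X, terms = _design(em, spec, n_lags)
    y = em["response"].astype(float).to_numpy()
    if backend == "cluster_robust":
        try:
            model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
            res = model.fit(cov_type="cluster", cov_kwds={"groups": em["subject"].to_numpy()})
        except Exception as exc:  # separation / singular design
            raise BehavFitError(f"choice-history GLM failed: {exc}") from exc
        if not np.all(np.isfinite(res.bse)):
            raise BehavFitError("choice-history GLM produced non-finite standard errors")
        est, se, p = res.params, res.bse, res.pvalues
    elif backend == "mixed":
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        exog_vc = pd.get_dummies(em["subject"]).to_numpy(dtype=float)
        md = BinomialBayesMixedGLM(
            y, X.to_numpy(), exog_vc, ident=np.zeros(exog_vc.shape[1], dtype=int)
        )
        res = md.fit_map()
        est, se = np.asarray(res.fe_mean), np.asarray(res.fe_sd)
        p = 2.0 * (1.0 - _norm_cdf(np.abs(est / se)))
    elif backend == "ridge":
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, fit_intercept=False, max_iter=2000)
        lr.fit(X.to_numpy(), y)
        est = lr.coef_.ravel()
        se = np.full_like(est, np.nan)
        p = np.full_like(est, np.nan)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    return pd.DataFrame(
        {
            "term": terms,
            "estimate": est,
            "se": se,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
            "p": np.asarray(p, dtype=float),
        }
    )


def _norm_cdf(z):
    from scipy.stats import norm

    return norm.cdf(z)


def simulate_agent(
    params: ModelParams,
    config: TaskConfig,
    rng: np.random.Generator,
    variant: str = "flexible",
    subject: int = 0,
    valence_update: str = "both",
) -> pd.DataFrame:
    """One agent playing a fresh task; returns the filled TrialTable+trajectory."""
    trials = generate_trial_table(config, rng, subject=subject)
    return run_model(trials, params, variant=variant, mode="simulate", rng=rng,
                     valence_update=valence_update)


def simulate_cohorts(
    n_sims: int,
    variant: str,
    param_pool: Sequence[ModelParams],
    config: TaskConfig,
    rng: np.random.Generator,
    n_agents: int = 29,
    n_lags: int = 5,
    backend: str = "cluster_robust",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated agent cohorts and their per-condition lag regressions.

    Each simulation draws ``n_agents`` parameter sets from ``param_pool``
    with replacement, plays a fresh task per agent, and fits the ten-lag
    choice-history model separately per condition.  Returns
    ``(per_sim, mean)`` coefficient tables; both are empty for ``n_sims=0``.
    """
    if n_sims > 0 and not len(param_pool):
        raise ValueError("param_pool must be non-empty")
    records = []
    for s in range(n_sims):
        tables = []
        for a in range(n_agents):
            params = param_pool[rng.integers(len(param_pool))]
            tables.append(simulate_agent(params, config, rng, variant=variant, subject=a))
        em = build_history_regressors(pd.concat(tables, ignore_index=True), n_lags=n_lags)
        for condition in ("dependent", "independent"):
            coef = fit_choice_history_model(
                em[em["condition"] == condition], spec="ten_lag_per_condition",
                n_lags=n_lags, backend=backend,
            )
            coef.insert(0, "condition", condition)
            coef.insert(0, "sim", s)
            records.append(coef)
    if not records:
        empty = pd.DataFrame(columns=["sim", "condition", "term", "estimate", "se", "ci_low", "ci_high", "p"])
        return empty, empty.drop(columns=["sim"])
    per_sim = pd.concat(records, ignore_index=True)
    mean = (
        per_sim.groupby(["condition", "term"], sort=False)["estimate"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "estimate", "std": "sd", "count": "n_sims"})
    )
    return per_sim, mean


@dataclass
class PermutationNull:
    """Null distribution of the differential-evidence x condition interaction."""

    draws: np.ndarray
    low: float
    high: float

    def empirical_p(self, observed: float) -> float:
        """Two-sided empirical p of an observed interaction under the null."""
        n = len(self.draws)
        lo = (1 + np.sum(self.draws <= observed)) / (n + 1)
        hi = (1 + np.sum(self.draws >= observed)) / (n + 1)
        return float(min(1.0, 2.0 * min(lo, hi)))


def permutation_null(
    n_groups: int,
    n_agents: int,
    fixed_pool: Sequence[Tuple[float, float]],
    config: TaskConfig,
    rng: np.random.Generator,
    backend: str = "cluster_robust",
) -> PermutationNull:
    """Interaction null from fixed-model agent groups with w ~ U(0, 1).

    Each group simulates ``n_agents`` agents under the fixed model whose
    (alpha, beta) pairs are resampled from ``fixed_pool`` and whose mixing
    weight cannot reverse between conditions; the
    differential_evidence x Condition coefficient is collected per group.
    """
    if not len(fixed_pool):
        raise ValueError("fixed_pool must be non-empty")
    draws = []
    for g in range(n_groups):
        tables = []
        for a in range(n_agents):
            alpha, beta = fixed_pool[rng.integers(len(fixed_pool))]
            params = ModelParams(alpha=alpha, beta=beta, w=float(rng.uniform()))
            tables.append(simulate_agent(params, config, rng, variant="fixed", subject=a))
        em = build_history_regressors(pd.concat(tables, ignore_index=True))
        coef = fit_choice_history_model(em, spec="differential_interaction", backend=backend)
        draws.append(
            float(coef.loc[coef["term"] == "differential_evidence:Condition", "estimate"].iloc[0])
        )
    draws = np.asarray(draws)
    low, high = np.percentile(draws, [2.5, 97.5])
    return PermutationNull(draws=draws, low=float(low), high=float(high))


@dataclass
class ConsistencySummary:
    consistency_positive: float  # percent
    consistency_negative: float  # percent
    valence_effect: float  # percentage points, positive - negative
    counts: pd.DataFrame  # rows: repeat/switch x positive/negative


def consistency_scores(
    trials: pd.DataFrame,
    scope: str = "all",
    free_choice_only: Optional[bool] = None,
) -> ConsistencySummary:
    """Percent of choices consistent with the previous trial's transition.

    A trial is a *repeat* trial when the previous terminal state is desirable
    again (prev heist & current gain, or prev neutral & current loss) and a
    *switch* trial otherwise; a choice is consistent when it repeats
    (repeat trials) or switches (switch trials) the previous door.  Trials
    split by the previous outcome's valence: positive (+1 on gain, 0 on
    loss), negative (-1 on loss, 0 on gain).  Per-valence scores average the
    repeat and switch category percentages.  The previous trial is the
    immediately preceding trial of the same block regardless of context.
    """
    if scope not in ("all", "dependent_only"):
        raise ValueError(f"unknown scope {scope!r}")
    if trials["subject"].nunique() > 1:
        raise ValueError("consistency_scores expects a single subject's trials")
    if free_choice_only is None:
        free_choice_only = bool((trials["trial_type"] == "forced").any())
    idx = trials["trial_index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError("trials must be time-ordered")
    sub = trials.reset_index(drop=True)
    block_id = sub["session"].astype(str) + "/" + sub["block"].astype(str)
    tallies = {
        (k, v): [0, 0] for k in ("repeat", "switch") for v in ("positive", "negative")
    }  # [consistent, total]
    for t in range(1, len(sub)):
        if block_id[t] != block_id[t - 1]:
            continue
        cur, prev = sub.iloc[t], sub.iloc[t - 1]
        if free_choice_only and cur["trial_type"] != "free":
            continue
        if scope == "dependent_only" and cur["condition"] != "dependent":
            continue
        for row in (cur, prev):
            if pd.isna(row["choice"]) or row["choice"] == "missed":
                break
        else:
            kind = (
                "repeat"
                if (prev["state"] == "heist") == (cur["valence"] == "gain")
                else "switch"
            )
            prev_positive = (prev["state"] == "heist") == (prev["valence"] == "gain")
            val = "positive" if prev_positive else "negative"
            consistent = (cur["choice"] == prev["choice"]) == (kind == "repeat")
            tallies[(kind, val)][0] += int(consistent)
            tallies[(kind, val)][1] += 1

    def score(valence: str) -> float:
        pcts = [
            100.0 * tallies[(k, valence)][0] / tallies[(k, valence)][1]
            for k in ("repeat", "switch")
            if tallies[(k, valence)][1] > 0
        ]
        return float(np.mean(pcts)) if pcts else float("nan")

    counts = pd.DataFrame(
        [
            dict(kind=k, valence=v, consistent=c, total=n)
            for (k, v), (c, n) in tallies.items()
        ]
    )
    pos, neg = score("positive"), score("negative")
    return ConsistencySummary(
        consistency_positive=pos,
        consistency_negative=neg,
        valence_effect=pos - neg,
        counts=counts,
    )


def cohort_consistency(trials: pd.DataFrame, scope: str = "all",
                       free_choice_only: Optional[bool] = None) -> pd.DataFrame:
    """Per-subject consistency scores for a multi-subject TrialTable."""
    rows = []
    for subject, sub in trials.groupby("subject", sort=False):
        s = consistency_scores(sub, scope=scope, free_choice_only=free_choice_only)
        rows.append(
            dict(
                subject=subject,
                consistency_positive=s.consistency_positive,
                consistency_negative=s.consistency_negative,
                valence_effect=s.valence_effect,
            )
        )
    return pd.DataFrame(rows)
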