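import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heistrl import behav
from heistrl.behav import (
    build_history_regressors,
    consistency_scores,
    differential_evidence,
    fit_choice_history_model,
    lag_columns,
    simulate_cohorts,
)
from heistrl.learner import ModelParams
from heistrl.task import TaskConfig

from helpers import manual_trials


def free(choice, state, **kw):
    kw.setdefault("trial_type", "free")
    return dict(choice=choice, state=state, **kw)


class TestHistoryRegressors:
    def test_gain_trial_same_context_heist_codes_plus_one(self):
        trials = manual_trials(
            [dict(choice="dark", state="heist"), free("dark", "heist", valence="gain")]
        )
        em = build_history_regressors(trials)
        assert len(em) == 1
        assert em.loc[0, "oneBackSame"] == 1
        assert em.loc[0, "oneBackOther"] == 0

    def test_loss_trial_reverses_coding(self):
        trials = manual_trials(
            [dict(choice="dark", state="heist"), free("dark", "heist", valence="loss")]
        )
        em = build_history_regressors(trials)
        assert em.loc[0, "oneBackSame"] == -1

    @pytest.mark.parametrize(
        "choice,state,expected",
        [
            ("dark", "heist", 1),
            ("light", "heist", -1),
            ("dark", "neutral", -1),
            ("light", "neutral", 1),
        ],
    )
    def test_transition_evidence_sign_table(self, choice, state, expected):
        trials = manual_trials([dict(choice=choice, state=state), free("dark", "heist")])
        em = build_history_regressors(trials)
        assert em.loc[0, "oneBackSame"] == expected

    def test_lag_routed_to_other_context_column(self):
        trials = manual_trials(
            [
                dict(choice="dark", state="heist", context=2),
                dict(choice="light", state="heist", context=1),
                dict(choice="dark", state="neutral", context=1),
                free("dark", "heist", context=1),
            ]
        )
        em = build_history_regressors(trials)
        assert em.loc[0, "threeBackSame"] == 0
        assert em.loc[0, "threeBackOther"] == 1  # dark->heist in context 2
        assert em.loc[0, "oneBackSame"] == -1  # dark->neutral same context

    def test_lags_do_not_cross_block_boundary(self):
        trials = manual_trials(
            [
                dict(choice="dark", state="heist"),
                free("dark", "heist", session=1, trial_index=1),
            ]
        )
        em = build_history_regressors(trials)
        assert (em[lag_columns(5)].to_numpy() == 0).all()

    def test_exclusive_routing_per_lag(self, rng):
        from heistrl.cohorts import simulate_cohort

        tables, _ = simulate_cohort(rng, n_subjects=2)
        em = build_history_regressors(pd.concat(tables, ignore_index=True))
        for k in ("one", "two", "three", "four", "five"):
            both = (em[f"{k}BackSame"] != 0) & (em[f"{k}BackOther"] != 0)
            assert not both.any()

    def test_unordered_input_rejected(self):
        trials = manual_trials([free("dark", "heist"), free("dark", "heist")])
        trials["trial_index"] = [1, 0]
        with pytest.raises(ValueError):
            build_history_regressors(trials)


class TestDifferentialEvidence:
    def test_all_zero_columns_give_zero(self):
        trials = manual_trials([free("dark", "heist")])
        em = build_history_regressors(trials)
        assert em.loc[0, "differential_evidence"] == 0.0

    def test_hand_arithmetic(self):
        em = pd.DataFrame(
            {
                "oneBackSame": [1], "twoBackSame": [-1], "threeBackSame": [0],
                "fourBackSame": [0], "fiveBackSame": [0],
                "oneBackOther": [1], "twoBackOther": [1], "threeBackOther": [0],
                "fourBackOther": [0], "fiveBackOther": [0],
            }
        )
        assert differential_evidence(em).iloc[0] == pytest.approx(-0.4)

    def test_extreme_bound(self):
        em = pd.DataFrame({c: [1 if "Same" in c else -1] for c in lag_columns(5)})
        assert differential_evidence(em).iloc[0] == pytest.approx(2.0)

    @given(vals=st.lists(st.integers(-1, 1), min_size=10, max_size=10))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_antisymmetric_under_column_swap(self, vals):
        cols = lag_columns(5)
        em = pd.DataFrame({c: [v] for c, v in zip(cols, vals)})
        swapped = em.rename(
            columns=lambda c: c.replace("Same", "X").replace("Other", "Same").replace("X", "Other")
        )
        assert differential_evidence(em).iloc[0] == pytest.approx(
            -differential_evidence(swapped).iloc[0]
        )


class TestChoiceHistoryModel:
    def test_deterministic_same_context_responder(self, rng):
        # responder repeats whatever lag-1 same-context evidence suggests
        rows = []
        ctx = 1
        ev = 1
        for t in range(400):
            choice = "dark" if ev == 1 else "light"
            state = "heist" if rng.random() < 0.5 else "neutral"
            rows.append(
                free(choice, state, context=ctx, trial_index=t, valence="gain")
            )
            ev = 1 if (choice == "dark") == (state == "heist") else -1
        trials = manual_trials(rows)
        em = build_history_regressors(trials)
        coef = fit_choice_history_model(em, backend="ridge")
        est = coef.set_index("term")["estimate"]
        lag1 = est["oneBackSame"]
        others = est.drop(["Intercept", "oneBackSame"]).abs()
        assert lag1 > 0 and lag1 > 2 * others.max()

    def test_null_responder_cis_cover_zero(self, rng):
        # choices independent of history: fixed effects should be ~0
        covered = []
        for _ in range(6):
            subs = []
            for s in range(8):
                rows = [
                    free("dark" if rng.random() < 0.5 else "light",
                         "heist" if rng.random() < 0.5 else "neutral",
                         trial_index=t, context=int(rng.integers(1, 3)))
                    for t in range(200)
                ]
                subs.append(manual_trials(rows, subject=s))
            em = build_history_regressors(pd.concat(subs, ignore_index=True))
            coef = fit_choice_history_model(em).set_index("term")
            lag_terms = coef.loc[lag_columns(5)]
            covered.append(((lag_terms["ci_low"] <= 0) & (lag_terms["ci_high"] >= 0)).mean())
        assert np.mean(covered) >= 0.85

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_choice_history_model(pd.DataFrame())


class TestSimulateCohorts:
    def test_zero_sims_empty(self, rng):
        per_sim, mean = simulate_cohorts(0, "flexible", [ModelParams(0.5, 1.5, 0.8)],
                                         TaskConfig.fmri(), rng)
        assert per_sim.empty and mean.empty

    def test_flexible_pool_transfers_only_in_dependent(self, rng):
        pool = [ModelParams(0.56, 1.59, 0.85)]
        per_sim, mean = simulate_cohorts(4, "flexible", pool, TaskConfig.fmri(), rng,
                                         n_agents=12)
        m = mean.set_index(["condition", "term"])["estimate"]
        assert m[("dependent", "oneBackOther")] > 0.15
        assert abs(m[("independent", "oneBackOther")]) < 0.15
        assert m[("independent", "oneBackSame")] > m[("independent", "oneBackOther")]

    def test_fixed_pool_symmetric_across_conditions(self, rng):
        pool = [ModelParams(0.65, 1.80, 0.61)]
        _, mean = simulate_cohorts(4, "fixed", pool, TaskConfig.fmri(), rng, n_agents=12)
        m = mean.set_index(["condition", "term"])["estimate"]
        gap = abs(m[("dependent", "oneBackOther")] - m[("independent", "oneBackOther")])
        assert gap < 0.2


class TestConsistencyScores:
    def test_constructed_eight_trial_fixture(self):
        # 4 positive-prevoutcome trials (3 consistent), 4 negative (1 consistent)
        rows = []
        seq = [
            # (prev_state, prev_valence) -> current (valence, choice rel. prev)
            ("heist", "gain", "gain", "same"),      # repeat-positive, consistent
            ("heist", "gain", "gain", "same"),      # repeat-positive, consistent
            ("neutral", "loss", "gain", "same"),    # switch-positive, inconsistent
            ("neutral", "loss", "gain", "other"),   # switch-positive, consistent
            ("heist", "loss", "gain", "other"),     # repeat-negative, inconsistent
            ("heist", "loss", "gain", "other"),     # repeat-negative, inconsistent
            ("heist", "loss", "loss", "other"),     # switch-negative, consistent
            ("heist", "loss", "loss", "same"),      # switch-negative, inconsistent
        ]
        t = 0
        for block, (ps, pv, cv, rel) in enumerate(seq):
            prev_choice = "dark"
            cur_choice = "dark" if rel == "same" else "light"
            rows.append(dict(choice=prev_choice, state=ps, valence=pv, session=block,
                             trial_index=t, trial_type="free"))
            rows.append(dict(choice=cur_choice, state="heist", valence=cv, session=block,
                             trial_index=t + 1, trial_type="free"))
            t += 2
        trials = manual_trials(rows)
        s = consistency_scores(trials, free_choice_only=False)
        assert s.consistency_positive == pytest.approx(75.0)
        assert s.consistency_negative == pytest.approx(25.0)
        assert s.valence_effect == pytest.approx(50.0)

    def test_repeat_positive_classification(self):
        trials = manual_trials(
            [
                dict(choice="dark", state="heist", valence="gain", trial_type="free"),
                free("dark", "heist", valence="gain"),
            ]
        )
        s = consistency_scores(trials, free_choice_only=False)
        assert s.consistency_positive == 100.0
        assert np.isnan(s.consistency_negative)

    def test_repeat_negative_same_sequence_after_loss(self):
        trials = manual_trials(
            [
                dict(choice="dark", state="heist", valence="loss", trial_type="free"),
                free("dark", "heist", valence="gain"),
            ]
        )
        s = consistency_scores(trials, free_choice_only=False)
        assert s.consistency_negative == 100.0
        assert np.isnan(s.consistency_positive)

    def test_first_trial_of_block_excluded(self):
        trials = manual_trials(
            [
                dict(choice="dark", state="heist", trial_type="free"),
                free("dark", "heist", session=1),
            ]
        )
        s = consistency_scores(trials, free_choice_only=False)
        assert s.counts["total"].sum() == 0

    def test_positive_only_updaters_exceed_symmetric_valence_effect(self, rng):
        # symmetric updaters already show a positive valence effect through
        # choice selection (successful previous trials are those where the
        # observed transition agreed with accumulated beliefs); updating only
        # after positive outcomes must push the effect well above that baseline
        from heistrl.behav import simulate_agent

        def cohort(valence_update):
            tables = [
                simulate_agent(ModelParams(0.6, 2.0, 0.85), TaskConfig.pilot(), rng,
                               subject=i, valence_update=valence_update)
                for i in range(10)
            ]
            return behav.cohort_consistency(pd.concat(tables, ignore_index=True))

        symmetric = cohort("both")["valence_effect"].mean()
        positive_only = cohort("positive_only")["valence_effect"].mean()
        assert positive_only > 10.0
        assert positive_only > symmetric + 5.0
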