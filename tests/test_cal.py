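"""Dual-module learning agent: module contracts, discounting, regressors."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rulemem.cal import (CALParams, LOWER_BOUNDS, UPPER_BOUNDS,
                         compute_v, derive_regressors, init_agent, predict,
                         reevaluate_feedback, simulate, step,
                         update_memory_module, update_rule_module)
from rulemem.task import (NO_REWARD, REWARD, TrialSpec, build_structure,
                          enumerate_pairs, generate_main_sequence)
from conftest import MEMORY_PARAMS, RULE_PARAMS


def _trial(left, right, target="left", rewarded=None, misleading=False):
    if rewarded is None:
        rewarded = left if target == "left" else right
    return TrialSpec(index=1, run=1, left_stim=left, right_stim=right,
                     target_side=target, rewarded_stim=rewarded,
                     misleading=misleading)


class TestInitAndPredict:
    def test_neutral_agent_is_uninformed(self):
        state = init_agent(RULE_PARAMS)
        alpha, beta = state.attention()
        assert alpha == pytest.approx([1 / 3] * 3)
        assert beta == pytest.approx([1 / 3] * 3)
        assert not state.solved
        pred = predict(state, _trial(0, 7))
        assert pred.p_choose_left == pytest.approx(0.5)
        assert pred.p_choose_left_rule_only == pytest.approx(0.5)

    def test_out_of_bounds_params_rejected(self):
        with pytest.raises(ValueError):
            init_agent(CALParams(5.0, 0, 0, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            init_agent(CALParams(0, 0, -0.1, 0, 0, 0, 0))

    def test_memory_advantage_raises_choice_probability(self):
        state = init_agent(MEMORY_PARAMS)
        state.memory.assoc[3] = 0.9
        state.memory.assoc[4] = 0.1
        assert predict(state, _trial(3, 4)).p_choose_left > 0.5
        assert predict(state, _trial(4, 3)).p_choose_left < 0.5

    def test_mastered_rule_agent_beats_90pct_on_all_pairs(self, solved_rb_trace,
                                                          rb_structure):
        trace, seq = solved_rb_trace
        # replay the trace through the step API to obtain the final state
        state = init_agent(RULE_PARAMS)
        for t, c in zip(seq, trace["choice"].astype(int)):
            step(state, t, choice="left" if c == 0 else "right",
                 relevant_dims=rb_structure.relevant_dims)
        assert state.solved
        for r, n in enumerate_pairs(rb_structure):
            assert predict(state, _trial(r, n)).p_choose_left > 0.9


class TestErrorDiscounting:
    def test_pre_solution_feedback_taken_at_face_value(self):
        state = init_agent(RULE_PARAMS)
        assert reevaluate_feedback(state, NO_REWARD, False) == NO_REWARD
        assert reevaluate_feedback(state, REWARD, False) == REWARD

    def test_streak_of_three_confident_correct_solves(self):
        state = init_agent(RULE_PARAMS)
        state.confident_correct_streak = 2
        reevaluate_feedback(state, REWARD, True)
        assert state.solved

    def test_streak_resets_on_unconfident_choice(self):
        state = init_agent(RULE_PARAMS)
        state.confident_correct_streak = 2
        reevaluate_feedback(state, REWARD, False)
        assert state.confident_correct_streak == 0
        assert not state.solved

    def test_post_solution_noreward_reevaluated_as_reward(self):
        state = init_agent(RULE_PARAMS)
        state.solved = True
        assert reevaluate_feedback(state, NO_REWARD, False) == REWARD

    def test_solved_never_reverts(self):
        state = init_agent(RULE_PARAMS)
        state.solved = True
        for _ in range(5):
            reevaluate_feedback(state, NO_REWARD, False)
        assert state.solved

    def test_update_identical_for_reward_and_noreward_once_solved(self):
        """Bitwise state equality: the error-discounting invariant."""
        base = init_agent(RULE_PARAMS)
        base.solved = True
        base.rule.simple_rule_weights[:] = [0.3, -0.2, 0.1]
        base.rule.modulator_tallies[0, 1] = 0.8
        base.memory.assoc[:] = np.linspace(0.2, 0.9, 8)
        base.rule.accumulated_reward = 30.0
        s_nr, s_r = copy.deepcopy(base), copy.deepcopy(base)
        t_nr = _trial(0, 5, rewarded=5, misleading=True)   # objective NoReward
        t_r = _trial(0, 5, rewarded=0, misleading=False)   # objective Reward
        step(s_nr, t_nr, choice="left")
        step(s_r, t_r, choice="left")
        assert np.array_equal(s_nr.rule.simple_rule_weights,
                              s_r.rule.simple_rule_weights)
        assert np.array_equal(s_nr.rule.modulator_tallies,
                              s_r.rule.modulator_tallies)
        assert np.array_equal(s_nr.memory.assoc, s_r.memory.assoc)
        assert s_nr.rule.accumulated_reward == s_r.rule.accumulated_reward
        assert s_nr.memory.lam_t == s_r.memory.lam_t == (-3.0, -5.0)


class TestFeedbackProcessingStrength:
    def test_no_salience_means_constant_v(self):
        p = CALParams(0, 0, 0.0, 0.0, 0, 0, 0)
        state = init_agent(p)
        for acc in (0, 10, 100):
            state.rule.accumulated_reward = acc
            assert compute_v(state, REWARD) == 0.0
            assert compute_v(state, NO_REWARD) == 0.0

    def test_reward_lowers_v_when_rho_i_positive(self):
        state = init_agent(CALParams(0, 0, 1.0, 0.05, 0, 0, 0))
        assert compute_v(state, REWARD) < compute_v(state, NO_REWARD)

    def test_v_nondecreasing_in_accumulated_reward(self):
        state = init_agent(CALParams(0, 0, 0.5, 0.1, 0, 0, 0))
        for fb in (REWARD, NO_REWARD):
            vals = []
            for acc in range(0, 120, 5):
                state.rule.accumulated_reward = acc
                vals.append(compute_v(state, fb))
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_reward_noreward_gap_shrinks_with_accumulated_reward(self):
        state = init_agent(CALParams(0, 0, 1.0, 0.1, 0, 0, 0))
        gaps = []
        for acc in (0, 20, 60, 120):
            state.rule.accumulated_reward = acc
            gaps.append(compute_v(state, NO_REWARD) - compute_v(state, REWARD))
        assert all(b < a for a, b in zip(gaps, gaps[1:]))
        assert gaps[0] == pytest.approx(1.0)


class TestRuleModule:
    def test_attention_normalized_after_update(self):
        state = init_agent(RULE_PARAMS)
        update_rule_module(state, _trial(0, 7), "left", REWARD)
        alpha, beta = state.attention()
        assert alpha.sum() == pytest.approx(1.0)
        assert beta.sum() == pytest.approx(1.0)
        assert (alpha >= 0).all() and (beta >= 0).all()

    def test_consistent_dim0_rewards_concentrate_rule_attention(self):
        state = init_agent(CALParams(-2.0, -3.0, 0.5, 0.05, -4, 0, 0))
        # rewarded choices always share feature 1 on dim0, dims 1-2 vary
        stims = [0b100, 0b101, 0b110, 0b111] * 5
        for s in stims:
            update_rule_module(state, _trial(s, s ^ 0b100), "left", REWARD)
        alpha, _ = state.attention()
        assert np.argmax(alpha) == 0

    def test_modulator_attention_concentrates_after_rb_discovery(
            self, solved_rb_trace):
        trace, _ = solved_rb_trace
        post = trace[trace["solved"] == 1]
        beta_irrelevant = post["beta2"].to_numpy()  # irrelevant_dim = 2
        assert beta_irrelevant[-20:].mean() < 0.15


class TestMemoryModule:
    def test_lambda_fixed_after_solution(self):
        state = init_agent(MEMORY_PARAMS)
        state.solved = True
        update_memory_module(state, _trial(0, 7), "left", NO_REWARD)
        assert state.memory.lam_t == (-3.0, -5.0)

    def test_zero_difference_parameters_give_equal_encoding_strength(self):
        p = CALParams(0, 0, 0, 0, 1.0, 0.0, 0.0)
        state = init_agent(p)
        update_memory_module(state, _trial(0, 7), "left", REWARD)
        lam_ch, lam_un = state.memory.lam_t
        assert lam_ch == lam_un == p.lam
        update_memory_module(state, _trial(0, 7), "left", NO_REWARD)
        lam_ch, lam_un = state.memory.lam_t
        assert lam_ch == lam_un == p.lam

    def test_repeated_rewarded_choices_strengthen_association(self):
        state = init_agent(CALParams(0, 0, 0, 0, 2.0, 1.0, 0.5))
        vals = [state.memory.assoc[3]]
        for _ in range(10):
            update_memory_module(state, _trial(3, 4), "left", REWARD)
            vals.append(state.memory.assoc[3])
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0


class TestSimulate:
    def test_same_seed_identical_traces(self, rb_sequence):
        a = simulate(RULE_PARAMS, rb_sequence, seed=4)
        b = simulate(RULE_PARAMS, rb_sequence, seed=4)
        assert a.equals(b)

    def test_fast_path_matches_step_reference(self, rb_structure, rb_sequence):
        """The jitted kernel and the step-level API trace the same agent."""
        trace = simulate(RULE_PARAMS, rb_sequence, seed=11)
        state = init_agent(RULE_PARAMS)
        for i, (t, c) in enumerate(zip(rb_sequence,
                                       trace["choice"].astype(int))):
            rec = step(state, t, choice="left" if c == 0 else "right",
                       relevant_dims=rb_structure.relevant_dims)
            assert rec["p_left"] == pytest.approx(trace["p_left"].iloc[i],
                                                  abs=1e-12)
            assert rec["v"] == pytest.approx(trace["v"].iloc[i], abs=1e-12)
            assert float(rec["solved"]) == trace["solved"].iloc[i]
        assert state.rule.accumulated_reward == pytest.approx(
            trace["fb_subjective"].sum())

    def test_rule_agent_shows_plateau_then_ceiling(self, solved_rb_trace):
        trace, _ = solved_rb_trace
        correct = trace["correct"].to_numpy()
        solve = int(np.argmax(trace["solved"].to_numpy()))
        assert correct[:20].mean() < 0.75           # early guessing plateau
        assert correct[solve + 1:].mean() > 0.85    # near-ceiling after solving

    def test_memory_agent_learns_gradually(self, solved_u_trace):
        trace, _ = solved_u_trace
        correct = trace["correct"].to_numpy()
        thirds = [correct[:53].mean(), correct[53:106].mean(),
                  correct[106:].mean()]
        assert thirds[0] < thirds[2]
        assert thirds[2] > 0.75

    def test_rule_off_rb_agents_transition_more_slowly(self, rb_structure):
        """Module separability: without an effective rule module, RB can only
        be solved gradually through memory — the fitted transition width
        exceeds the rule-profile agents'."""
        from rulemem.changepoint import sample_posterior, subject_estimates
        mem_rb, rule_rb = [], []
        for rep in range(8):
            seq = generate_main_sequence(rb_structure, seed=600 + rep)
            mem_rb.append(simulate(MEMORY_PARAMS, seq, seed=rep)["correct"])
            rule_rb.append(simulate(RULE_PARAMS, seq, seed=rep)["correct"])
        widths = {}
        for name, mats in (("memory", mem_rb), ("rule", rule_rb)):
            d = sample_posterior(np.vstack(mats), n_iter=1200, burn_in=400,
                                 seed=17)
            est = subject_estimates(d)
            w = (est["t_s"] - est["t_o"])[~est["nonlearner"]]
            widths[name] = float(np.median(w))
        assert widths["memory"] > widths["rule"]

    def test_memory_off_keeps_u_task_at_chance(self, u_structure):
        """Module separability: the rule module cannot solve parity."""
        accs = []
        for rep in range(15):
            seq = generate_main_sequence(u_structure, seed=400 + rep)
            tr = simulate(RULE_PARAMS, seq, seed=rep)  # lam at lower range
            accs.append(tr["correct"].mean())
        mean = float(np.mean(accs))
        # 15 x 160 Bernoulli(0.5) trials: 99% CI half-width ~ 0.026
        assert abs(mean - 0.5) < 0.05


@settings(derandomize=True, max_examples=25, deadline=None)
@given(vec=st.tuples(*[st.floats(lo, hi, allow_nan=False)
                       for lo, hi in zip(LOWER_BOUNDS, UPPER_BOUNDS)]),
       seed=st.integers(0, 10_000))
def test_attention_normalization_invariant(vec, seed):
    """Sum(alpha) = Sum(beta) = 1 after every trial for any parameter draw."""
    params = CALParams(*vec)
    structure = build_structure("RB", irrelevant_dim=0)
    seq = generate_main_sequence(structure, seed=3)
    trace = simulate(params, seq, seed=seed)
    alphas = trace[["alpha0", "alpha1", "alpha2"]].to_numpy()
    betas = trace[["beta0", "beta1", "beta2"]].to_numpy()
    assert np.allclose(alphas.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(betas.sum(axis=1), 1.0, atol=1e-9)
    assert (alphas >= 0).all() and (betas >= 0).all()
    probs = trace[["p_left", "p_left_rule", "rule_confidence",
                   "memory_confidence"]].to_numpy()
    assert ((probs >= 0) & (probs <= 1)).all()


class TestRegressors:
    def test_zscoring_and_nuisance_flags(self, solved_rb_trace, rb_structure):
        trace, _ = solved_rb_trace
        tab = derive_regressors(trace, rb_structure, "RB")
        assert tab.loc[tab["nuisance"] == 1, "trial"].tolist() == \
            [1, 33, 65, 97, 129]
        keep = tab["nuisance"] == 0
        for col in ("choice_regressor", "outcome_regressor"):
            assert tab.loc[keep, col].mean() == pytest.approx(0.0, abs=1e-9)
            assert tab.loc[keep, col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_u_outcome_regressor_higher_on_reward_trials(self, solved_u_trace,
                                                         u_structure):
        trace, _ = solved_u_trace
        tab = derive_regressors(trace, u_structure, "U")
        pre = trace["solved"] == 0
        rew = trace["fb_subjective"] == 1
        assert (tab.loc[pre & rew, "outcome_regressor"].mean()
                > tab.loc[pre & ~rew, "outcome_regressor"].mean())

    def test_zero_variance_raises(self, solved_u_trace, u_structure):
        trace, _ = solved_u_trace
        flat = trace.copy()
        flat["memory_confidence"] = 0.5
        with pytest.raises(ValueError, match="zero-variance"):
            derive_regressors(flat, u_structure, "U")

    def test_unknown_task_rejected(self, solved_rb_trace, rb_structure):
        with pytest.raises(ValueError):
            derive_regressors(solved_rb_trace[0], rb_structure, "XY")
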