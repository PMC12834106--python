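"""Numba-jitted trial loop for the dual-module learning agent.

This is a fast path over identical arithmetic to the step-level reference
implementation in :mod:`rulemem.cal`; a regression test asserts the two
trajectories agree.  The kernel runs choose -> feedback -> re-evaluate ->
update for a whole trial array, either teacher-forced on observed choices
(model fitting) or sampling its own choices (simulation).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# output column layout of the trial trace
COLS = ("p_left", "p_left_rule", "choice", "correct", "fb_objective",
        "fb_subjective", "v", "lam_chosen", "lam_unchosen", "rule_confidence",
        "memory_confidence", "alpha0", "alpha1", "alpha2", "beta0", "beta1",
        "beta2", "solved", "streak", "eta_rule", "eta_mod")
N_COLS = len(COLS)

# signed +/-1 feature coding of the 8 stimuli (row = stimulus id)
FEATURES_PM = np.array(
    [[2 * ((s >> 2) & 1) - 1, 2 * ((s >> 1) & 1) - 1, 2 * (s & 1) - 1]
     for s in range(8)], dtype=np.float64)


@njit(cache=True)
def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def _softmax3(v0, v1, v2, sharp):
    m = max(v0, max(v1, v2))
    e0 = np.exp(sharp * (v0 - m))
    e1 = np.exp(sharp * (v1 - m))
    e2 = np.exp(sharp * (v2 - m))
    s = e0 + e1 + e2
    return e0 / s, e1 / s, e2 / s


@njit(cache=True)
def run_trials(params, consts, feats, trials, observed, u_rand, irrelevant_dim,
               out):
    """Run the agent over ``trials``, filling ``out`` (n, N_COLS).

    params : (gamma, omega, rho_i, rho_a, lam, lam_r, lam_nr)
    consts : (phi, c_att, conf_thresh, kappa_w, k_mem, post_lam_ch,
              post_lam_un, streak_criterion, gain_cap, mod_rate_scale,
              unchosen_offset)
    feats  : (8, 3) +/-1 feature matrix
    trials : int64 (n, 5): left_stim, right_stim, target_is_left,
             rewarded_stim, reset_state_before
    observed : int64 (n,) observed choice (0 left, 1 right) or -1 to simulate
    u_rand : (n,) uniforms consumed when simulating
    irrelevant_dim : ground-truth irrelevant dimension (-1 if none / U task)
    """
    gamma, omega, rho_i, rho_a, lam, lam_r, lam_nr = (
        params[0], params[1], params[2], params[3], params[4], params[5],
        params[6])
    phi, c_att, conf_thresh, kappa_w, k_mem = (
        consts[0], consts[1], consts[2], consts[3], consts[4])
    post_lam_ch, post_lam_un = consts[5], consts[6]
    streak_criterion = int(consts[7])
    gain_cap = consts[8]
    mod_rate_scale = consts[9]
    unchosen_offset = consts[10]

    w = np.zeros(3)
    u = np.zeros((3, 3))
    a = np.full(8, 0.5)
    acc = 0.0
    streak = 0
    solved = False

    n = trials.shape[0]
    for i in range(n):
        if trials[i, 4] == 1:  # phase boundary: fresh stimulus set
            for m in range(3):
                w[m] = 0.0
                for c in range(3):
                    u[m, c] = 0.0
            for s in range(8):
                a[s] = 0.5
            acc = 0.0
            streak = 0
            solved = False

        left = trials[i, 0]
        right = trials[i, 1]
        target_is_left = trials[i, 2]
        rewarded = trials[i, 3]

        # attention from current rule / modulator knowledge
        a0, a1, a2 = _softmax3(abs(w[0]), abs(w[1]), abs(w[2]), c_att)
        alpha = (a0, a1, a2)
        s0 = a1 * abs(u[1, 0]) + a2 * abs(u[2, 0])
        s1 = a0 * abs(u[0, 1]) + a2 * abs(u[2, 1])
        s2 = a0 * abs(u[0, 2]) + a1 * abs(u[1, 2])
        b0, b1, b2 = _softmax3(s0, s1, s2, c_att)
        beta = (b0, b1, b2)

        # contextual-control gain on the modulated term: opens as rewards
        # accumulate (rho_a), scaled by the modulation strength omega
        g_acc = gain_cap * np.tanh(rho_a * acc / gain_cap)
        gain = 2.0 * _sigmoid(omega + g_acc)

        # per-stimulus evidence from each module
        r_ev = np.empty(2)
        m_ev = np.empty(2)
        stims = (left, right)
        for k in range(2):
            s = stims[k]
            ev = 0.0
            for m in range(3):
                xm = feats[s, m]
                mod = 0.0
                for c in range(3):
                    if c != m:
                        mod += beta[c] * u[m, c] * feats[s, c]
                ev += alpha[m] * xm * (kappa_w * w[m] + gain * mod)
            r_ev[k] = ev
            m_ev[k] = 2.0 * a[s] - 1.0

        p_left = _sigmoid(phi * ((r_ev[0] + m_ev[0]) - (r_ev[1] + m_ev[1])))
        p_left_rule = _sigmoid(phi * (r_ev[0] - r_ev[1]))

        if observed[i] >= 0:
            choice = observed[i]
        else:
            choice = 0 if u_rand[i] < p_left else 1
        chosen = stims[choice]
        unchosen = stims[1 - choice]
        p_chosen = p_left if choice == 0 else 1.0 - p_left
        confident = p_chosen >= conf_thresh
        correct = (choice == 0) == (target_is_left == 1)
        fb_obj = 1.0 if chosen == rewarded else 0.0

        # error discounting: re-evaluate feedback, then advance the streak
        solved_pre = solved
        r = 1.0 if (solved_pre and fb_obj == 0.0) else fb_obj
        rule_conf = 0.0
        for m in range(3):
            if m != irrelevant_dim:
                rule_conf += 0.5 * (alpha[m] + beta[m])
        mem_conf = a[chosen]
        if not solved:
            if confident and correct:
                streak += 1
            else:
                streak = 0
            if streak >= streak_criterion:
                solved = True

        # trial-wise feedback-processing strength and learning rates
        v = rho_a * acc - rho_i * r * np.exp(-rho_a * acc)
        g = gain_cap * np.tanh(v / gain_cap)
        eta_rule = _sigmoid(-(gamma + g))
        eta_mod = mod_rate_scale * _sigmoid(omega + g)

        # configural memory (Hebbian, chosen/unchosen asymmetry)
        if solved:
            lam_ch = post_lam_ch
            lam_un = post_lam_un
        elif r == 1.0:
            lam_ch = lam + lam_r
            lam_un = lam - lam_r
        else:
            lam_ch = lam - lam_nr
            lam_un = lam + lam_nr
        a[chosen] += _sigmoid(lam_ch - k_mem) * (r - a[chosen])
        a[unchosen] += (_sigmoid(lam_un - k_mem - unchosen_offset)
                        * ((1.0 - r) - a[unchosen]))

        # rule module: reward -> chosen only; no-reward -> chosen then unchosen.
        # Simple-Rule weights are recency tallies of the labels; modulator
        # tallies are error-gated (driven by the rule module's own
        # mispredictions, computed before any within-trial update)
        if r == 1.0:
            ex_stims = (chosen, chosen)
            ex_ys = (1.0, 0.0)
            ex_yhat = (r_ev[choice], 0.0)
            n_ex = 1
        else:
            ex_stims = (chosen, unchosen)
            ex_ys = (-1.0, 1.0)
            ex_yhat = (r_ev[choice], r_ev[1 - choice])
            n_ex = 2
        for e in range(n_ex):
            s = ex_stims[e]
            y = ex_ys[e]
            yhat = min(1.0, max(-1.0, ex_yhat[e]))
            for m in range(3):
                xm = feats[s, m]
                w[m] += eta_rule * (y * xm - w[m])
                for c in range(3):
                    if c != m:
                        u[m, c] += eta_mod * (y - yhat) * xm * feats[s, c]

        acc += r

        out[i, 0] = p_left
        out[i, 1] = p_left_rule
        out[i, 2] = choice
        out[i, 3] = 1.0 if correct else 0.0
        out[i, 4] = fb_obj
        out[i, 5] = r
        out[i, 6] = v
        out[i, 7] = lam_ch
        out[i, 8] = lam_un
        out[i, 9] = rule_conf
        out[i, 10] = mem_conf
        out[i, 11] = alpha[0]
        out[i, 12] = alpha[1]
        out[i, 13] = alpha[2]
        out[i, 14] = beta[0]
        out[i, 15] = beta[1]
        out[i, 16] = beta[2]
        out[i, 17] = 1.0 if solved else 0.0
        out[i, 18] = streak
        out[i, 19] = eta_rule
        out[i, 20] = eta_mod
    return out
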