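"""Dual-module category/value abstraction learning (CAL) agent.

The agent combines two learning systems that map stimulus features onto
reward predictions:

* a **rule module** that learns first-order feature->outcome contingencies
  ("Simple Rules", weights ``w``) on each of the three dimensions, plus
  recency-weighted **modulator tallies** ``u[m, c]`` that track how the
  success of the rule on dimension ``m`` co-varies with the context feature
  on dimension ``c``.  The modulated term implements occasion setting: for a
  Type II (XOR) problem the cross-tally saturates and flips the simple rule
  in the right context, producing a sudden, step-like task solution.
* a **configural memory module** that associates each of the 8 whole
  stimulus configurations with its outcome via delta-rule (Hebbian-style)
  strengthening, producing gradual learning (the only route to solving a
  Type VI / parity problem).

Feedback processing is governed by the trial-wise strength

    v_t = rho_a * A_t - rho_i * r_t * exp(-rho_a * A_t)

with ``r_t`` the (subjective) reward of the trial, coded 1/0, and ``A_t``
the running sum of subjective rewards.  Reward (``rho_i > 0``) lowers v_t,
which narrows the generalization width ``gamma_t = gamma + v_t`` (stronger,
more precise Simple-Rule updates) and weakens modulator updates
(``omega_t = omega + v_t``); accumulated reward (``rho_a > 0``) raises v_t
over training, strengthening modulation as rewards accrue.

Once the agent has made three consecutive *confident* correct choices it
considers the task solved: no-reward feedback is thereafter re-evaluated as
consistent with its own choice (semi-self-supervised error discounting) and
the memory encoding strengths ``lam_t`` are fixed to (-3, -5) for the
chosen/unchosen stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import task as task_mod
from ._calcore import COLS, FEATURES_PM, run_trials
from .task import NO_REWARD, REWARD, ProblemStructure, TrialSpec

PARAM_NAMES = ("gamma", "omega", "rho_i", "rho_a", "lam", "lam_r", "lam_nr")
LOWER_BOUNDS = (-4.0, -5.0, 0.0, 0.0, -5.0, -3.0, -3.0)
UPPER_BOUNDS = (4.0, 5.0, 2.0, 0.2, 5.0, 3.0, 3.0)


@dataclass(frozen=True)
class CALParams:
    """The seven free parameters (all within the fitting box bounds)."""

    gamma: float      # similarity/contrast precision; larger -> weaker rules
    omega: float      # contextual modulation strength
    rho_i: float      # salience of the current gain (>= 0)
    rho_a: float      # salience of the accumulated gain (>= 0)
    lam: float        # configural memory strength (transformed scale)
    lam_r: float      # chosen-vs-unchosen encoding gain under reward
    lam_nr: float     # unchosen-vs-chosen encoding gain under no-reward

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def validate(self) -> "CALParams":
        for name, lo, hi in zip(PARAM_NAMES, LOWER_BOUNDS, UPPER_BOUNDS):
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(
                    f"parameter {name}={val} outside bounds [{lo}, {hi}]")
        return self

    @classmethod
    def from_array(cls, arr) -> "CALParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))


@dataclass
class ModelConfig:
    """Fixed model constants (not fitted)."""

    choice_sensitivity: float = 4.0    # logistic slope on the evidence difference
    attention_sharpness: float = 5.0   # softmax gain of alpha/beta weights
    confidence_threshold: float = 0.8  # "confident" choice for the solved streak
    rule_prior_weight: float = 0.15    # weight of the Simple-Rule term in evidence
    memory_rate_offset: float = 3.0    # lam_t -> rate via sigmoid(lam_t - offset)
    post_solution_lam: tuple[float, float] = (-3.0, -5.0)  # chosen, unchosen
    streak_criterion: int = 3
    gain_cap: float = 3.0              # saturation of the v_t -> rate compression
    modulation_rate_scale: float = 0.25  # ceiling of the modulator tally rate
    unchosen_encoding_offset: float = 1.0  # constant attenuation of unchosen encoding

    def as_array(self) -> np.ndarray:
        return np.array([self.choice_sensitivity, self.attention_sharpness,
                         self.confidence_threshold, self.rule_prior_weight,
                         self.memory_rate_offset, self.post_solution_lam[0],
                         self.post_solution_lam[1],
                         float(self.streak_criterion), self.gain_cap,
                         self.modulation_rate_scale,
                         self.unchosen_encoding_offset], dtype=float)


DEFAULT_CONFIG = ModelConfig()


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def _softmax(values, sharp):
    v = np.asarray(values, dtype=float)
    e = np.exp(sharp * (v - v.max()))
    return e / e.sum()


@dataclass
class RuleState:
    simple_rule_weights: np.ndarray      # w, shape (3,)
    modulator_tallies: np.ndarray        # u, shape (3, 3); u[m, m] unused
    accumulated_reward: float = 0.0

    @property
    def alpha(self) -> np.ndarray:
        return _softmax(np.abs(self.simple_rule_weights),
                        DEFAULT_CONFIG.attention_sharpness)


@dataclass
class MemoryState:
    assoc: np.ndarray                    # predicted reward probability per stimulus
    lam_t: tuple[float, float] = (0.0, 0.0)


@dataclass
class AgentState:
    params: CALParams
    rule: RuleState
    memory: MemoryState
    config: ModelConfig
    confident_correct_streak: int = 0
    solved: bool = False
    trial: int = 0

    # -- derived attention ------------------------------------------------
    def attention(self) -> tuple[np.ndarray, np.ndarray]:
        """(alpha, beta): rule and modulator attention weights (each sums to 1)."""
        c = self.config.attention_sharpness
        w = self.rule.simple_rule_weights
        u = self.rule.modulator_tallies
        alpha = _softmax(np.abs(w), c)
        s = np.zeros(3)
        for cdim in range(3):
            for m in range(3):
                if m != cdim:
                    s[cdim] += alpha[m] * abs(u[m, cdim])
        beta = _softmax(s, c)
        return alpha, beta


def init_agent(params: CALParams, config: ModelConfig | None = None) -> AgentState:
    """Fresh agent: uniform attention, neutral rules and memory, not solved."""
    params.validate()
    return AgentState(
        params=params,
        rule=RuleState(simple_rule_weights=np.zeros(3),
                       modulator_tallies=np.zeros((3, 3))),
        memory=MemoryState(assoc=np.full(8, 0.5)),
        config=config or ModelConfig())


def _modulation_gain(state: AgentState) -> float:
    """Contextual-control gain on the modulated rule term; opens with
    accumulated reward (rho_a) at strength omega."""
    p = state.params
    cap = state.config.gain_cap
    g_acc = cap * math.tanh(p.rho_a * state.rule.accumulated_reward / cap)
    return 2.0 * _sigmoid(p.omega + g_acc)


def _rule_evidence(state: AgentState, stim: int,
                   alpha: np.ndarray, beta: np.ndarray, gain: float) -> float:
    w = state.rule.simple_rule_weights
    u = state.rule.modulator_tallies
    kw = state.config.rule_prior_weight
    x = FEATURES_PM[stim]
    ev = 0.0
    for m in range(3):
        mod = sum(beta[c] * u[m, c] * x[c] for c in range(3) if c != m)
        ev += alpha[m] * x[m] * (kw * w[m] + gain * mod)
    return ev


def _memory_evidence(state: AgentState, stim: int) -> float:
    return 2.0 * state.memory.assoc[stim] - 1.0


@dataclass(frozen=True)
class Prediction:
    p_choose_left: float
    p_choose_left_rule_only: float
    rule_pred: dict[int, float]          # per-stimulus rule-module evidence
    mem_pred: dict[int, float]           # per-stimulus memory reward probability


def predict(state: AgentState, trial: TrialSpec) -> Prediction:
    """Choice probabilities from the combined (and rule-only) evidence."""
    alpha, beta = state.attention()
    phi = state.config.choice_sensitivity
    gain = _modulation_gain(state)
    rl = _rule_evidence(state, trial.left_stim, alpha, beta, gain)
    rr = _rule_evidence(state, trial.right_stim, alpha, beta, gain)
    ml = _memory_evidence(state, trial.left_stim)
    mr = _memory_evidence(state, trial.right_stim)
    return Prediction(
        p_choose_left=_sigmoid(phi * ((rl + ml) - (rr + mr))),
        p_choose_left_rule_only=_sigmoid(phi * (rl - rr)),
        rule_pred={trial.left_stim: rl, trial.right_stim: rr},
        mem_pred={trial.left_stim: state.memory.assoc[trial.left_stim],
                  trial.right_stim: state.memory.assoc[trial.right_stim]})


def reevaluate_feedback(state: AgentState, objective_feedback: str,
                        was_correct_and_confident: bool) -> str:
    """Subjective feedback + streak/solved update (error discounting).

    Pre-solution the feedback is taken at face value and the confident-correct
    streak advances; once solved, NoReward is re-evaluated as Reward.  The
    re-evaluation uses the solved state *entering* the trial, so the trial
    that completes the streak still processes its objective feedback.
    """
    subjective = (REWARD if (state.solved and objective_feedback == NO_REWARD)
                  else objective_feedback)
    if not state.solved:
        if was_correct_and_confident:
            state.confident_correct_streak += 1
        else:
            state.confident_correct_streak = 0
        if state.confident_correct_streak >= state.config.streak_criterion:
            state.solved = True
    return subjective


def compute_v(state: AgentState, subjective_feedback: str) -> float:
    """Trial-wise feedback-processing strength v_t (reward coded +1)."""
    r = 1.0 if subjective_feedback == REWARD else 0.0
    p = state.params
    acc = state.rule.accumulated_reward
    return p.rho_a * acc - p.rho_i * r * math.exp(-p.rho_a * acc)


def _learning_rates(state: AgentState, v: float) -> tuple[float, float]:
    cap = state.config.gain_cap
    g = cap * math.tanh(v / cap)
    eta_rule = _sigmoid(-(state.params.gamma + g))
    eta_mod = state.config.modulation_rate_scale * _sigmoid(state.params.omega + g)
    return eta_rule, eta_mod


def update_rule_module(state: AgentState, trial: TrialSpec, choice: str,
                       subjective_feedback: str, v: float | None = None) -> AgentState:
    """Simple-Rule and modulator-tally updates.

    Reward: only the chosen stimulus is processed (label +1).  NoReward: the
    chosen stimulus is processed first (label -1), then the unchosen (+1).
    Simple-Rule weights are recency tallies of the labels; modulator tallies
    are error-gated (driven by the rule module's own misprediction, evaluated
    before any within-trial update), so they accumulate while the modulated
    rule mispredicts and freeze once it accounts for the feedback.
    """
    if v is None:
        v = compute_v(state, subjective_feedback)
    eta_rule, eta_mod = _learning_rates(state, v)
    chosen = trial.stim_on(choice)
    unchosen = trial.stim_on("right" if choice == "left" else "left")
    if subjective_feedback == REWARD:
        examples = [(chosen, 1.0)]
    else:
        examples = [(chosen, -1.0), (unchosen, 1.0)]
    alpha, beta = state.attention()
    gain = _modulation_gain(state)
    yhats = [max(-1.0, min(1.0, _rule_evidence(state, stim, alpha, beta, gain)))
             for stim, _ in examples]
    w = state.rule.simple_rule_weights
    u = state.rule.modulator_tallies
    for (stim, y), yhat in zip(examples, yhats):
        x = FEATURES_PM[stim]
        for m in range(3):
            w[m] += eta_rule * (y * x[m] - w[m])
            for c in range(3):
                if c != m:
                    u[m, c] += eta_mod * (y - yhat) * x[m] * x[c]
    return state


def update_memory_module(state: AgentState, trial: TrialSpec, choice: str,
                         subjective_feedback: str) -> AgentState:
    """Configural association update with chosen/unchosen asymmetric strength."""
    p = state.params
    cfg = state.config
    r = 1.0 if subjective_feedback == REWARD else 0.0
    if state.solved:
        lam_ch, lam_un = cfg.post_solution_lam
    elif r == 1.0:
        lam_ch, lam_un = p.lam + p.lam_r, p.lam - p.lam_r
    else:
        lam_ch, lam_un = p.lam - p.lam_nr, p.lam + p.lam_nr
    chosen = trial.stim_on(choice)
    unchosen = trial.stim_on("right" if choice == "left" else "left")
    a = state.memory.assoc
    k = cfg.memory_rate_offset
    a[chosen] += _sigmoid(lam_ch - k) * (r - a[chosen])
    a[unchosen] += (_sigmoid(lam_un - k - cfg.unchosen_encoding_offset)
                    * ((1.0 - r) - a[unchosen]))
    state.memory.lam_t = (lam_ch, lam_un)
    return state


def step(state: AgentState, trial: TrialSpec, choice: str | None = None,
         rng: np.random.Generator | None = None,
         relevant_dims: tuple[int, ...] | None = None) -> dict:
    """One full trial: choose, resolve feedback, re-evaluate, update.

    If ``choice`` is None the agent samples its own choice (requires ``rng``).
    Returns the per-trial record (same quantities as the fast-path trace).
    """
    pred = predict(state, trial)
    if choice is None:
        choice = "left" if rng.random() < pred.p_choose_left else "right"
    p_chosen = pred.p_choose_left if choice == "left" else 1.0 - pred.p_choose_left
    confident = p_chosen >= state.config.confidence_threshold
    correct = choice == trial.target_side
    fb = task_mod.resolve_feedback(trial, choice)

    alpha, beta = state.attention()
    if relevant_dims is None:
        relevant_dims = (0, 1, 2)
    rule_conf = float(sum(0.5 * (alpha[m] + beta[m]) for m in relevant_dims))
    mem_conf = float(state.memory.assoc[trial.stim_on(choice)])

    subjective = reevaluate_feedback(state, fb, confident and correct)
    v = compute_v(state, subjective)
    update_memory_module(state, trial, choice, subjective)
    update_rule_module(state, trial, choice, subjective, v=v)
    state.rule.accumulated_reward += 1.0 if subjective == REWARD else 0.0
    state.trial += 1
    return {"p_left": pred.p_choose_left,
            "p_left_rule": pred.p_choose_left_rule_only,
            "choice": choice, "correct": correct,
            "fb_objective": fb, "fb_subjective": subjective, "v": v,
            "lam_chosen": state.memory.lam_t[0],
            "lam_unchosen": state.memory.lam_t[1],
            "rule_confidence": rule_conf, "memory_confidence": mem_conf,
            "alpha": alpha, "beta": beta, "solved": state.solved,
            "streak": state.confident_correct_streak}


# ---------------------------------------------------------------------------
# fast-path simulation over trial arrays

def trials_to_arrays(trials, reset_at: set[int] | None = None) -> np.ndarray:
    """(n, 5) int64 array: left, right, target_is_left, rewarded, reset flag."""
    arr = np.zeros((len(trials), 5), dtype=np.int64)
    for i, t in enumerate(trials):
        arr[i, 0] = t.left_stim
        arr[i, 1] = t.right_stim
        arr[i, 2] = 1 if t.target_side == "left" else 0
        arr[i, 3] = t.rewarded_stim
        arr[i, 4] = 1 if (reset_at and i in reset_at) else 0
    return arr


def run_agent(params: CALParams, trial_arr: np.ndarray,
              irrelevant_dim: int | None,
              observed: np.ndarray | None = None,
              seed: int | None = None,
              config: ModelConfig | None = None) -> np.ndarray:
    """Raw trace matrix (n, len(COLS)) from the jitted kernel."""
    cfg = config or DEFAULT_CONFIG
    n = trial_arr.shape[0]
    if observed is None:
        observed = np.full(n, -1, dtype=np.int64)
        if seed is None:
            raise ValueError("seed required when simulating choices")
        u_rand = np.random.default_rng(seed).random(n)
    else:
        observed = np.asarray(observed, dtype=np.int64)
        u_rand = np.zeros(n)
    out = np.empty((n, len(COLS)))
    run_trials(params.as_array(), cfg.as_array(), FEATURES_PM, trial_arr,
               observed, u_rand, -1 if irrelevant_dim is None else irrelevant_dim,
               out)
    return out


def simulate(params: CALParams, sequence, seed: int,
             config: ModelConfig | None = None) -> pd.DataFrame:
    """Simulate the agent over a TrialSequence; deterministic given seed."""
    structure: ProblemStructure = sequence.structure
    trial_arr = trials_to_arrays(list(sequence))
    out = run_agent(params, trial_arr, structure.irrelevant_dim, seed=seed,
                    config=config)
    df = pd.DataFrame(out, columns=list(COLS))
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    df.insert(1, "run", [t.run for t in sequence])
    return df


# ---------------------------------------------------------------------------
# model-informed trial-wise regressors

RUN_STARTS = (1, 33, 65, 97, 129)


def derive_regressors(trace: pd.DataFrame, structure: ProblemStructure,
                      task: str) -> pd.DataFrame:
    """Task-specific choice/outcome regressors, z-scored within participant.

    Choice phase: rule confidence p_t(A) in RB, memory confidence p_t(C) in U.
    Outcome phase: v_t in RB, lam_t (chosen coding) in U.  The first trial of
    each of the 5 runs is flagged as nuisance; z-scoring (mean 0, SD 1) is
    over the non-nuisance trials.
    """
    task = task.upper()
    if task not in ("RB", "U"):
        raise ValueError(f"task must be 'RB' or 'U', got {task!r}")
    choice_col = "rule_confidence" if task == "RB" else "memory_confidence"
    outcome_col = "v" if task == "RB" else "lam_chosen"
    tab = pd.DataFrame({
        "trial": trace["trial"].to_numpy(),
        "run": trace["run"].to_numpy(),
        "choice_regressor_raw": trace[choice_col].to_numpy(dtype=float),
        "outcome_regressor_raw": trace[outcome_col].to_numpy(dtype=float),
    })
    tab["nuisance"] = tab["trial"].isin(RUN_STARTS).astype(int)
    keep = tab["nuisance"] == 0
    for raw, z in (("choice_regressor_raw", "choice_regressor"),
                   ("outcome_regressor_raw", "outcome_regressor")):
        vals = tab.loc[keep, raw].to_numpy()
        sd = vals.std()
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(
                f"zero-variance regressor {raw!r} ({task} task): the model-"
                "derived quantity is constant over non-nuisance trials")
        tab[z] = (tab[raw] - vals.mean()) / sd
    return tab


def regressor_three_column(table: pd.DataFrame, column: str,
                           onsets=None, duration: float = 0.0) -> pd.DataFrame:
    """Onset/duration/value export (non-nuisance rows) for fMRI GLM software."""
    keep = table["nuisance"] == 0
    ons = (table.loc[keep, "trial"].to_numpy(dtype=float) if onsets is None
           else np.asarray(onsets, dtype=float)[keep.to_numpy()])
    return pd.DataFrame({"onset": ons, "duration": duration,
                         "value": table.loc[keep, column].to_numpy()})
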