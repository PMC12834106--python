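"""Category structures and trial scheduling for the two-alternative reward task.

Eight stimuli enumerate all binary triples over three feature dimensions.
Two problem structures are supported:

* ``RB`` ("rule based", Shepard Type II): reward category is the XOR of two
  relevant dimensions; the third dimension is irrelevant.
* ``U`` ("unstructured", Shepard Type VI): reward category is the parity of
  all three dimensions; no single dimension or pair of dimensions is
  predictive.

The main task presents the 16 cross-category stimulus pairs 10 times each
(160 trials in 5 runs of 32), with 2 of each pair's 10 repetitions scheduled
as misleading (feedback rewards the objectively wrong stimulus; 80% valid
feedback overall) and no pair repeated on consecutive trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

N_DIMS = 3
N_STIMULI = 8
N_PAIRS = 16
PAIR_REPETITIONS = 10
MISLEADING_PER_PAIR = 2
N_TRIALS_MAIN = N_PAIRS * PAIR_REPETITIONS
N_RUNS = 5
RUN_LENGTH = N_TRIALS_MAIN // N_RUNS

REWARD = "Reward"
NO_REWARD = "NoReward"


def stimulus_features(stim_id: int) -> tuple[int, int, int]:
    """Binary feature triple (dim0, dim1, dim2) of stimulus ``stim_id`` (0-7)."""
    if not 0 <= stim_id < N_STIMULI:
        raise ValueError(f"stimulus id must be in 0..7, got {stim_id}")
    return ((stim_id >> 2) & 1, (stim_id >> 1) & 1, stim_id & 1)


def stimulus_id(features) -> int:
    f0, f1, f2 = features
    return (f0 << 2) | (f1 << 1) | f2


@dataclass(frozen=True)
class ProblemStructure:
    """Category assignment of the 8 stimuli.

    ``kind`` is ``"RB"`` or ``"U"``; ``irrelevant_dim`` names the non-predictive
    dimension for RB (``None`` for U); ``polarity`` selects which XOR/parity
    class is the Reward category.
    """

    kind: str
    irrelevant_dim: int | None
    polarity: int
    category_of: dict[int, str] = field(compare=False)

    @property
    def relevant_dims(self) -> tuple[int, ...]:
        if self.kind == "RB":
            return tuple(d for d in range(N_DIMS) if d != self.irrelevant_dim)
        return tuple(range(N_DIMS))

    def reward_stimuli(self) -> list[int]:
        return [s for s in range(N_STIMULI) if self.category_of[s] == REWARD]

    def noreward_stimuli(self) -> list[int]:
        return [s for s in range(N_STIMULI) if self.category_of[s] == NO_REWARD]


def build_structure(kind: str, irrelevant_dim: int | None = None,
                    polarity: int = 0) -> ProblemStructure:
    """Construct an RB (Type II XOR) or U (Type VI parity) category structure.

    For RB, stimuli whose two relevant features agree (XOR == 0) form one
    category; ``polarity`` flips which one is Reward.  For U, stimuli with
    even feature sum form one parity class; ``polarity`` flips the labels.
    """
    kind = kind.upper()
    if kind not in ("RB", "U"):
        raise ValueError(f"kind must be 'RB' or 'U', got {kind!r}")
    if polarity not in (0, 1):
        raise ValueError(f"polarity must be 0 or 1, got {polarity}")
    if kind == "RB":
        if irrelevant_dim is None:
            raise ValueError("RB structure requires an irrelevant_dim")
        if not 0 <= irrelevant_dim < N_DIMS:
            raise ValueError(f"irrelevant_dim must be in 0..2, got {irrelevant_dim}")
    else:
        irrelevant_dim = None

    category_of: dict[int, str] = {}
    for s in range(N_STIMULI):
        feats = stimulus_features(s)
        if kind == "RB":
            rel = [feats[d] for d in range(N_DIMS) if d != irrelevant_dim]
            value = rel[0] ^ rel[1]
        else:
            value = (feats[0] + feats[1] + feats[2]) % 2
        category_of[s] = REWARD if value == polarity else NO_REWARD
    return ProblemStructure(kind=kind, irrelevant_dim=irrelevant_dim,
                            polarity=polarity, category_of=category_of)


def enumerate_pairs(structure: ProblemStructure) -> list[tuple[int, int]]:
    """All (Reward-member, NoReward-member) cross-category pairs (16 of them)."""
    pairs = [(r, n) for r, n in itertools.product(
        structure.reward_stimuli(), structure.noreward_stimuli())]
    assert len(pairs) == N_PAIRS
    return pairs


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: pair identity, sides, feedback schedule."""

    index: int                 # 1-based trial number
    run: int                   # 1..5
    left_stim: int
    right_stim: int
    target_side: str           # side of the true Reward-category stimulus
    rewarded_stim: int         # choosing this stimulus yields Reward feedback
    misleading: bool
    phase: str = "main"

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.left_stim, self.right_stim)))

    @property
    def target_stim(self) -> int:
        return self.left_stim if self.target_side == "left" else self.right_stim

    def stim_on(self, side: str) -> int:
        return self.left_stim if side == "left" else self.right_stim


@dataclass(frozen=True)
class TrialSequence:
    trials: tuple[TrialSpec, ...]
    structure: ProblemStructure
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]


def _schedule_pair_order(pair_ids: np.ndarray, rng: np.random.Generator,
                         max_restarts: int) -> np.ndarray:
    """Order 160 pair tokens with no immediate repeats, by constrained draws.

    Draws the next pair proportionally to its remaining count among pairs
    different from the previous one; dead ends trigger a restart.
    """
    counts0 = np.bincount(pair_ids, minlength=N_PAIRS)
    for _ in range(max_restarts):
        counts = counts0.copy()
        order = np.empty(counts.sum(), dtype=np.int64)
        prev = -1
        ok = True
        for i in range(order.size):
            weights = counts.astype(float)
            if prev >= 0:
                weights[prev] = 0.0
            total = weights.sum()
            if total <= 0:
                ok = False
                break
            pick = rng.choice(N_PAIRS, p=weights / total)
            order[i] = pick
            counts[pick] -= 1
            prev = pick
        if ok:
            return order
    raise RuntimeError(
        f"could not schedule a no-adjacent-repeat pair order in {max_restarts} restarts")


def generate_main_sequence(structure: ProblemStructure, seed: int,
                           max_restarts: int = 10_000) -> TrialSequence:
    """160-trial main sequence: 16 pairs x 10, 2 misleading each, no repeats.

    Misleading trials are placed uniformly at random among each pair's 10
    repetitions; the left/right side of the Reward-category member is a fair
    coin per trial.
    """
    rng = np.random.default_rng(seed)
    pairs = enumerate_pairs(structure)
    tokens = np.repeat(np.arange(N_PAIRS), PAIR_REPETITIONS)
    order = _schedule_pair_order(tokens, rng, max_restarts)

    # choose which of each pair's 10 occurrences carry misleading feedback
    misleading_slots = {p: set(rng.choice(PAIR_REPETITIONS, size=MISLEADING_PER_PAIR,
                                          replace=False).tolist())
                        for p in range(N_PAIRS)}
    seen = np.zeros(N_PAIRS, dtype=int)
    trials = []
    for i, p in enumerate(order):
        reward_member, noreward_member = pairs[p]
        misleading = seen[p] in misleading_slots[p]
        seen[p] += 1
        target_side = "left" if rng.random() < 0.5 else "right"
        left, right = ((reward_member, noreward_member) if target_side == "left"
                       else (noreward_member, reward_member))
        rewarded = noreward_member if misleading else reward_member
        trials.append(TrialSpec(
            index=i + 1, run=i // RUN_LENGTH + 1,
            left_stim=left, right_stim=right, target_side=target_side,
            rewarded_stim=rewarded, misleading=misleading, phase="main"))
    return TrialSequence(trials=tuple(trials), structure=structure, seed=seed)


def resolve_feedback(trial: TrialSpec, choice: str) -> str:
    """Scheduled feedback for choosing ``choice`` ('left'/'right') on ``trial``."""
    if choice not in ("left", "right"):
        raise ValueError(f"choice must be 'left' or 'right', got {choice!r}")
    return REWARD if trial.stim_on(choice) == trial.rewarded_stim else NO_REWARD


@dataclass
class PretrainingResult:
    trials: list[TrialSpec]
    choices: list[str]
    feedback: list[str]
    n_deterministic: int
    converged: bool

    def __len__(self):
        return len(self.trials)


def run_pretraining(structure: ProblemStructure, agent, criterion: int = 15,
                    probabilistic_n: int = 40, seed: int = 0,
                    trial_cap: int = 1000) -> PretrainingResult:
    """To-criterion practice task: deterministic phase, then 80% feedback.

    The deterministic phase presents random cross-category pairs (no immediate
    pair repeat) with always-valid feedback and stops at the first trial
    completing ``criterion`` consecutive correct choices (or at ``trial_cap``,
    flagged as non-converged).  A probabilistic familiarization phase of
    ``probabilistic_n`` trials follows, each misleading with probability 0.2.

    ``agent`` is called as ``agent(trial, history)`` where ``history`` is the
    list of (trial, choice, feedback) so far, and must return 'left'/'right'.
    """
    rng = np.random.default_rng(seed)
    pairs = enumerate_pairs(structure)
    trials: list[TrialSpec] = []
    choices: list[str] = []
    feedback: list[str] = []
    history: list[tuple] = []

    def make_trial(index: int, phase: str, misleading: bool, prev_pair) -> TrialSpec:
        while True:
            p = int(rng.integers(N_PAIRS))
            if pairs[p] != prev_pair:
                break
        reward_member, noreward_member = pairs[p]
        target_side = "left" if rng.random() < 0.5 else "right"
        left, right = ((reward_member, noreward_member) if target_side == "left"
                       else (noreward_member, reward_member))
        rewarded = noreward_member if misleading else reward_member
        return TrialSpec(index=index, run=1, left_stim=left, right_stim=right,
                         target_side=target_side, rewarded_stim=rewarded,
                         misleading=misleading, phase=phase)

    streak = 0
    converged = False
    prev_pair = None
    while len(trials) < trial_cap:
        t = make_trial(len(trials) + 1, "pretraining_deterministic", False, prev_pair)
        prev_pair = t.pair
        c = agent(t, history)
        fb = resolve_feedback(t, c)
        trials.append(t); choices.append(c); feedback.append(fb)
        history.append((t, c, fb))
        streak = streak + 1 if c == t.target_side else 0
        if streak >= criterion:
            converged = True
            break
    n_det = len(trials)

    for _ in range(probabilistic_n):
        misleading = bool(rng.random() < MISLEADING_PER_PAIR / PAIR_REPETITIONS)
        t = make_trial(len(trials) + 1, "pretraining_probabilistic", misleading, prev_pair)
        prev_pair = t.pair
        c = agent(t, history)
        fb = resolve_feedback(t, c)
        trials.append(t); choices.append(c); feedback.append(fb)
        history.append((t, c, fb))

    return PretrainingResult(trials=trials, choices=choices, feedback=feedback,
                             n_deterministic=n_det, converged=converged)


# ---------------------------------------------------------------------------
# tabular I/O

def _features_str(stim: int) -> str:
    return "".join(str(f) for f in stimulus_features(stim))


def sequence_to_frame(seq, choices=None, feedback=None) -> pd.DataFrame:
    """Flatten a TrialSequence (or list of TrialSpec) into a tidy trial table."""
    trials = list(seq)
    rows = []
    for i, t in enumerate(trials):
        rows.append({
            "index": t.index, "run": t.run, "phase": t.phase,
            "left_features": _features_str(t.left_stim),
            "right_features": _features_str(t.right_stim),
            "left_stim": t.left_stim, "right_stim": t.right_stim,
            "target_side": t.target_side, "rewarded_stim": t.rewarded_stim,
            "misleading": int(t.misleading),
            "choice": choices[i] if choices is not None else "",
            "feedback": feedback[i] if feedback is not None else "",
        })
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame) -> list[TrialSpec]:
    cols = {c: df[c].tolist() for c in
            ("index", "run", "left_stim", "right_stim", "target_side",
             "rewarded_stim", "misleading", "phase")}
    return [TrialSpec(index=int(cols["index"][i]), run=int(cols["run"][i]),
                      left_stim=int(cols["left_stim"][i]),
                      right_stim=int(cols["right_stim"][i]),
                      target_side=str(cols["target_side"][i]),
                      rewarded_stim=int(cols["rewarded_stim"][i]),
                      misleading=bool(int(cols["misleading"][i])),
                      phase=str(cols["phase"][i]))
            for i in range(len(df))]


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def structure_config(structure: ProblemStructure, seed: int | None = None) -> str:
    """Plain-text key=value serialization of a structure (and optional seed)."""
    lines = [f"kind={structure.kind}",
             f"irrelevant_dim={'' if structure.irrelevant_dim is None else structure.irrelevant_dim}",
             f"polarity={structure.polarity}"]
    if seed is not None:
        lines.append(f"seed={seed}")
    return "\n".join(lines) + "\n"


def parse_structure_config(text: str) -> ProblemStructure:
    kv = dict(line.split("=", 1) for line in text.strip().splitlines())
    irr = kv.get("irrelevant_dim", "")
    return build_structure(kv["kind"], int(irr) if irr != "" else None,
                          int(kv.get("polarity", 0)))
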