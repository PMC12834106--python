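"""Synthetic participant cohorts with the statistical structure the analyses
assume: rule-profile learners (long guessing plateau, abrupt transition to
near-ceiling accuracy on the RB task), memory-profile learners (gradual
accuracy increase on the U task), non-learners (never reliably above
chance), and a changepoint-generative profile that bypasses the learning
agent and emits Bernoulli correctness directly from the changepoint model's
predicted-accuracy curve.

Parameter profiles are drawn uniformly within sub-ranges of the fitting
bounds; the profile centres follow the group means estimated in the study
this design emulates (current-gain salience ~0.87, accumulated-gain
salience ~0.08 for rule learners; chosen-reward encoding gain ~1.45 >
unchosen-no-reward gain ~0.66 for memory learners).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import task as task_mod
from .cal import CALParams, ModelConfig, init_agent, predict, simulate, step
from .changepoint import predicted_accuracy
from .fitting import ParticipantData
from .task import ProblemStructure, build_structure, generate_main_sequence

# uniform draw ranges per profile: (gamma, omega, rho_i, rho_a, lam, lam_r, lam_nr)
PROFILE_RANGES = {
    "rule": {
        "gamma": (-2.0, -0.5), "omega": (-4.0, -2.5),
        "rho_i": (0.6, 1.2), "rho_a": (0.05, 0.12),
        "lam": (-5.0, -4.0), "lam_r": (-0.3, 0.3), "lam_nr": (-0.3, 0.3),
    },
    "memory": {
        "gamma": (3.0, 4.0), "omega": (-5.0, -4.0),
        "rho_i": (0.0, 0.2), "rho_a": (0.0, 0.02),
        "lam": (-1.5, -0.3), "lam_r": (1.2, 1.8), "lam_nr": (0.4, 0.9),
    },
    "nonlearner": {
        "gamma": (3.5, 4.0), "omega": (-5.0, -4.8),
        "rho_i": (0.0, 0.05), "rho_a": (0.0, 0.01),
        "lam": (-5.0, -4.5), "lam_r": (-0.1, 0.1), "lam_nr": (-0.1, 0.1),
    },
}

# generative-profile onset/slope draw ranges
GENERATIVE_RANGES = {"o": (20, 90), "b": (0.1, 2.0)}


def sample_agent_params(profile: str, rng: np.random.Generator,
                        ranges: dict | None = None) -> CALParams:
    """Draw agent parameters uniformly within the profile's sub-ranges."""
    if ranges is None:
        if profile not in PROFILE_RANGES:
            raise ValueError(f"unknown profile {profile!r}")
        ranges = PROFILE_RANGES[profile]
    return CALParams(**{name: float(rng.uniform(*ranges[name]))
                        for name in ranges}).validate()


@dataclass
class CohortSpec:
    n_subjects: int
    task: str                                   # 'RB' or 'U'
    agent_profile: str                          # rule|memory|nonlearner|changepoint_generative
    nonlearner_fraction: float = 0.0
    seed: int = 0
    parameter_ranges: dict | None = None        # override PROFILE_RANGES entry
    generative_ranges: dict | None = None       # override GENERATIVE_RANGES
    with_pretraining: bool = False
    pretraining_probabilistic_n: int = 40
    pretraining_trial_cap: int = 300

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.nonlearner_fraction <= 1.0:
            raise ValueError("nonlearner_fraction must be in [0, 1]")
        self.task = self.task.upper()
        if self.task not in ("RB", "U"):
            raise ValueError(f"task must be 'RB' or 'U', got {self.task!r}")


@dataclass
class SyntheticSubject:
    subject: int
    structure: ProblemStructure
    profile: str
    params: CALParams | None
    true_onset: int | None                      # generative profile only
    true_slope: float | None
    sequence: object                            # main TrialSequence
    trace: pd.DataFrame                         # per-trial simulation trace
    pretraining: object | None = None           # PretrainingResult

    @property
    def correct(self) -> np.ndarray:
        return self.trace["correct"].to_numpy(dtype=float)

    def to_participant_data(self) -> ParticipantData:
        if self.pretraining is None:
            raise ValueError("subject was generated without pre-training")
        main_choices = ["left" if c == 0 else "right"
                        for c in self.trace["choice"].astype(int)]
        return ParticipantData(
            structure=self.structure,
            pre_trials=self.pretraining.trials,
            pre_choices=self.pretraining.choices,
            main_trials=list(self.sequence),
            main_choices=main_choices)


class _CALResponder:
    """Adapter exposing a learning agent as a pre-training responder callback.

    Processes each fed-back trial through the full agent step before choosing
    on the next one.
    """

    def __init__(self, params: CALParams, rng: np.random.Generator,
                 config: ModelConfig | None = None):
        self.state = init_agent(params, config)
        self.rng = rng
        self._n_seen = 0

    def __call__(self, trial, history):
        for t, c, fb in history[self._n_seen:]:
            step(self.state, t, choice=c, rng=self.rng)
            self._n_seen += 1
        p_left = predict(self.state, trial).p_choose_left
        return "left" if self.rng.random() < p_left else "right"


def _generate_structure(spec: CohortSpec, rng: np.random.Generator) -> ProblemStructure:
    polarity = int(rng.integers(2))
    if spec.task == "RB":
        # irrelevant dimension counterbalanced across subjects
        return build_structure("RB", irrelevant_dim=int(rng.integers(3)),
                               polarity=polarity)
    return build_structure("U", polarity=polarity)


def generate_cohort(spec: CohortSpec,
                    config: ModelConfig | None = None) -> list[SyntheticSubject]:
    """Simulate a cohort: one trial table, trace and ground truth per subject."""
    rng = np.random.default_rng(spec.seed)
    n_nonlearners = int(round(spec.n_subjects * spec.nonlearner_fraction))
    subjects = []
    for s in range(spec.n_subjects):
        structure = _generate_structure(spec, rng)
        seq_seed = int(rng.integers(2**31 - 1))
        sequence = generate_main_sequence(structure, seq_seed)
        profile = spec.agent_profile
        if profile != "changepoint_generative" and s < n_nonlearners:
            profile = "nonlearner"

        if profile == "changepoint_generative":
            granges = spec.generative_ranges or GENERATIVE_RANGES
            o = int(rng.integers(granges["o"][0], granges["o"][1] + 1))
            b = float(rng.uniform(*granges["b"]))
            T = len(sequence)
            t = np.arange(1, T + 1)
            p = predicted_accuracy(o, b, t)
            correct = (rng.random(T) < p).astype(float)
            trace = pd.DataFrame({
                "trial": t, "run": [tr.run for tr in sequence],
                "correct": correct,
                "choice": np.where(
                    correct == ((np.array([tr.target_side for tr in sequence])
                                 == "left").astype(float)), 0.0, 1.0),
            })
            subjects.append(SyntheticSubject(
                subject=s, structure=structure, profile=profile, params=None,
                true_onset=o, true_slope=b, sequence=sequence, trace=trace))
            continue

        params = sample_agent_params(profile, rng, spec.parameter_ranges)
        sim_seed = int(rng.integers(2**31 - 1))
        trace = simulate(params, sequence, seed=sim_seed, config=config)
        pre = None
        if spec.with_pretraining:
            responder = _CALResponder(params, np.random.default_rng(sim_seed + 1),
                                      config)
            pre = task_mod.run_pretraining(
                structure, responder,
                probabilistic_n=spec.pretraining_probabilistic_n,
                seed=int(rng.integers(2**31 - 1)),
                trial_cap=spec.pretraining_trial_cap)
        subjects.append(SyntheticSubject(
            subject=s, structure=structure, profile=profile, params=params,
            true_onset=None, true_slope=None, sequence=sequence, trace=trace,
            pretraining=pre))
    return subjects


def cohort_accuracy_matrix(subjects) -> np.ndarray:
    return np.vstack([s.correct for s in subjects])


def ground_truth_manifest(subjects) -> str:
    """JSON manifest of the cohort's ground truth."""
    entries = []
    for s in subjects:
        entries.append({
            "subject": s.subject,
            "profile": s.profile,
            "task": s.structure.kind,
            "irrelevant_dim": s.structure.irrelevant_dim,
            "polarity": s.structure.polarity,
            "params": (None if s.params is None else
                       {k: getattr(s.params, k) for k in
                        ("gamma", "omega", "rho_i", "rho_a", "lam", "lam_r",
                         "lam_nr")}),
            "true_onset": s.true_onset,
            "true_slope": s.true_slope,
            "nonlearner": s.profile == "nonlearner",
        })
    return json.dumps(entries, indent=2)
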