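"""Simulate the two synthetic cohorts the downstream analyses run on.

Rule-profile learners on the rule-based (Type II / XOR) task and
memory-profile learners on the unstructured (Type VI / parity) task, each
with a 10% fraction of non-learners, matching the study conditions the
analyses assume (160 trials, 16 pairs x 10, 80% valid feedback).

Writes per-subject trial tables, simulation traces and the ground-truth
manifest under results/cohorts/<task>/.
"""

from pathlib import Path

import numpy as np

from rulemem import task
from rulemem.cohort import CohortSpec, generate_cohort, ground_truth_manifest

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
N_SUBJECTS = 20
NONLEARNER_FRACTION = 0.1


def main():
    for kind, profile, seed in (("RB", "rule", 101), ("U", "memory", 202)):
        spec = CohortSpec(n_subjects=N_SUBJECTS, task=kind,
                          agent_profile=profile,
                          nonlearner_fraction=NONLEARNER_FRACTION, seed=seed)
        subjects = generate_cohort(spec)
        outdir = OUT / kind
        outdir.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            choices = ["left" if c == 0 else "right"
                       for c in s.trace["choice"].astype(int)]
            feedback = ["Reward" if f == 1 else "NoReward"
                        for f in s.trace["fb_objective"]]
            df = task.sequence_to_frame(s.sequence, choices, feedback)
            task.write_trial_table(df, outdir / f"subject_{s.subject:03d}.tsv")
            s.trace.to_csv(outdir / f"subject_{s.subject:03d}_trace.tsv",
                           sep="\t", index=False)
        (outdir / "ground_truth.json").write_text(ground_truth_manifest(subjects))
        acc = np.mean([s.correct.mean() for s in subjects])
        print(f"{kind}: {len(subjects)} subjects "
              f"({sum(s.profile == 'nonlearner' for s in subjects)} non-learners), "
              f"mean accuracy {acc:.3f} -> {outdir}")


if __name__ == "__main__":
    main()
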