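"""Posterior-predictive and process checks of the fitted model.

For each task: simulate new choice data from the fitted parameters on each
subject's own trial sequence, run the identical changepoint regression on
the simulated curves, and correlate the model's solution-trial estimates
with the data's (the posterior-predictive check).  Also exports the
solution-aligned feature-attention summary (rule-based agents should drop
attention to the irrelevant dimension after solving) and the z-scored
trial-wise fMRI regressor tables.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rulemem.cal import CALParams, derive_regressors, simulate
from rulemem.changepoint import AccuracyData, sample_posterior, subject_estimates
from rulemem.cohort import CohortSpec, generate_cohort
from rulemem.report import feature_attention_summary, model_data_agreement

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    for kind, profile, seed, cp_seed in (("RB", "rule", 77, 31),
                                         ("U", "memory", 42, 32)):
        fitdir = ROOT / "fits" / kind
        fits = sorted(fitdir.glob("subject_*.json"))
        if not fits:
            raise SystemExit("run 03_fit_cal.py first")
        spec = CohortSpec(n_subjects=len(fits), task=kind,
                          agent_profile=profile, seed=seed,
                          with_pretraining=True)
        subjects = generate_cohort(spec)

        data_mats, model_mats = [], []
        for s, f in zip(subjects, fits):
            params = CALParams(**json.loads(f.read_text())["params"])
            model_trace = simulate(params, s.sequence, seed=500 + s.subject)
            data_mats.append(s.correct)
            model_mats.append(model_trace["correct"].to_numpy())
        est_data = subject_estimates(sample_posterior(
            AccuracyData.from_matrix(np.vstack(data_mats)),
            n_iter=1500, burn_in=500, seed=cp_seed))
        est_model = subject_estimates(sample_posterior(
            AccuracyData.from_matrix(np.vstack(model_mats)),
            n_iter=1500, burn_in=500, seed=cp_seed + 1))
        outdir = ROOT / "checks" / kind
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"t_s_data": est_data["t_s"],
                      "t_s_model": est_model["t_s"]}).to_csv(
            outdir / "ppc_t_s.tsv", sep="\t", index=False)
        try:
            agree = model_data_agreement(est_model["t_s"], est_data["t_s"],
                                         sentinel=161)
            print(f"{kind}: model-vs-data t_s r = {agree['r']:.2f} "
                  f"(n = {agree['n']})")
        except ValueError as e:
            print(f"{kind}: t_s agreement not computable ({e})")

        # feature attention and regressor exports for the first learner
        s0 = subjects[0]
        t_s0 = int(est_data["t_s"].iloc[0])
        att = feature_attention_summary(
            s0.trace, s0.structure, t_s=t_s0,
            matched_dim=None if kind == "RB" else 0)
        att.to_csv(outdir / "feature_attention.tsv", sep="\t", index=False)
        reg = derive_regressors(s0.trace, s0.structure, kind)
        reg.to_csv(outdir / "regressors_subject000.tsv", sep="\t", index=False)
        if kind == "RB":
            pre = att[att["block"] <= 0]
            post = att[att["block"] >= 1]
            print(f"  irrelevant-dimension attention: "
                  f"{np.average(pre['irrelevant'], weights=pre['n_trials']):.3f} before vs "
                  f"{np.average(post['irrelevant'], weights=post['n_trials']):.3f} after t_s")


if __name__ == "__main__":
    main()
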