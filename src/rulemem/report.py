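"""Descriptive summaries and model checks: forward learning curves,
solution-aligned block coding, model-vs-data agreement on the solution
trial, and feature-attention summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .task import N_TRIALS_MAIN, ProblemStructure

BLOCK_SIZE_ALIGNED = 32
MIN_EDGE_TRIALS = 10
BLOCK_FLOOR = -2          # blocks <= -2 collapsed
BLOCK_CEIL = 5            # blocks >= 5 collapsed


def forward_curves(correct_matrix, block_size: int = 16) -> pd.DataFrame:
    """Per-subject and group-mean accuracy per forward block of trials."""
    y = np.asarray(correct_matrix, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    S, T = y.shape
    n_blocks = T // block_size
    rows = []
    for s in range(S):
        for b in range(n_blocks):
            rows.append({"subject": s, "block": b + 1,
                         "accuracy": float(np.nanmean(
                             y[s, b * block_size:(b + 1) * block_size]))})
    df = pd.DataFrame(rows)
    group = (df.groupby("block", as_index=False)["accuracy"].mean()
             .assign(subject="mean"))
    return pd.concat([df, group], ignore_index=True)


def solution_aligned_block(trial: np.ndarray, t_s: int,
                           n_trials: int | None = None) -> np.ndarray:
    """Block index relative to the solution trial.

    Trials are coded into 32-trial blocks such that ``t_s`` is the last
    trial of block 0.  The first and last ``MIN_EDGE_TRIALS`` trials are
    always coded before (block <= 0) / after (block >= 1) the solution, and
    blocks <= -2 / >= 5 are collapsed into single bins.  For non-learners
    pass the sentinel t_s = T + 1.
    """
    t = np.asarray(trial, dtype=int)
    if n_trials is None:
        n_trials = int(t.max())
    block = np.ceil((t - t_s) / BLOCK_SIZE_ALIGNED).astype(int)
    block = np.where(t <= MIN_EDGE_TRIALS, np.minimum(block, 0), block)
    block = np.where(t > n_trials - MIN_EDGE_TRIALS, np.maximum(block, 1), block)
    return np.clip(block, BLOCK_FLOOR, BLOCK_CEIL)


def solution_aligned_blocks(data: pd.DataFrame, t_s_by_subject: dict,
                            value_cols=("correct",),
                            n_trials: int = N_TRIALS_MAIN) -> pd.DataFrame:
    """Aggregate per-trial variables within solution-aligned blocks.

    ``data`` is a tidy frame with columns subject, trial and the value
    columns; returns per-subject per-block means plus trial counts.
    """
    df = data.copy()
    df["block"] = 0
    for sid, t_s in t_s_by_subject.items():
        m = df["subject"] == sid
        df.loc[m, "block"] = solution_aligned_block(
            df.loc[m, "trial"].to_numpy(), int(t_s), n_trials)
    agg = (df.groupby(["subject", "block"], as_index=False)
           .agg(**{c: (c, "mean") for c in value_cols},
                n_trials=("trial", "size")))
    return agg


def model_data_agreement(t_s_model, t_s_data,
                         sentinel: int | None = None) -> dict:
    """Pearson correlation between model and data solution-trial estimates.

    Non-learner sentinels (values > ``sentinel``-1, if given) are excluded
    pairwise.
    """
    a = np.asarray(t_s_model, dtype=float)
    b = np.asarray(t_s_data, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired estimates must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    if sentinel is not None:
        keep &= (a < sentinel) & (b < sentinel)
    if keep.sum() < 3:
        raise ValueError("need at least 3 valid pairs for a correlation")
    r, p = stats.pearsonr(a[keep], b[keep])
    return {"r": float(r), "p": float(p), "n": int(keep.sum()),
            "pairs": pd.DataFrame({"model": a[keep], "data": b[keep]})}


def feature_attention_summary(trace: pd.DataFrame,
                              structure: ProblemStructure,
                              t_s: int,
                              matched_dim: int | None = None,
                              n_trials: int = N_TRIALS_MAIN) -> pd.DataFrame:
    """Mean attention on relevant(-average) vs irrelevant dimension per
    solution-aligned block.

    Per trial the attention on dimension m is (alpha_m + beta_m) / 2; the
    relevant value averages the two truly relevant dimensions (RB).  For U
    traces all dimensions are relevant; ``matched_dim`` names the spatially
    matched dimension used in place of RB's irrelevant one.
    """
    if structure.kind == "RB":
        irrelevant = structure.irrelevant_dim
    else:
        if matched_dim is None:
            raise ValueError("U trace requires matched_dim")
        irrelevant = matched_dim
    rel_dims = [d for d in range(3) if d != irrelevant]
    att = {m: 0.5 * (trace[f"alpha{m}"].to_numpy()
                     + trace[f"beta{m}"].to_numpy()) for m in range(3)}
    df = pd.DataFrame({
        "trial": trace["trial"].to_numpy(),
        "relevant": np.mean([att[d] for d in rel_dims], axis=0),
        "irrelevant": att[irrelevant],
    })
    df["block"] = solution_aligned_block(df["trial"].to_numpy(), int(t_s),
                                         n_trials)
    return (df.groupby("block", as_index=False)
            .agg(relevant=("relevant", "mean"),
                 irrelevant=("irrelevant", "mean"),
                 n_trials=("trial", "size")))
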