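"""Hierarchical Bayesian changepoint logistic regression for learning curves.

Each subject's trial-wise correctness (0/1 over T trials) is modeled as
guessing (p = 0.5) up to a latent onset trial ``o_s``, followed by a logistic
rise::

    p_hat(s, t) = 0.5                          for t <= o_s
    p_hat(s, t) = 1 / (1 + exp(-b_s (t - o_s)))  for t > o_s

with hierarchy  o_s ~ Categorical(theta), theta ~ Dirichlet(1, ..., 1) over
the T trial indices, b_s ~ Gaussian(beta_M, beta_SD) truncated to [0, 3],
beta_M ~ Uniform(0, 3), beta_SD ~ Gaussian(0.1, 1) truncated positive, and a
Bernoulli likelihood.

Sampling is component-wise MCMC: conjugate Dirichlet update for theta,
exact enumeration of the discrete full conditional for each o_s, and
random-walk Metropolis for b_s and the two hyperparameters.

Derived per-subject estimates: the onset trial ``t_o`` (posterior median of
o_s), the slope ``b_hat`` (posterior mean of b_s, with log transform for
group comparisons), and the solution trial ``t_s`` — per posterior draw the
first trial where the predicted accuracy reaches 80%, summarized by the
modal trial; subjects whose draws mostly never cross 80% are flagged as
non-learners (sentinel T + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

LOG_HALF = math.log(0.5)
SLOPE_MAX = 3.0
HYPER_MEAN_MAX = 3.0


def predicted_accuracy(o, b, t):
    """Model-predicted accuracy: 0.5 at or before onset, logistic after.

    Vectorized over any of the arguments.
    """
    o = np.asarray(o, dtype=float)
    b = np.asarray(b, dtype=float)
    t = np.asarray(t, dtype=float)
    d = t - o
    out = np.where(d <= 0, 0.5, 1.0 / (1.0 + np.exp(-b * np.where(d > 0, d, 0.0))))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class AccuracyData:
    """Per-subject binary correctness matrix (subjects x trials)."""

    y: np.ndarray            # (S, T) int8, 0/1 (value ignored where invalid)
    valid: np.ndarray        # (S, T) int8, 1 = observed trial
    subject_ids: list

    @classmethod
    def from_matrix(cls, y, subject_ids=None) -> "AccuracyData":
        y = np.asarray(y)
        if y.ndim != 2:
            raise ValueError("correctness data must be 2-D (subjects x trials)")
        yf = np.asarray(y, dtype=float)
        valid = np.isfinite(yf).astype(np.int8)
        if not np.isin(yf[valid == 1], (0.0, 1.0)).all():
            raise ValueError("correctness entries must be binary (0/1)")
        yy = np.where(valid == 1, yf, 0).astype(np.int8)
        if subject_ids is None:
            subject_ids = list(range(y.shape[0]))
        return cls(y=yy, valid=valid, subject_ids=list(subject_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject="subject", trial="trial",
                   correct="correct") -> "AccuracyData":
        wide = df.pivot_table(index=subject, columns=trial, values=correct)
        return cls.from_matrix(wide.to_numpy(), list(wide.index))

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_trials(self) -> int:
        return self.y.shape[1]


@njit(cache=True)
def _trunc_norm_log_z(mu, sd, lo, hi):
    # log P(lo < X < hi) for X ~ N(mu, sd)
    zl = (lo - mu) / (sd * math.sqrt(2.0))
    zh = (hi - mu) / (sd * math.sqrt(2.0))
    p = 0.5 * (math.erf(zh) - math.erf(zl))
    if p < 1e-300:
        p = 1e-300
    return math.log(p)


@njit(cache=True)
def _slope_loglik(yrow, vrow, o, b, T):
    # Bernoulli log-likelihood of trials after onset (pre-onset terms are
    # constant in b)
    ll = 0.0
    for t in range(o + 1, T + 1):
        if vrow[t - 1] == 1:
            p = 1.0 / (1.0 + math.exp(-b * (t - o)))
            if p < 1e-12:
                p = 1e-12
            elif p > 1.0 - 1e-12:
                p = 1.0 - 1e-12
            ll += math.log(p) if yrow[t - 1] == 1 else math.log(1.0 - p)
    return ll


@njit(cache=True)
def _sample_chain(y, valid, n_iter, burn_in, seed, prop_b, prop_m, prop_s,
                  o_draws, b_draws, theta_draws, bm_draws, bsd_draws, accept):
    np.random.seed(seed)
    S, T = y.shape

    # initial state
    theta = np.full(T, 1.0 / T)
    o = np.empty(S, dtype=np.int64)
    b = np.empty(S)
    for s in range(S):
        o[s] = 1 + int(np.random.random() * T)
        b[s] = 0.2 + 1.0 * np.random.random()
    beta_m = 1.0
    beta_sd = 0.5

    log_theta = np.log(theta)
    logw = np.empty(T)
    A = np.empty(T)
    B = np.empty(T)

    n_keep = n_iter - burn_in
    for it in range(n_iter):
        # --- theta | o : conjugate Dirichlet(1 + counts) -------------------
        galpha = np.ones(T)
        for s in range(S):
            galpha[o[s] - 1] += 1.0
        tot = 0.0
        for k in range(T):
            theta[k] = np.random.gamma(galpha[k], 1.0)
            tot += theta[k]
        for k in range(T):
            theta[k] /= tot
            log_theta[k] = math.log(theta[k])

        for s in range(S):
            yrow = y[s]
            vrow = valid[s]

            # --- o_s : exact discrete full conditional ---------------------
            bs = b[s]
            for d in range(1, T):
                p = 1.0 / (1.0 + math.exp(-bs * d))
                if p < 1e-12:
                    p = 1e-12
                elif p > 1.0 - 1e-12:
                    p = 1.0 - 1e-12
                A[d] = math.log(p)
                B[d] = math.log(1.0 - p)
            for oo in range(1, T + 1):
                ll = 0.0
                for t in range(1, oo + 1):
                    if vrow[t - 1] == 1:
                        ll += LOG_HALF
                for t in range(oo + 1, T + 1):
                    if vrow[t - 1] == 1:
                        d = t - oo
                        ll += A[d] if yrow[t - 1] == 1 else B[d]
                logw[oo - 1] = ll + log_theta[oo - 1]
            m = logw[0]
            for k in range(1, T):
                if logw[k] > m:
                    m = logw[k]
            tot = 0.0
            for k in range(T):
                logw[k] = math.exp(logw[k] - m)
                tot += logw[k]
            r = np.random.random() * tot
            cum = 0.0
            pick = T
            for k in range(T):
                cum += logw[k]
                if r <= cum:
                    pick = k + 1
                    break
            o[s] = pick

            # --- b_s : random-walk Metropolis ------------------------------
            bp = b[s] + prop_b * np.random.standard_normal()
            if 0.0 <= bp <= SLOPE_MAX:
                cur = (_slope_loglik(yrow, vrow, o[s], b[s], T)
                       - 0.5 * ((b[s] - beta_m) / beta_sd) ** 2)
                new = (_slope_loglik(yrow, vrow, o[s], bp, T)
                       - 0.5 * ((bp - beta_m) / beta_sd) ** 2)
                if math.log(np.random.random() + 1e-300) < new - cur:
                    b[s] = bp
                    accept[0] += 1.0
            accept[1] += 1.0

        # --- hyperparameters ----------------------------------------------
        logz = _trunc_norm_log_z(beta_m, beta_sd, 0.0, SLOPE_MAX)
        mp = beta_m + prop_m * np.random.standard_normal()
        if 0.0 <= mp <= HYPER_MEAN_MAX:
            logz_p = _trunc_norm_log_z(mp, beta_sd, 0.0, SLOPE_MAX)
            cur = 0.0
            new = 0.0
            for s in range(S):
                cur += -0.5 * ((b[s] - beta_m) / beta_sd) ** 2 - logz
                new += -0.5 * ((b[s] - mp) / beta_sd) ** 2 - logz_p
            if math.log(np.random.random() + 1e-300) < new - cur:
                beta_m = mp
                logz = logz_p
                accept[2] += 1.0
        accept[3] += 1.0

        sp = beta_sd + prop_s * np.random.standard_normal()
        if sp > 1e-3:
            logz_p = _trunc_norm_log_z(beta_m, sp, 0.0, SLOPE_MAX)
            cur = -0.5 * (beta_sd - 0.1) ** 2
            new = -0.5 * (sp - 0.1) ** 2
            for s in range(S):
                cur += (-0.5 * ((b[s] - beta_m) / beta_sd) ** 2
                        - math.log(beta_sd) - logz)
                new += (-0.5 * ((b[s] - beta_m) / sp) ** 2
                        - math.log(sp) - logz_p)
            if math.log(np.random.random() + 1e-300) < new - cur:
                beta_sd = sp
            accept[4] += 1.0

        if it >= burn_in:
            k = it - burn_in
            for s in range(S):
                o_draws[k, s] = o[s]
                b_draws[k, s] = b[s]
            for t in range(T):
                theta_draws[k, t] = theta[t]
            bm_draws[k] = beta_m
            bsd_draws[k] = beta_sd


@dataclass
class ChangepointDraws:
    """Post-burn-in posterior draws (chains concatenated)."""

    o: np.ndarray          # (n_draws, S) onset trial draws, 1-based
    b: np.ndarray          # (n_draws, S) slope draws
    theta: np.ndarray      # (n_draws, T)
    beta_m: np.ndarray     # (n_draws,)
    beta_sd: np.ndarray    # (n_draws,)
    n_trials: int
    subject_ids: list
    n_iter: int
    burn_in: int
    n_chains: int
    seed: int
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return self.o.shape[0]


def _split_rhat(chains: np.ndarray) -> float:
    # chains: (n_chains, n_draws); standard split-R-hat
    half = chains.shape[1] // 2
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    w = segs.var(axis=1, ddof=1).mean()
    bvar = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * w + bvar / n) / w))


def sample_posterior(data, n_iter: int = 2000, burn_in: int = 500,
                     seed: int = 0, n_chains: int = 1,
                     prop_b: float = 0.15, prop_m: float = 0.1,
                     prop_s: float = 0.1) -> ChangepointDraws:
    """MCMC draws from the joint posterior of the changepoint model."""
    if not isinstance(data, AccuracyData):
        data = AccuracyData.from_matrix(data)
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    S, T = data.y.shape
    n_keep = n_iter - burn_in
    chains = []
    accepts = []
    for c in range(n_chains):
        o_d = np.empty((n_keep, S), dtype=np.int64)
        b_d = np.empty((n_keep, S))
        th_d = np.empty((n_keep, T))
        bm_d = np.empty(n_keep)
        bs_d = np.empty(n_keep)
        accept = np.zeros(5)
        chain_seed = (int(seed) + 7919 * c) % (2**31 - 1)
        _sample_chain(data.y, data.valid, n_iter, burn_in, chain_seed,
                      prop_b, prop_m, prop_s, o_d, b_d, th_d, bm_d, bs_d,
                      accept)
        chains.append((o_d, b_d, th_d, bm_d, bs_d))
        accepts.append(accept)

    o = np.concatenate([c[0] for c in chains])
    b = np.concatenate([c[1] for c in chains])
    theta = np.concatenate([c[2] for c in chains])
    bm = np.concatenate([c[3] for c in chains])
    bsd = np.concatenate([c[4] for c in chains])
    acc = np.sum(accepts, axis=0)
    diagnostics = {
        "accept_rate_b": float(acc[0] / max(acc[1], 1)),
        "accept_rate_beta_m": float(acc[2] / max(acc[3], 1)),
    }
    if n_chains > 1:
        diagnostics["rhat_beta_m"] = _split_rhat(
            np.stack([c[3] for c in chains]))
        diagnostics["rhat_beta_sd"] = _split_rhat(
            np.stack([c[4] for c in chains]))
    return ChangepointDraws(o=o, b=b, theta=theta, beta_m=bm, beta_sd=bsd,
                            n_trials=T, subject_ids=data.subject_ids,
                            n_iter=n_iter, burn_in=burn_in, n_chains=n_chains,
                            seed=seed, diagnostics=diagnostics)


LOG4 = math.log(4.0)
LAST_BLOCK = 16   # crossings in the final block are pooled with never-reachers


def first_crossing(o: int, b: float, T: int) -> int:
    """First trial with predicted accuracy >= 0.8, or T + 1 if never."""
    if b <= 0:
        return T + 1
    t = o + math.ceil(LOG4 / b)
    return t if t <= T else T + 1


def derive_t_s(draws: ChangepointDraws, subject: int) -> tuple[int, bool]:
    """(t_s, nonlearner): modal first-80%-crossing trial over iterations.

    Draws whose predicted accuracy never reaches 80% before the final
    16-trial block count as non-learning (subjects reaching 80% only in the
    last block are pooled with never-reachers); if they are the majority,
    the sentinel T + 1 is returned with the non-learner flag set.
    """
    T = draws.n_trials
    crossings = np.array([first_crossing(int(o), float(b), T)
                          for o, b in zip(draws.o[:, subject],
                                          draws.b[:, subject])])
    never = crossings > T - LAST_BLOCK
    if never.mean() > 0.5:
        return T + 1, True
    vals, counts = np.unique(crossings[~never], return_counts=True)
    return int(vals[np.argmax(counts)]), False


def derive_slope(draws: ChangepointDraws, subject: int) -> tuple[float, float]:
    """Posterior-mean slope and its log (for group comparisons)."""
    b_hat = float(draws.b[:, subject].mean())
    return b_hat, math.log(b_hat)


def derive_t_o(draws: ChangepointDraws, subject: int) -> int:
    """Onset estimate: posterior median of the onset trial index."""
    return int(round(float(np.median(draws.o[:, subject]))))


def subject_estimates(draws: ChangepointDraws) -> pd.DataFrame:
    """Tidy per-subject table of t_o, b_hat, log-slope, t_s, nonlearner."""
    rows = []
    for s, sid in enumerate(draws.subject_ids):
        t_s, nonlearner = derive_t_s(draws, s)
        b_hat, slope_log = derive_slope(draws, s)
        rows.append({"subject": sid, "t_o": derive_t_o(draws, s),
                     "b_hat": b_hat, "slope_log": slope_log,
                     "t_s": t_s, "nonlearner": nonlearner})
    return pd.DataFrame(rows)


def ppc_apply_to_model(cal_traces, n_iter: int = 2000, burn_in: int = 500,
                       seed: int = 0) -> pd.DataFrame:
    """Posterior-predictive check: run the identical changepoint pipeline on
    model-generated correctness sequences (one trace per simulated agent)."""
    traces = list(cal_traces)
    if len(traces) == 0:
        raise ValueError("no model traces supplied")
    mats = []
    for tr in traces:
        corr = np.asarray(tr["correct"], dtype=float)
        if corr.size == 0:
            raise ValueError("empty model trace")
        mats.append(corr)
    y = np.vstack(mats)
    draws = sample_posterior(AccuracyData.from_matrix(y), n_iter=n_iter,
                             burn_in=burn_in, seed=seed)
    return subject_estimates(draws)
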