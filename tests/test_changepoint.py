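"""Hierarchical changepoint logistic regression: exact forms, sampler
correctness against brute-force enumeration, and derived estimates."""

import math

import numpy as np
import pytest
from scipy.stats import norm, truncnorm

from rulemem.changepoint import (AccuracyData, ChangepointDraws, derive_slope,
                                 derive_t_o, derive_t_s, first_crossing,
                                 ppc_apply_to_model, predicted_accuracy,
                                 sample_posterior, subject_estimates)


class TestPredictedAccuracy:
    def test_guessing_before_and_at_onset(self):
        assert predicted_accuracy(50, 2.0, 30) == 0.5
        assert predicted_accuracy(50, 0.7, 1) == 0.5
        assert predicted_accuracy(50, 2.0, 50) == 0.5  # exp(0) boundary

    def test_logistic_closed_form_after_onset(self):
        assert predicted_accuracy(50, 0.5, 60) == \
            pytest.approx(1 / (1 + math.exp(-5)), abs=1e-15)

    def test_monotone_and_saturating(self):
        t = np.arange(1, 161)
        p = predicted_accuracy(40, 0.8, t)
        assert (np.diff(p) >= 0).all()
        assert p[-1] > 0.999
        assert (p >= 0.5).all() and (p <= 1).all()


class TestAccuracyData:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            AccuracyData.from_matrix(np.full((2, 10), 0.3))

    def test_missing_trials_masked(self):
        y = np.ones((1, 10))
        y[0, 3] = np.nan
        d = AccuracyData.from_matrix(y)
        assert d.valid[0, 3] == 0
        assert d.valid.sum() == 9


@pytest.fixture(scope="module")
def step_draws():
    """Posterior for two clean step subjects (chance then perfect)."""
    rng = np.random.default_rng(0)
    rows = []
    for onset in (40, 80):
        y = np.concatenate([(rng.random(onset) < 0.5).astype(int),
                            np.ones(160 - onset, dtype=int)])
        rows.append(y)
    return sample_posterior(np.vstack(rows), n_iter=1500, burn_in=400, seed=2)


class TestSampler:
    def test_deterministic_given_seed(self):
        y = (np.random.default_rng(1).random((3, 60)) < 0.6).astype(int)
        a = sample_posterior(y, n_iter=300, burn_in=100, seed=5)
        b = sample_posterior(y, n_iter=300, burn_in=100, seed=5)
        assert np.array_equal(a.o, b.o)
        assert np.array_equal(a.b, b.b)

    def test_draw_domains(self, step_draws):
        d = step_draws
        assert np.allclose(d.theta.sum(axis=1), 1.0, atol=1e-9)
        assert d.o.min() >= 1 and d.o.max() <= d.n_trials
        assert d.b.min() >= 0 and d.b.max() <= 3
        assert (d.beta_m >= 0).all() and (d.beta_m <= 3).all()
        assert (d.beta_sd > 0).all()

    def test_step_onsets_recovered(self, step_draws):
        modes = []
        for s in range(2):
            vals, counts = np.unique(step_draws.o[:, s], return_counts=True)
            modes.append(vals[np.argmax(counts)])
        assert abs(modes[0] - 40) <= 3
        assert abs(modes[1] - 80) <= 3

    def test_chance_data_yields_nonlearner(self):
        y = (np.random.default_rng(7).random((2, 160)) < 0.5).astype(int)
        d = sample_posterior(y, n_iter=1200, burn_in=300, seed=3)
        est = subject_estimates(d)
        assert est["nonlearner"].all()
        assert (est["t_s"] == 161).all()

    def test_burnin_validation(self):
        with pytest.raises(ValueError):
            sample_posterior(np.ones((1, 10), dtype=int), n_iter=10, burn_in=10)

    def test_multichain_diagnostics_reported(self):
        y = (np.random.default_rng(2).random((2, 60)) < 0.7).astype(int)
        d = sample_posterior(y, n_iter=400, burn_in=100, seed=1, n_chains=2)
        assert "rhat_beta_m" in d.diagnostics
        assert d.o.shape[0] == 2 * 300


class TestOracleEquivalence:
    def test_marginal_onset_posterior_matches_enumeration(self):
        """On a T=20 toy, the sampler's marginal P(o_s | data) matches
        brute-force integration over (b, hyperparameters) with the Dirichlet
        weights collapsed analytically."""
        rng = np.random.default_rng(3)
        T = 20
        t = np.arange(1, T + 1)

        def gen(o, b):
            p = predicted_accuracy(o, b, t)
            return (rng.random(T) < p).astype(int)

        Y = np.vstack([gen(8, 1.5), gen(14, 0.8)])
        bgrid = np.linspace(0.01, 2.99, 120)
        mgrid = np.linspace(0.02, 2.98, 30)
        sgrid = np.linspace(0.03, 3.0, 30)
        loglik = np.zeros((2, T, bgrid.size))
        for s in range(2):
            for oi in range(T):
                p = predicted_accuracy(oi + 1, bgrid[:, None], t[None, :])
                p = np.clip(p, 1e-12, 1 - 1e-12)
                loglik[s, oi] = np.where(Y[s] == 1, np.log(p),
                                         np.log(1 - p)).sum(axis=1)
        lik = np.exp(loglik - loglik.max())
        marg = np.zeros((2, T))
        for m in mgrid:
            for sd in sgrid:
                pb = truncnorm.pdf(bgrid, (0 - m) / sd, (3 - m) / sd,
                                   loc=m, scale=sd)
                if pb.sum() == 0:
                    continue
                pb = pb / pb.sum()
                prior_h = norm.pdf(sd, 0.1, 1.0)
                A = lik @ pb
                joint = np.outer(A[0], A[1]) * (1.0 + np.eye(T))
                marg[0] += prior_h * joint.sum(axis=1)
                marg[1] += prior_h * joint.sum(axis=0)
        marg /= marg.sum(axis=1, keepdims=True)
        oracle_mean = marg @ t

        d = sample_posterior(Y, n_iter=12000, burn_in=2000, seed=9)
        for s in range(2):
            mc = np.bincount(d.o[:, s], minlength=T + 1)[1:] / d.n_draws
            assert abs(mc @ t - oracle_mean[s]) < 0.4
            assert 0.5 * np.abs(mc - marg[s]).sum() < 0.1  # total variation


def _draws_from_arrays(o, b, T=160):
    o = np.asarray(o)[:, None]
    b = np.asarray(b)[:, None]
    n = o.shape[0]
    return ChangepointDraws(o=o, b=b, theta=np.full((n, T), 1 / T),
                            beta_m=np.ones(n), beta_sd=np.ones(n),
                            n_trials=T, subject_ids=[0], n_iter=n, burn_in=0,
                            n_chains=1, seed=0, diagnostics={})


class TestDerivedEstimates:
    def test_unanimous_crossing(self):
        # o=50, b=0.5: first 80% crossing at 50 + ceil(ln4 / 0.5) = 53
        d = _draws_from_arrays([50] * 10, [0.5] * 10)
        t_s, nonlearner = derive_t_s(d, 0)
        assert (t_s, nonlearner) == (53, False)
        assert first_crossing(50, 0.5, 160) == 53

    def test_modal_crossing(self):
        d = _draws_from_arrays([50] * 6 + [58] * 4, [0.5] * 10)
        t_s, _ = derive_t_s(d, 0)
        assert t_s == 53

    def test_majority_never_crossing_gives_sentinel(self):
        d = _draws_from_arrays([150] * 7 + [50] * 3, [0.5] * 10)
        t_s, nonlearner = derive_t_s(d, 0)
        assert nonlearner and t_s == 161

    def test_slope_summaries(self):
        d = _draws_from_arrays([50, 50], [0.5, 1.5])
        b_hat, slope_log = derive_slope(d, 0)
        assert b_hat == pytest.approx(1.0)
        assert slope_log == pytest.approx(0.0)
        d2 = _draws_from_arrays([50], [1.0])
        assert derive_slope(d2, 0) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_onset_summary_is_posterior_median(self):
        d = _draws_from_arrays([10, 20, 90], [1, 1, 1])
        assert derive_t_o(d, 0) == 20


class TestPPC:
    def test_empty_traces_raise(self):
        with pytest.raises(ValueError):
            ppc_apply_to_model([])

    def test_pipeline_runs_on_model_traces(self, solved_rb_trace):
        trace, _ = solved_rb_trace
        est = ppc_apply_to_model([trace], n_iter=600, burn_in=200, seed=4)
        assert len(est) == 1
        assert {"t_o", "t_s", "b_hat", "slope_log", "nonlearner"} <= \
            set(est.columns)
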