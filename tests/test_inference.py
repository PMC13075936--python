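"""Diagnostics, WAIC, MLE, and the HMC backend."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import random_params, random_trials
from rgtlearn import cohort, sampler
from rgtlearn.inference import (
    MCMCConfig,
    MLERLModel,
    HierarchicalRLModel,
    fit_hierarchical,
    fit_mle,
    rhat,
    waic,
    waic_difference,
)
from rgtlearn.models import RLParams, simulate_agent, subject_loglik


class TestRhat:
    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(0)
        vals = [rhat(rng.standard_normal((4, 2000))) for _ in range(20)]
        # the split estimator may dip just below 1 when B is tiny
        assert all(0.995 <= v <= 1.01 for v in vals)

    def test_separated_chains_flagged(self):
        # hand oracle on 8 fixed numbers: chains at 0 and 10, split in half
        chains = np.array([[-1.0, 1.0, -1.0, 1.0], [9.0, 11.0, 9.0, 11.0]])
        # split halves: means (0, 0, 10, 10), within-var mean W = 2,
        # between B/n = var([0,0,10,10], ddof=1) = 100/3,
        # var+ = (1/2)*2 + 100/3, rhat = sqrt(var+/W) = sqrt(1/2 + 50/3)
        expected = np.sqrt(0.5 + 50.0 / 3.0)
        assert rhat(chains) == pytest.approx(expected, rel=1e-12)
        assert rhat(chains) > 1.1

    def test_constant_chains_undefined(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rhat(np.ones((2, 10))))

    def test_agrees_with_arviz_on_random_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 500)) + np.array([[0.0], [0.1], [0.0], [0.2]])
        # arviz "split" method is the classic split-PSRF
        theirs = float(az.rhat(chains, method="split"))
        assert rhat(chains) == pytest.approx(theirs, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            rhat(np.zeros((2, 3)))


class TestWaic:
    def test_matches_hand_formula_on_random_matrix(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-1.0, 0.3, size=(5, 3))
        res = waic(ll)
        # independent elementwise computation
        elpd_i = np.log(np.exp(ll).mean(axis=0)) - ll.var(axis=0, ddof=1)
        assert res.elpd == pytest.approx(elpd_i.sum(), abs=1e-10)
        assert res.waic == pytest.approx(-2 * elpd_i.sum(), abs=1e-10)
        assert res.p_waic == pytest.approx(ll.var(axis=0, ddof=1).sum(), abs=1e-10)
        pw = -2 * elpd_i
        assert res.se == pytest.approx(np.sqrt(3 * pw.var(ddof=1)), abs=1e-10)

    def test_point_posterior_has_zero_penalty(self):
        ll = np.tile(np.array([-1.2, -0.7, -2.0]), (6, 1))
        res = waic(ll)
        assert res.p_waic == pytest.approx(0.0, abs=1e-12)
        assert res.waic == pytest.approx(-2 * ll[0].sum(), abs=1e-10)

    def test_duplicating_points_doubles_waic(self):
        rng = np.random.default_rng(2)
        ll = rng.normal(-1.0, 0.2, size=(8, 10))
        doubled = np.concatenate([ll, ll], axis=1)
        assert waic(doubled).waic == pytest.approx(2 * waic(ll).waic, abs=1e-8)

    def test_nonfinite_rejected(self):
        bad = np.full((3, 2), -1.0)
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            waic(bad)


class TestWaicDifference:
    def test_self_difference_is_zero(self):
        rng = np.random.default_rng(3)
        w = waic(rng.normal(-1, 0.2, size=(10, 20)))
        d, sem = waic_difference(w, w)
        assert d == 0.0 and sem == 0.0

    def test_mismatched_points_rejected(self):
        rng = np.random.default_rng(4)
        wa = waic(rng.normal(size=(5, 6)))
        wb = waic(rng.normal(size=(5, 7)))
        with pytest.raises(ValueError):
            waic_difference(wa, wb)


class TestFitMLE:
    def test_recovers_generating_parameters_at_large_n(self):
        p = RLParams("basic", beta=2.0, eta_plus=0.4, eta_minus=0.2)
        sim = simulate_agent(p, n_sessions=1, trials_mode="fixed_n",
                             trials_per_session=2000, rng=np.random.default_rng(7))
        res = fit_mle("basic", sim.to_frame())
        assert res.success
        assert abs(res.params.beta - 2.0) < 0.5
        assert abs(res.params.eta_plus - 0.4) < 0.1

    def test_single_trial_is_flat_and_flagged(self):
        trials = pd.DataFrame(
            [{"session": 1, "trial_index": 1, "choice": "P2",
              "outcome": "win", "pellets": 2, "penalty_s": 0.0}]
        )
        res = fit_mle("basic", trials)
        assert res.low_information
        assert res.loglik == pytest.approx(np.log(0.25), abs=1e-6)

    def test_nested_model_attains_at_least_nested_likelihood(self, rng):
        trials = random_trials(400, rng)
        ll_scaled = fit_mle("scaled", trials, seed=0).loglik
        ll_offset = fit_mle("scaled_offset", trials, seed=0).loglik
        assert ll_offset >= ll_scaled - 1e-6

    def test_estimator_wrapper_fits_per_subject(self, rng):
        logs = cohort.generate_cohort_logs(
            [RLParams("basic", beta=1.5, eta_plus=0.2, eta_minus=0.3)] * 2,
            n_sessions=2, seed=1,
        )
        est = MLERLModel(model_id="basic", n_starts=4, fit_sessions=(1, 2)).fit(logs)
        assert list(est.params_.columns) == ["beta", "eta_plus", "eta_minus"]
        assert len(est.params_) == 2


class TestSamplerOnKnownTarget:
    def test_recovers_correlated_gaussian_moments(self):
        cov = np.array([[1.0, 0.8], [0.8, 2.0]])
        prec = np.linalg.inv(cov)

        def logp_grad(x):
            return -0.5 * x @ prec @ x, -prec @ x

        draws, stats_ = sampler.run_chains(
            logp_grad, [np.zeros(2), np.ones(2)], n_warmup=500, n_samples=1500,
            seed=0, max_leapfrog=16,
        )
        flat = draws.reshape(-1, 2)
        np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=0.15)
        np.testing.assert_allclose(np.cov(flat.T), cov, atol=0.3)

    def test_deterministic_under_seed(self):
        def logp_grad(x):
            return -0.5 * x @ x, -x

        a, _ = sampler.run_chains(logp_grad, [np.zeros(3)], 200, 100, seed=5)
        b, _ = sampler.run_chains(logp_grad, [np.zeros(3)], 200, 100, seed=5)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def tiny_cohort():
    h = cohort.default_hypers("basic", "uncued", n_subjects=4)
    return cohort.make_cohort(h, n_sessions=2, seed=21)


class TestHierarchicalFit:
    def test_identical_seeds_give_identical_draws(self, tiny_cohort):
        cfg = MCMCConfig(n_chains=2, n_warmup=200, warmup_cap=200, n_samples=100, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_hierarchical("basic", tiny_cohort.logs, config=cfg)
            f2 = fit_hierarchical("basic", tiny_cohort.logs, config=cfg)
        np.testing.assert_array_equal(f1.mu, f2.mu)
        np.testing.assert_array_equal(f1.z, f2.z)

    def test_posterior_is_in_plausible_region(self, tiny_cohort):
        cfg = MCMCConfig(n_chains=2, n_warmup=300, warmup_cap=300, n_samples=200, seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fit_hierarchical("basic", tiny_cohort.logs, config=cfg)
        em_true = np.mean([p.eta_minus for p in tiny_cohort.true_params])
        em_post = f.group_mean_samples("eta_minus").mean()
        assert abs(em_post - em_true) < 0.2
        means = f.subject_posterior_means()
        assert means.shape == (4, 3)
        assert (means["beta"] > 0).all()

    def test_estimator_wrapper_exposes_fitted_attributes(self, tiny_cohort):
        cfg = MCMCConfig(n_chains=2, n_warmup=200, warmup_cap=200, n_samples=100, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = HierarchicalRLModel(model_id="basic", config=cfg,
                                      fit_sessions=(1, 2)).fit(tiny_cohort.logs)
        assert set(est.group_means_) == {"beta", "eta_plus", "eta_minus"}
        assert est.subject_means_.shape == (4, 3)
        assert est.get_params()["model_id"] == "basic"

    def test_requires_two_subjects(self, tiny_cohort):
        one = tiny_cohort.logs[tiny_cohort.logs["subject_id"] == "S000"]
        with pytest.raises(ValueError):
            fit_hierarchical("basic", one)

    def test_unknown_model_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            fit_hierarchical("independent_cost", tiny_cohort.logs)


def test_hierarchical_gradient_matches_finite_differences(rng):
    """Analytic gradient of the hierarchical posterior, all centerings."""
    from rgtlearn._kernels import (
        MODEL_CODES, MODEL_K, MODEL_TRANSFORMS, _hier_logp_grad_mixed,
    )
    from rgtlearn.inference import _prepare_group_data

    logs = cohort.generate_cohort_logs(
        [random_params("nonlinear", rng) for _ in range(3)], n_sessions=1, seed=2
    )
    sids, offsets, ch, iw, rw, pn = _prepare_group_data(logs, fit_sessions=(1, 1))
    code, K, S = MODEL_CODES["nonlinear"], 5, 3
    tc = np.ascontiguousarray(MODEL_TRANSFORMS[code, :K])
    mu_sd = np.array([2.0 if t == 2 else 1.0 for t in tc])
    sg_sd = np.ones(K)
    for cent in (np.ones(K, np.int64), np.zeros(K, np.int64),
                 np.array([1, 1, 1, 0, 0], np.int64)):
        theta = 0.2 * rng.standard_normal(2 * K + S * K)
        lp, g = _hier_logp_grad_mixed(theta, code, K, S, offsets, ch, iw, rw, pn,
                                      tc, mu_sd, sg_sd, cent)
        eps = 1e-6
        for i in range(0, theta.size, 5):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (
                _hier_logp_grad_mixed(tp, code, K, S, offsets, ch, iw, rw, pn,
                                      tc, mu_sd, sg_sd, cent)[0]
                - _hier_logp_grad_mixed(tm, code, K, S, offsets, ch, iw, rw, pn,
                                        tc, mu_sd, sg_sd, cent)[0]
            ) / (2 * eps)
            assert abs(g[i] - fd) < 1e-4 * max(1.0, abs(fd))


def test_prior_predictive_spans_both_risk_profiles():
    """Sampling from the priors yields both optimal and risky agents."""
    rng = np.random.default_rng(6)
    scores = []
    for _ in range(30):
        mu = {
            "beta": rng.normal(0, 1), "eta_plus": rng.normal(0, 1),
            "eta_minus": rng.normal(0, 1), "b": rng.normal(0, 2),
            "r": rng.normal(0, 1),
        }
        p = RLParams(
            "nonlinear",
            beta=float(np.exp(np.clip(mu["beta"], -3, 2.5))),
            eta_plus=float(0.5 * (1 + np.tanh(mu["eta_plus"]))),  # cheap Phi-like map
            eta_minus=float(0.5 * (1 + np.tanh(mu["eta_minus"]))),
            b=float(mu["b"]),
            r=float(np.exp(np.clip(mu["r"], -2, 1))),
        )
        sim = simulate_agent(p, n_sessions=2, trials_mode="fixed_n",
                             trials_per_session=100, rng=rng)
        counts = np.bincount(sim.choices[sim.sessions == 2], minlength=4)
        pct = counts / counts.sum() * 100
        scores.append((pct[0] + pct[1]) - (pct[2] + pct[3]))
    assert min(scores) < 0 < max(scores)
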