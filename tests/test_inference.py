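"""Posterior construction, quadrature accuracy and sampler behavior."""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit

from regmsar.filter import forward_loglik
from regmsar.inference import (
    Diagnostics,
    SamplerConfig,
    build_log_posterior,
    convergence_and_precision,
    posterior_mode,
    sample_posterior,
    summarize,
)
from regmsar.model import PanelDataset
from regmsar.simulate import Sim1Design, Sim2Design, generate_sim1, generate_sim2


@pytest.fixture(scope="module")
def tiny_sim1():
    return generate_sim1(Sim1Design(N=12, T=8, P=3, seed=42))


@pytest.fixture(scope="module")
def tiny_model(tiny_sim1):
    return build_log_posterior(tiny_sim1.data, "ridge-0")


class TestLogPosterior:
    def test_finite_at_initialization(self, tiny_model):
        x0 = tiny_model.initial_center()
        assert np.isfinite(tiny_model.log_posterior(x0))

    def test_vectorized_matches_scalar(self, tiny_model, rng):
        xs = tiny_model.initial_center()[None, :] + 0.05 * rng.standard_normal((4, tiny_model.dim))
        batch = tiny_model.log_posterior(xs)
        singles = np.array([tiny_model.log_posterior(x) for x in xs])
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_stacking_dataset_doubles_likelihood_term(self, tiny_sim1):
        data = tiny_sim1.data
        doubled = PanelDataset(
            eta_y=np.concatenate([data.eta_y] * 2),
            eta_x=np.concatenate([data.eta_x] * 2),
            eta_z=np.concatenate([data.eta_z] * 2),
        )
        m1 = build_log_posterior(data, "ridge-0")
        m2 = build_log_posterior(doubled, "ridge-0")
        x0 = m1.initial_center()
        # same slot layout: the doubled model shares dimensions
        assert m2.dim == m1.dim
        assert m2.log_likelihood(x0) == pytest.approx(2.0 * m1.log_likelihood(x0), rel=1e-12)

    @pytest.mark.parametrize("preset", ["ridge-0", "b-lasso", "abss-lasso-0", "reg-hs-0"])
    def test_all_prior_families_finite_and_smooth(self, tiny_sim1, preset, rng):
        model = build_log_posterior(tiny_sim1.data, preset)
        x0 = model.initial_center()
        assert np.isfinite(model.log_posterior(x0))
        # central differences stable across step size in a random direction
        d = rng.standard_normal(model.dim)
        d /= np.linalg.norm(d)
        f = lambda eps: model.log_posterior(x0 + eps * d)
        g1 = (f(1e-4) - f(-1e-4)) / 2e-4
        g2 = (f(1e-5) - f(-1e-5)) / 2e-5
        assert np.isfinite(g1) and g1 == pytest.approx(g2, rel=5e-3, abs=1e-5)

    def test_non_finite_regions_map_to_minus_inf(self, tiny_model):
        x = tiny_model.initial_center()
        x[0] = 1e4  # exp overflow in a2
        assert tiny_model.log_posterior(x) == -np.inf


class TestEps0Marginalization:
    def test_quadrature_matches_adaptive_integration(self):
        sim = generate_sim1(Sim1Design(N=2, T=6, P=2, seed=9))
        model = build_log_posterior(sim.data, "ridge-0", gh_points=31)
        x0 = model.initial_center()
        comp = model.components(x0[None, :])
        got = comp["loglik"][0]
        # independent oracle: integrate each individual's filter likelihood
        # over the random intercept with adaptive quadrature
        pars = {}
        for name, size in model.slots:
            a, b = model._offsets[name]
            pars[name] = x0[a:b]
        sigma0 = math.exp(pars["log_sigma_eps0"][0])
        w = sim.true_within.__class__(
            a2=[math.exp(pars["log_a2"][0])],
            b2=[[pars["b2"][0]]],
            gamma=pars["gamma"][0],
            sigma_eps=math.exp(pars["log_sigma_eps"][0]),
        )
        between = sim.true_between.__class__(
            beta0=math.exp(pars["log_beta0"][0]),
            beta_x=pars["beta"][: sim.data.Q],
            sigma_eps0=sigma0,
        )
        total = 0.0
        for i in range(sim.data.N):
            sub = PanelDataset(
                eta_y=sim.data.eta_y[i : i + 1],
                eta_x=sim.data.eta_x[i : i + 1],
                eta_z=sim.data.eta_z[i : i + 1],
            )
            def f(e):
                ll = forward_loglik(sub, w, between, np.array([e])).loglik
                return math.exp(ll) * stats.norm.pdf(e, scale=sigma0)
            val, _ = integrate.quad(f, -8 * sigma0, 8 * sigma0, limit=200)
            total += math.log(val)
        assert got == pytest.approx(total, abs=1e-6)

    def test_vanishing_random_intercept_recovers_conditional_loglik(self):
        sim = generate_sim1(Sim1Design(N=4, T=7, P=2, seed=10))
        model = build_log_posterior(sim.data, "ridge-0")
        x0 = model.initial_center()
        a, _ = model._offsets["log_sigma_eps0"]
        x0[a] = math.log(1e-6)
        got = model.log_likelihood(x0)
        pars = {}
        for name, size in model.slots:
            lo, hi = model._offsets[name]
            pars[name] = x0[lo:hi]
        w = sim.true_within.__class__(
            a2=[math.exp(pars["log_a2"][0])],
            b2=[[pars["b2"][0]]],
            gamma=pars["gamma"][0],
            sigma_eps=math.exp(pars["log_sigma_eps"][0]),
        )
        between = sim.true_between.__class__(
            beta0=math.exp(pars["log_beta0"][0]),
            beta_x=pars["beta"][: sim.data.Q],
            sigma_eps0=0.0,
        )
        cond = forward_loglik(sim.data, w, between, np.zeros(sim.data.N)).loglik
        assert got == pytest.approx(cond, abs=1e-6)

    def test_explicit_eps0_path_matches_filter(self, tiny_sim1):
        model = build_log_posterior(tiny_sim1.data, "ridge-0", marginalize_eps0=False)
        assert model.dim == 6 + 3 + tiny_sim1.data.N
        x0 = model.initial_center()
        assert np.isfinite(model.log_posterior(x0))


class TestSim2Posterior:
    def test_time_varying_predictors_enter_likelihood(self):
        sim = generate_sim2(Sim2Design(N=8, T=6, seed=2))
        model = build_log_posterior(sim.data, "ridge-0", include_mu1=True)
        assert model.P == 15
        x0 = model.initial_center()
        base = model.log_likelihood(x0)
        a, b = model._offsets["beta"]
        x1 = x0.copy()
        x1[a + sim.data.Q] = 0.9  # the time-varying covariate slope
        assert model.log_likelihood(x1) != pytest.approx(base)


class TestSampling:
    def test_prior_only_ridge_matches_standard_normal(self):
        model = build_log_posterior(None, "ridge-0", prior_only=True, P_override=2)
        cfg = SamplerConfig(chains=2, iterations=1500, warmup=500, seed=3)
        draws, _ = sample_posterior(model, cfg)
        flat = draws.stacked("beta").ravel()
        sub = flat[:: max(1, flat.size // 4000)]
        ks = stats.kstest(sub, "norm")
        assert ks.statistic < 0.05
        assert np.mean(flat) == pytest.approx(0.0, abs=0.05)
        assert np.std(flat) == pytest.approx(1.0, abs=0.05)

    def test_same_seed_reproduces_summaries(self, tiny_model):
        cfg = SamplerConfig(chains=2, iterations=300, warmup=150, seed=11)
        d1, _ = sample_posterior(tiny_model, cfg)
        d2, _ = sample_posterior(tiny_model, cfg)
        np.testing.assert_array_equal(d1.unconstrained, d2.unconstrained)

    def test_quantiles_of_normal_draws(self, rng):
        # interval machinery check on known draws
        from regmsar.inference import PosteriorDraws

        arr = rng.standard_normal((2, 5000))
        draws = PosteriorDraws(params={"z": arr}, unconstrained=np.zeros((2, 5000, 1)), param_names=["z"])
        s = summarize(draws)
        assert s.loc[0, "lower"] == pytest.approx(-1.96, abs=0.08)
        assert s.loc[0, "upper"] == pytest.approx(1.96, abs=0.08)

    def test_eti_and_hpd_agree_for_symmetric_draws(self, rng):
        from regmsar.inference import PosteriorDraws

        arr = rng.standard_normal((2, 8000))
        draws = PosteriorDraws(params={"z": arr}, unconstrained=np.zeros((2, 8000, 1)), param_names=["z"])
        eti = summarize(draws, "eti")
        hpd = summarize(draws, "hpd")
        assert eti.loc[0, "lower"] == pytest.approx(hpd.loc[0, "lower"], abs=0.1)
        assert eti.loc[0, "upper"] == pytest.approx(hpd.loc[0, "upper"], abs=0.1)

    def test_too_few_draws_rejected(self):
        from regmsar.inference import PosteriorDraws

        arr = np.ones((1, 10))
        draws = PosteriorDraws(params={"z": arr}, unconstrained=np.zeros((1, 10, 1)), param_names=["z"])
        with pytest.raises(ValueError, match="too few"):
            summarize(draws)


class TestDiagnosticsAggregation:
    def _diag(self, converged, ess=500.0):
        return Diagnostics(
            rhat={},
            ess={},
            max_rhat=1.05 if converged else 1.5,
            min_ess=ess,
            divergences=0,
            converged=converged,
            precision={100: ess > 100, 400: ess > 400, 1000: ess > 1000},
        )

    def test_counting(self):
        out = convergence_and_precision([self._diag(True)] * 3 + [self._diag(False)])
        assert out["convergence_rate"] == pytest.approx(0.75)

    def test_all_converged(self):
        out = convergence_and_precision([self._diag(True, ess=1200.0)] * 5)
        assert out["convergence_rate"] == 1.0
        assert out["precision_rates"][1000] == 1.0

    def test_order_invariance(self):
        a = [self._diag(True), self._diag(False), self._diag(True)]
        assert (
            convergence_and_precision(a)["convergence_rate"]
            == convergence_and_precision(a[::-1])["convergence_rate"]
        )
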