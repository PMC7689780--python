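"""Marginal likelihoods, priors, sampler determinism and diagnostics."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import psfsignal as ps
from psfsignal import hier_models
from psfsignal.hier_models import ModelSpec, PosteriorResult, build_model


def brute_force_pair_loglik(pair, params, model_id, t100):
    """Integrate the latent replicate and pair levels numerically.

    p(r_j) = int p(rstar_j) prod_i [ int N(r_ij; rstar_ij, s2r) N(rstar_ij;
    rstar_j, s2w) drstar_ij ] drstar_j, with the inner integrals also done by
    quadrature so the oracle shares nothing with the implementation.
    """
    spec = ModelSpec(model_id)
    sw = params["sigma_w"]

    def replicate_density(r_obs, var_obs, rstar_j):
        # plain-formula densities: quad calls this thousands of times
        c1 = 1.0 / math.sqrt(2 * math.pi * var_obs)
        c2 = 1.0 / (math.sqrt(2 * math.pi) * sw)

        def f(u):
            return (
                c1
                * math.exp(-0.5 * (r_obs - u) ** 2 / var_obs)
                * c2
                * math.exp(-0.5 * (u - rstar_j) ** 2 / sw**2)
            )

        # integrate over the union of the two bells
        lo = min(rstar_j - 9 * sw, r_obs - 9 * math.sqrt(var_obs))
        hi = max(rstar_j + 9 * sw, r_obs + 9 * math.sqrt(var_obs))
        val, _ = integrate.quad(f, lo, hi, epsabs=1e-11, limit=100)
        return val

    if spec.family == "normal":
        var = params["sigma"] ** 2 + (params.get("k", 0.0) * t100 if spec.variance_growth else 0.0)
        mean = params.get("beta", 0.0) * t100 if spec.trend else 0.0
        prior = lambda x: stats.norm.pdf(x, mean, np.sqrt(var))
        spread = np.sqrt(var)
    else:
        df = params["upsilon"] + params["k"] * t100
        mean = params.get("beta", 0.0) * t100 if spec.trend else 0.0
        prior = lambda x: stats.t.pdf(x, df, loc=mean, scale=params["s"])
        spread = params["s"] * 3

    def integrand(x):
        dens = prior(x)
        for obs in pair.observations:
            dens *= replicate_density(obs.r, obs.var_r, x)
        return dens

    r_all = pair.r_values
    lo = min(mean - 12 * spread, r_all.min() - 6)
    hi = max(mean + 12 * spread, r_all.max() + 6)
    val, _ = integrate.quad(integrand, lo, hi, epsabs=1e-12, limit=200)
    return np.log(val)


@pytest.mark.parametrize(
    "model_id, params",
    [
        (1, {"sigma_w": 0.3, "sigma": 0.7}),
        (4, {"sigma_w": 0.25, "beta": -0.03, "sigma": 0.5, "k": 0.08}),
        (5, {"sigma_w": 0.3, "s": 0.5, "upsilon": 4.0, "k": -0.2}),
    ],
)
def test_marginal_likelihood_matches_quadrature_oracle(tiny_pairs, model_id, params):
    """Analytic/Gauss-Hermite marginalization vs brute-force nested quadrature."""
    model = build_model(model_id, tiny_pairs)
    fast = model.pointwise_loglik(params)
    for j, pair in enumerate(tiny_pairs):
        slow = brute_force_pair_loglik(pair, params, model_id, pair.t_myr / 100.0)
        assert fast[j] == pytest.approx(slow, abs=1e-4)


def test_model1_marginal_is_rank_one_mvn(tiny_pairs):
    """Direct multivariate-normal evaluation of the collapsed replicate vector."""
    params = {"sigma_w": 0.4, "sigma": 0.9}
    model = build_model(1, tiny_pairs)
    fast = model.pointwise_loglik(params)
    for j, pair in enumerate(tiny_pairs):
        n = pair.n_replicates
        cov = np.diag(pair.var_r_values + params["sigma_w"] ** 2) + params["sigma"] ** 2
        direct = stats.multivariate_normal.logpdf(pair.r_values, np.zeros(n), cov)
        assert fast[j] == pytest.approx(direct, abs=1e-10)


@pytest.mark.parametrize(
    "wide_id, null_param, narrow_id",
    [
        (2, "beta", 1),
        (4, "k", 2),
        (3, "k", 1),
        (6, "beta", 5),
    ],
)
def test_nested_models_coincide_at_null(tiny_pairs, wide_id, null_param, narrow_id):
    """Fixing the extra parameter at zero reproduces the nested model exactly."""
    base = {"sigma_w": 0.3, "sigma": 0.7, "beta": -0.05, "k": 0.1,
            "s": 0.6, "upsilon": 5.0}
    wide = dict(base, **{null_param: 0.0})
    ll_wide = build_model(wide_id, tiny_pairs).pointwise_loglik(wide)
    ll_narrow = build_model(narrow_id, tiny_pairs).pointwise_loglik(base)
    np.testing.assert_allclose(ll_wide, ll_narrow, atol=1e-12)


def test_family_shifts_model_nests_plain_t(tiny_pairs):
    spec7 = {"sigma_w": 0.3, "beta": -0.02, "s": 0.6, "upsilon": 5.0, "k": -0.1,
             "s_alpha": 0.5, "nu_alpha": 10.0,
             "alpha": np.zeros(len({p.family_pair_id for p in tiny_pairs}))}
    spec6 = {"sigma_w": 0.3, "beta": -0.02, "s": 0.6, "upsilon": 5.0, "k": -0.1}
    ll7 = build_model(7, tiny_pairs).pointwise_loglik(spec7)
    ll6 = build_model(6, tiny_pairs).pointwise_loglik(spec6)
    np.testing.assert_allclose(ll7, ll6, atol=1e-12)


def test_student_t_limit_recovers_normal(tiny_pairs):
    """At a million degrees of freedom the t pair level is numerically normal."""
    ll_t = build_model(6, tiny_pairs).pointwise_loglik(
        {"sigma_w": 0.3, "beta": -0.05, "s": 0.6, "upsilon": 1e6, "k": 0.0}
    )
    ll_n = build_model(4, tiny_pairs).pointwise_loglik(
        {"sigma_w": 0.3, "beta": -0.05, "sigma": 0.6, "k": 0.0}
    )
    np.testing.assert_allclose(ll_t, ll_n, atol=1e-3)


def test_unsatisfiable_df_constraint_rejected(tiny_pairs):
    # max distance 600 Myr = 6 units: upsilon + k*6 = 3 - 0.5*6 = 0 <= 2
    with pytest.raises(hier_models.ModelConfigurationError):
        build_model(
            ModelSpec(5, params={"sigma_w": 0.3, "s": 0.5, "upsilon": 3.0, "k": -0.5}),
            tiny_pairs,
        )


def test_fit_is_deterministic(small_pairs):
    kwargs = dict(chains=2, iterations=300, burn_in=100, seed=123)
    a = ps.fit(build_model(2, small_pairs), **kwargs)
    b = ps.fit(build_model(2, small_pairs), **kwargs)
    for name in a.draws:
        np.testing.assert_array_equal(a.draws[name], b.draws[name])
    np.testing.assert_array_equal(a.pointwise_loglik, b.pointwise_loglik)


def test_fit_recovers_constant_variance(small_pairs):
    res = ps.fit(build_model(1, small_pairs), chains=2, iterations=1500,
                 burn_in=400, seed=2)
    assert res.max_rhat < 1.1
    summary = ps.posterior_summary(res)
    # the generator used sigma_w = 0.3; the pair-level spread under the
    # heavy-tailed generating model is bounded below by s = 0.5
    assert summary.loc["sigma_w", "q2.5"] < 0.3 < summary.loc["sigma_w", "q97.5"] * 1.5
    assert summary.loc["sigma", "mean"] > 0.3


def test_pointwise_loglik_shape_and_rhat_bookkeeping(small_pairs):
    res = ps.fit(build_model(2, small_pairs), chains=2, iterations=200,
                 burn_in=100, seed=5)
    assert res.pointwise_loglik.shape == (2, 200, len(small_pairs))
    assert set(res.rhat) == {"sigma_w", "beta", "sigma"}


class TestGelmanRubin:
    def test_constant_chains_return_one(self):
        assert ps.gelman_rubin(np.ones((3, 50))) == 1.0

    def test_well_mixed_chains_below_1_05(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 10_000))
        assert ps.gelman_rubin(chains) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 5000), rng.normal(10, 1, 5000)])
        assert ps.gelman_rubin(chains) > 1.5

    def test_single_chain_errors(self):
        with pytest.raises(ValueError):
            ps.gelman_rubin(np.zeros((1, 100)))


class TestPosteriorSummary:
    def _result(self, draws):
        return PosteriorResult(
            spec=ModelSpec(1), draws=draws,
            pointwise_loglik=np.zeros((2, draws["sigma"].shape[1], 3)),
            rhat={k: 1.0 for k in draws}, seed=0,
            pair_ids=["a", "b", "c"], family_pairs=[],
        )

    def test_degenerate_draws_give_point_interval(self):
        res = self._result({"sigma": np.full((2, 100), 2.5),
                            "sigma_w": np.full((2, 100), 0.1)})
        row = ps.posterior_summary(res).loc["sigma"]
        assert row["q2.5"] == row["q97.5"] == 2.5

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(3)
        res = self._result({"sigma": rng.normal(size=(2, 200_000)),
                            "sigma_w": np.ones((2, 200_000))})
        row = ps.posterior_summary(res).loc["sigma"]
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.05)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.05)

    def test_trend_rescaling_to_600_myr(self):
        draws = {"beta": np.full((2, 100), -0.0217), "sigma": np.ones((2, 100)),
                 "sigma_w": np.ones((2, 100))}
        res = PosteriorResult(
            spec=ModelSpec(2), draws=draws,
            pointwise_loglik=np.zeros((2, 100, 3)),
            rhat={k: 1.0 for k in draws}, seed=0,
            pair_ids=["a", "b", "c"], family_pairs=[],
        )
        frame = ps.posterior_summary(res, transform_per_myr=600)
        assert frame.loc["beta", "change_over_600myr"] == pytest.approx(-0.13, abs=0.005)


def test_two_stage_variant_runs_and_differs(small_pairs):
    model = build_model(1, small_pairs)
    joint = ps.fit(model, chains=2, iterations=400, burn_in=150, seed=9)
    plug = ps.fit(model, chains=2, iterations=400, burn_in=150, seed=9, two_stage=True)
    assert joint.pointwise_loglik.shape == plug.pointwise_loglik.shape
    assert not np.allclose(joint.pointwise_loglik, plug.pointwise_loglik)
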