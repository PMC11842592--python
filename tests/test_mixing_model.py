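import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isomix import mixing_model as mm
from isomix import synthetic_data as synth
from isomix.isodata import (
    InvalidInputError,
    IsotopeSample,
    Period,
    Role,
    SourceSummary,
    TDFSpec,
)

from conftest import make_scenario


def _consumer(sample_id, d13c, d15n, cls=None, year=2002):
    return IsotopeSample(
        sample_id=sample_id, role=Role.CONSUMER, taxon="beluga",
        period=Period.P2000S, year=year, d13c=d13c, d15n=d15n,
        sex_age_class=cls,
    )


class TestIlr:
    def test_uniform_maps_to_zero(self):
        for k in range(2, 8):
            np.testing.assert_allclose(
                mm.ilr_transform(np.full(k, 1.0 / k)), np.zeros(k - 1), atol=1e-12
            )

    def test_k2_closed_form(self):
        p = np.array([0.731, 0.269])
        expected = math.log(0.731 / 0.269) / math.sqrt(2.0)
        assert mm.ilr_transform(p)[0] == pytest.approx(expected, abs=1e-12)

    def test_round_trip(self, rng):
        for k in (2, 3, 5, 7):
            p = rng.dirichlet(np.ones(k), size=10)
            z = mm.ilr_transform(p)
            np.testing.assert_allclose(mm.ilr_inverse(z, k), p, atol=1e-10)

    def test_matches_reference_implementation(self, rng):
        comp = pytest.importorskip("skbio.stats.composition")
        p = rng.dirichlet(np.ones(5))
        np.testing.assert_allclose(mm.ilr_transform(p), comp.ilr(p), atol=1e-10)

    def test_zero_component_rejected(self):
        with pytest.raises(InvalidInputError):
            mm.ilr_transform(np.array([0.0, 1.0]))

    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=2**31))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_property(self, k, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(k))
        p = np.clip(p, 1e-9, None)
        p /= p.sum()
        np.testing.assert_allclose(mm.ilr_inverse(mm.ilr_transform(p), k), p, atol=1e-9)


@pytest.fixture
def two_sources():
    return [
        SourceSummary("a", Period.P2000S, 10, np.array([-20.0, 12.0]),
                      np.array([1.0, 1.0]), np.array([0.4, 0.4])),
        SourceSummary("b", Period.P2000S, 10, np.array([-24.0, 16.0]),
                      np.array([2.0, 2.0]), np.array([0.2, 0.2])),
    ]


class TestMixtureMoments:
    def test_single_source_limit(self, tri_sources):
        tdf = TDFSpec(np.array([1.3, 2.4]), np.array([0.5, 0.5]))
        mu, var = mm.mixture_moments(np.array([1.0, 0.0, 0.0]), tri_sources, tdf)
        np.testing.assert_allclose(mu, tri_sources[0].mean + tdf.mean)
        np.testing.assert_allclose(var, tri_sources[0].sd**2 + tdf.sd**2)

    def test_equal_p_equal_conc_symmetry(self):
        tdf = TDFSpec(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        sources = [
            SourceSummary("a", Period.P2000S, 5, np.array([-20.0, 12.0]),
                          np.array([1.0, 1.0]), np.array([0.4, 0.1])),
            SourceSummary("b", Period.P2000S, 5, np.array([-24.0, 16.0]),
                          np.array([1.0, 1.0]), np.array([0.4, 0.1])),
        ]
        mu, _ = mm.mixture_moments(np.array([0.5, 0.5]), sources, tdf)
        np.testing.assert_allclose(mu, [(-20 - 24) / 2 + 1.0, (12 + 16) / 2 + 2.0])

    def test_hand_evaluated_concentration_weights(self, two_sources):
        # tracer 1 (carbon): conc (0.4, 0.2), p = (0.6, 0.4)
        # w = (0.24, 0.08)/0.32 = (0.75, 0.25)
        tdf = TDFSpec(np.array([1.3, 2.4]), np.array([0.5, 0.5]))
        mu, var = mm.mixture_moments(np.array([0.6, 0.4]), two_sources, tdf)
        expected_mu = 0.75 * (-20 + 1.3) + 0.25 * (-24 + 1.3)
        expected_var = 0.75**2 * (1.0 + 0.25) + 0.25**2 * (4.0 + 0.25)
        assert mu[0] == pytest.approx(expected_mu, abs=1e-12)
        assert var[0] == pytest.approx(expected_var, abs=1e-12)


class TestLogLikelihood:
    @pytest.fixture
    def unit_var_spec(self):
        # process variance exactly 1 per tracer: sd^2 0.64 + tdf sd^2 0.36
        sources = (
            SourceSummary("a", Period.P2000S, 5, np.array([-20.0, 12.0]),
                          np.array([0.8, 0.8]), np.array([0.4, 0.1])),
            SourceSummary("b", Period.P2000S, 5, np.array([-24.0, 16.0]),
                          np.array([0.8, 0.8]), np.array([0.4, 0.1])),
        )
        tdf = TDFSpec(np.array([0.0, 0.0]), np.array([0.6, 0.6]))
        return mm.MixingModelSpec(sources=sources, tdf=tdf)

    def test_observation_at_mean_closed_form(self, unit_var_spec):
        p = np.array([1.0, 0.0])
        mu, var = mm.mixture_moments(p, unit_var_spec.sources, unit_var_spec.tdf)
        np.testing.assert_allclose(var, [1.0, 1.0])
        c = _consumer("x", mu[0], mu[1])
        ll = mm.log_likelihood(c, p, unit_var_spec, np.array([1.0, 1.0]))
        assert ll == pytest.approx(2 * (-0.5 * math.log(2 * math.pi)), abs=1e-12)

    def test_xi_one_equals_process_only(self, unit_var_spec):
        c = _consumer("x", -21.0, 13.5)
        p = np.array([0.6, 0.4])
        with_xi = mm.log_likelihood(c, p, unit_var_spec, np.array([1.0, 1.0]))
        proc_spec = mm.MixingModelSpec(
            sources=unit_var_spec.sources, tdf=unit_var_spec.tdf,
            error_structure=mm.ErrorStructure.PROCESS_ONLY,
        )
        assert mm.log_likelihood(c, p, proc_spec) == pytest.approx(with_xi)

    def test_density_integrates_to_one(self, unit_var_spec):
        # quadrature oracle: exp(loglik) over a fine tracer grid sums to 1
        p = np.array([0.3, 0.7])
        mu, var = mm.mixture_moments(p, unit_var_spec.sources, unit_var_spec.tdf)
        xi = np.array([1.4, 0.8])
        sd = np.sqrt(var * xi)
        g1 = np.linspace(mu[0] - 8 * sd[0], mu[0] + 8 * sd[0], 201)
        g2 = np.linspace(mu[1] - 8 * sd[1], mu[1] + 8 * sd[1], 201)
        integral = np.trapezoid(
            [
                np.trapezoid(
                    np.exp([
                        mm.log_likelihood(_consumer("g", x1, x2), p, unit_var_spec, xi)
                        for x2 in g2
                    ]),
                    g2,
                )
                for x1 in g1
            ],
            g1,
        )
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_invalid_inputs(self, unit_var_spec):
        c = _consumer("x", -21.0, 13.5)
        with pytest.raises(InvalidInputError):
            mm.log_likelihood(c, np.array([0.5, 0.5]), unit_var_spec, np.array([0.0, 1.0]))
        bad = _consumer("y", math.nan, 13.5)
        with pytest.raises(InvalidInputError):
            mm.log_likelihood(bad, np.array([0.5, 0.5]), unit_var_spec)


class TestRhat:
    def test_same_distribution_near_one(self, rng):
        x = rng.normal(size=(4, 4000))
        assert mm.rhat(x) < 1.01

    def test_shifted_chains_flagged(self, rng):
        x = rng.normal(size=(4, 500)) + np.arange(4)[:, None] * 3.0
        assert mm.rhat(x) > 1.5

    def test_matches_reference_implementation(self, rng):
        az = pytest.importorskip("arviz")
        x = rng.normal(size=(4, 1000)) + 0.1 * np.arange(4)[:, None]
        ref = float(az.rhat(az.convert_to_dataset(x), method="split")["x"].values)
        assert mm.rhat(x) == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_nan(self):
        assert math.isnan(mm.rhat(np.ones((3, 100))))


class TestMixingPolygon:
    def test_centroid_consumer_included(self, tri_sources):
        tdf = TDFSpec(np.array([0.0, 0.0]), np.array([0.1, 0.1]))
        centroid = np.mean([s.mean for s in tri_sources], axis=0)
        c = _consumer("mid", centroid[0], centroid[1])
        probs = mm.mixing_polygon_check([c], tri_sources, tdf, n_iter=300, seed=0)
        assert probs["mid"] > 0.95

    def test_far_consumer_excluded(self, tri_sources):
        tdf = TDFSpec(np.array([0.0, 0.0]), np.array([0.1, 0.1]))
        c = _consumer("far", -10.0, 25.0)
        probs = mm.mixing_polygon_check([c], tri_sources, tdf, n_iter=300, seed=0)
        assert probs["far"] < 0.05

    def test_agrees_with_point_in_polygon_oracle(self, rng):
        from matplotlib.path import Path as MplPath

        # near-degenerate SDs freeze the hull at the source means
        sources = [
            SourceSummary(f"s{i}", Period.P2000S, 5, mean,
                          np.array([1e-9, 1e-9]), np.array([0.4, 0.1]))
            for i, mean in enumerate(
                [np.array([-22.0, 12.0]), np.array([-18.0, 14.0]), np.array([-20.0, 17.5])]
            )
        ]
        tdf = TDFSpec(np.array([0.0, 0.0]), np.array([0.0, 0.0]))
        pts = np.column_stack([rng.uniform(-24, -16, 40), rng.uniform(10, 19, 40)])
        consumers = [_consumer(f"c{i}", x, y) for i, (x, y) in enumerate(pts)]
        probs = mm.mixing_polygon_check(consumers, sources, tdf, n_iter=100, seed=1)
        hull = MplPath(np.array([s.mean for s in sources]))
        oracle = hull.contains_points(pts, radius=1e-9)
        for c, inside in zip(consumers, oracle):
            assert (probs[c.sample_id] > 0.5) == bool(inside)

    def test_short_run_warns(self, tri_sources, caplog):
        tdf = TDFSpec(np.zeros(2), np.zeros(2))
        with caplog.at_level("WARNING"):
            mm.mixing_polygon_check(
                [_consumer("a", -20.0, 14.0)], tri_sources, tdf, n_iter=50
            )
        assert any("coarse" in m for m in caplog.messages)


class TestSpecValidation:
    def test_individual_only_requires_process_only(self, tri_sources):
        with pytest.raises(InvalidInputError):
            mm.MixingModelSpec(
                sources=tuple(tri_sources), random_individual=True,
                error_structure=mm.ErrorStructure.RESIDUAL_X_PROCESS,
            )

    def test_single_source_rejected(self, tri_sources):
        with pytest.raises(InvalidInputError):
            mm.MixingModelSpec(sources=(tri_sources[0],))


class TestFit:
    def test_degenerate_fixture_concentrates_near_truth(self):
        scenario = make_scenario([("adult_male", (0.6, 0.3, 0.1))], seed=9, n_per=30)
        consumers, _ = synth.generate_consumers(scenario)
        spec = mm.MixingModelSpec(
            sources=tuple(synth.true_sources(scenario)),
            error_structure=mm.ErrorStructure.PROCESS_ONLY,
        )
        draws = mm.fit(spec, consumers, chains=3, iterations=2000, warmup=1500, seed=4)
        assert draws.converged
        post_mean = draws.global_p.mean(axis=0)
        post_sd = draws.global_p.std(axis=0)
        truth = np.array([0.6, 0.3, 0.1])
        assert np.all(np.abs(post_mean - truth) < 3 * post_sd + 0.02)

    def test_class_effect_orders_posteriors(self):
        scenario = make_scenario(
            [("adult_male", (0.7, 0.2, 0.1)), ("adult_female", (0.2, 0.7, 0.1))],
            seed=11, n_per=15,
        )
        consumers, _ = synth.generate_consumers(scenario)
        spec = mm.MixingModelSpec(
            sources=tuple(synth.true_sources(scenario)),
            fixed_effect=mm.FixedEffect.CLASS,
            error_structure=mm.ErrorStructure.PROCESS_ONLY,
        )
        draws = mm.fit(spec, consumers, chains=3, iterations=2000, warmup=1500, seed=5)
        level_means = draws.level_p.mean(axis=0)  # (L, K)
        # levels sorted: adult_female first, adult_male second
        labels = [str(lv) for lv in draws.fixed_levels]
        i_f = labels.index("SexAgeClass.ADULT_FEMALE") if "SexAgeClass.ADULT_FEMALE" in labels else 0
        i_m = 1 - i_f
        assert level_means[i_m, 0] > level_means[i_f, 0]
        assert level_means[i_f, 1] > level_means[i_m, 1]

    def test_draws_on_simplex_and_loglik_stored(self):
        scenario = make_scenario([("adult_male", (0.5, 0.3, 0.2))], seed=2, n_per=10)
        consumers, _ = synth.generate_consumers(scenario)
        spec = mm.MixingModelSpec(sources=tuple(synth.true_sources(scenario)))
        draws = mm.fit(spec, consumers, chains=2, iterations=300, warmup=300, seed=0)
        np.testing.assert_allclose(draws.p.sum(axis=2), 1.0, atol=1e-9)
        assert draws.loglik_pointwise.shape == (600, 10)
        assert np.all(np.isfinite(draws.loglik_pointwise))
        assert draws.error_mult is not None and np.all(draws.error_mult > 0)

    def test_flat_noise_posterior_near_prior(self):
        scenario = make_scenario([("adult_male", (0.5, 0.3, 0.2))], seed=3, n_per=20)
        consumers, _ = synth.generate_consumers(scenario)
        noisy = tuple(
            SourceSummary(s.group_label, s.period, s.n, s.mean,
                          np.array([25.0, 25.0]), s.conc)
            for s in synth.true_sources(scenario)
        )
        spec = mm.MixingModelSpec(sources=noisy, error_structure=mm.ErrorStructure.PROCESS_ONLY)
        draws = mm.fit(spec, consumers, chains=3, iterations=1500, warmup=1500, seed=6)
        np.testing.assert_allclose(draws.global_p.mean(axis=0), 1 / 3, atol=0.06)

    def test_missing_covariate_design_error(self, tri_sources):
        consumers = [_consumer("a", -20.0, 14.0), _consumer("b", -19.0, 14.5)]
        spec = mm.MixingModelSpec(
            sources=tuple(tri_sources), fixed_effect=mm.FixedEffect.CLASS,
        )
        with pytest.raises(mm.DesignError):
            mm.fit(spec, consumers, chains=2, iterations=10, warmup=10)


class TestPriorPosteriorCompare:
    def test_uniform_prior_marginals(self, tri_sources):
        scenario = make_scenario([("adult_male", (0.6, 0.3, 0.1))], seed=1, n_per=10)
        consumers, _ = synth.generate_consumers(scenario)
        spec = mm.MixingModelSpec(
            sources=tuple(synth.true_sources(scenario)),
            error_structure=mm.ErrorStructure.PROCESS_ONLY,
        )
        draws = mm.fit(spec, consumers, chains=2, iterations=200, warmup=200, seed=0)
        table = mm.prior_posterior_compare(spec, draws)
        assert len(table) == 3
        np.testing.assert_allclose(table["prior_mean"], 1 / 3)
        # informative data: posterior should overlap the prior less than fully
        assert (table["overlap"] < 0.9).all()
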