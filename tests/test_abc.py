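"""ABC machinery: priors, summary statistics, model choice, posteriors."""

import numpy as np
import pandas as pd
import pytest

from fragdiv import FragdivError, simulate_scenario
from fragdiv.abc import (
    AbcDesign,
    PriorSpec,
    abc_model_choice,
    abc_parameter_posterior,
    allele_size_variance,
    calibrate_event_times,
    combine_posteriors,
    make_scenario,
    posterior_summary,
    summary_stats,
)
from fragdiv.coalescent import ScenarioSpec


class TestPriors:
    def test_draws_respect_ranges_and_order(self):
        priors = PriorSpec()
        rng = np.random.default_rng(1)
        for _ in range(200):
            params = priors.draw(rng)
            for name, (low, high, _d) in priors.ranges.items():
                assert low <= params[name] <= high
            assert params["tb1"] <= params["t1"] <= params["t2"]

    def test_seeded_draws_are_reproducible(self):
        priors = PriorSpec()
        a = priors.draw(np.random.default_rng(7))
        b = priors.draw(np.random.default_rng(7))
        assert a == b

    def test_bad_range_rejected(self):
        with pytest.raises(FragdivError, match="range"):
            PriorSpec(ranges={"x": (5.0, 2.0, "uniform")})


@pytest.fixture(scope="module")
def tiny_scenario_matrix():
    spec = ScenarioSpec(
        scenario="1", focal_pops=["F1", "F2"], outgroup="OG",
        sample_sizes={"F1": 5, "F2": 5, "OG": 5},
        t1=200.0, t2=600.0, ne_br=2000.0, ne_sc=4000.0,
        tb1=25.0, ne_current=100.0)
    return simulate_scenario(spec, "ssr_length", 10, mu=5e-4, seed=5)


class TestSummaryStats:
    def test_invariant_to_individual_order(self, tiny_scenario_matrix):
        gm = tiny_scenario_matrix
        stats = summary_stats(gm, "ssr_length")
        perm = list(reversed(gm.individuals))
        stats_perm = summary_stats(gm.subset(individuals=perm), "ssr_length")
        pd.testing.assert_series_equal(stats, stats_perm)

    def test_length_statistics_refused_for_identity_coded(self, tiny_scenario_matrix):
        gm = tiny_scenario_matrix
        gm_id = gm.subset()
        gm_id.marker_kinds = ["ssr_id"] * gm.n_loci
        with pytest.raises(FragdivError, match="length-coded"):
            allele_size_variance(gm_id, 0, np.arange(gm_id.n_individuals))
        stats = summary_stats(gm_id, "ssr_id")
        assert "mean_allele_size_var" not in stats.index

    def test_monomorphic_dataset_degenerates_cleanly(self):
        spec = ScenarioSpec(
            scenario="1", focal_pops=["F1", "F2"], outgroup="OG",
            sample_sizes={"F1": 4, "F2": 4, "OG": 4},
            t1=100.0, t2=300.0, ne_br=500.0, ne_sc=500.0,
            tb1=10.0, ne_current=50.0)
        gm = simulate_scenario(spec, "ssr_length", 5, mu=0.0, seed=9)
        stats = summary_stats(gm, "ssr_length")
        assert stats["mean_alleles"] == 1.0
        assert stats["mean_he"] == 0.0
        assert stats["fst_global"] == 0.0  # undefined -> reported as 0


def _craft_table(rng, n_per_scenario=300, sep=4.0):
    """Two scenarios with Gaussian statistic clouds separated by ``sep``."""
    rows = []
    for scenario, centre in (("1", 0.0), ("2", sep)):
        stats = rng.normal(centre, 1.0, size=(n_per_scenario, 3))
        for k in range(n_per_scenario):
            rows.append({
                "scenario": scenario,
                "ne_br": float(rng.uniform(1000, 10000)),
                "stat:s1": stats[k, 0], "stat:s2": stats[k, 1],
                "stat:s3": stats[k, 2],
            })
    return pd.DataFrame(rows)


class TestModelChoice:
    def test_observation_inside_one_cloud_selects_it(self):
        rng = np.random.default_rng(11)
        table = _craft_table(rng)
        observed = pd.Series({"s1": 0.0, "s2": 0.0, "s3": 0.0})
        res = abc_model_choice(observed, table, retain_fraction=0.2)
        assert res.posteriors["1"] > 0.95

    def test_identical_generative_models_are_symmetric(self):
        rng = np.random.default_rng(12)
        posts = []
        for _ in range(10):
            table = _craft_table(rng, sep=0.0)
            observed = pd.Series({"s1": 0.0, "s2": 0.0, "s3": 0.0})
            res = abc_model_choice(observed, table, retain_fraction=0.2)
            posts.append(res.posteriors["1"])
        assert np.mean(posts) == pytest.approx(0.5, abs=0.12)

    def test_single_scenario_retained_falls_back_to_rejection(self):
        rng = np.random.default_rng(13)
        table = _craft_table(rng, sep=50.0)
        observed = pd.Series({"s1": 0.0, "s2": 0.0, "s3": 0.0})
        res = abc_model_choice(observed, table, retain_fraction=0.05)
        assert res.method == "rejection"
        assert res.posteriors == {"1": 1.0, "2": 0.0}

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(14)
        table = _craft_table(rng, sep=1.0)
        observed = pd.Series({"s1": 0.5, "s2": 0.5, "s3": 0.5})
        res = abc_model_choice(observed, table, retain_fraction=0.3)
        assert sum(res.posteriors.values()) == pytest.approx(1.0)


class TestParameterPosterior:
    def test_constant_parameter_returns_point_mass(self):
        rng = np.random.default_rng(15)
        table = _craft_table(rng)
        table["ne_br"] = 4242.0
        observed = pd.Series({"s1": 0.0, "s2": 0.0, "s3": 0.0})
        samples = abc_parameter_posterior(observed, table, ["ne_br"],
                                          retain_fraction=0.2)
        summary = posterior_summary(samples, "ne_br")
        assert summary["peak"] == pytest.approx(4242.0)
        assert summary["low"] == pytest.approx(4242.0)

    def test_uninformative_stats_reduce_to_rejection_sampling(self):
        # when the parameter is independent of every statistic the local
        # regression slope vanishes and adjustment changes nothing much
        rng = np.random.default_rng(16)
        table = _craft_table(rng, n_per_scenario=2000, sep=0.0)
        observed = pd.Series({"s1": 0.0, "s2": 0.0, "s3": 0.0})
        samples = abc_parameter_posterior(observed, table, ["ne_br"],
                                          retain_fraction=0.1)
        raw = table["ne_br"]
        assert samples["ne_br"].mean() == pytest.approx(raw.mean(), rel=0.1)
        assert samples["ne_br"].std() == pytest.approx(raw.std(), rel=0.25)

    def test_linear_relation_is_sharpened_by_adjustment(self):
        # parameter = stat + noise: regression adjustment should shrink
        # the retained spread toward the observed value
        rng = np.random.default_rng(17)
        n = 2000
        s = rng.normal(0, 1, n)
        table = pd.DataFrame({
            "scenario": "1",
            "theta": 10.0 + 5.0 * s + rng.normal(0, 0.1, n),
            "stat:s1": s,
        })
        observed = pd.Series({"s1": 0.0})
        samples = abc_parameter_posterior(observed, table, ["theta"],
                                          retain_fraction=0.25)
        assert samples["theta"].std() < 0.5  # raw retained spread ~ 5*0.25
        assert posterior_summary(samples, "theta")["peak"] == pytest.approx(
            10.0, abs=0.3)

    def test_adjusted_samples_clipped_to_prior_support(self):
        rng = np.random.default_rng(18)
        table = _craft_table(rng)
        observed = pd.Series({"s1": -8.0, "s2": -8.0, "s3": -8.0})
        priors = PriorSpec()
        samples = abc_parameter_posterior(observed, table, ["ne_br"],
                                          retain_fraction=0.2, priors=priors)
        low, high = priors.support("ne_br")
        assert (samples["ne_br"] >= low).all()
        assert (samples["ne_br"] <= high).all()


class TestCombinePosteriors:
    def test_identical_inputs_preserve_density(self):
        rng = np.random.default_rng(19)
        v = rng.normal(500, 40, 800)
        w = np.full(800, 1 / 800)
        out = combine_posteriors([(v, w), (v, w)], (0, 1000))
        assert out["peak"] == pytest.approx(500, abs=20)
        assert out["low"] < 500 < out["high"]

    def test_product_of_gaussians_peaks_at_midpoint(self):
        rng = np.random.default_rng(20)
        a = rng.normal(400, 50, 2000)
        b = rng.normal(600, 50, 2000)
        w = np.full(2000, 1 / 2000)
        out = combine_posteriors([(a, w), (b, w)], (0, 1000))
        assert out["peak"] == pytest.approx(500, abs=25)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(21)
        a = rng.normal(300, 30, 500)
        w = np.full(500, 1 / 500)
        out = combine_posteriors([(a, w), (a + 10, w)], (0, 1000))
        assert np.trapezoid(out["density"], out["grid"]) == pytest.approx(1.0)

    def test_disjoint_posteriors_rejected(self):
        a = np.full(100, 100.0) + np.random.default_rng(0).normal(0, 1, 100)
        b = a + 800.0
        w = np.full(100, 0.01)
        with pytest.raises(FragdivError, match="overlap"):
            combine_posteriors([(a, w), (b, w)], (0, 1000))


class TestCalibration:
    @pytest.mark.parametrize("gens,want", [
        (23, (230, 345)), (11, (110, 165)), (0, (0, 0))])
    def test_generation_time_scaling(self, gens, want):
        assert calibrate_event_times(gens, (10, 15)) == want

    def test_negative_input_rejected(self):
        with pytest.raises(FragdivError):
            calibrate_event_times(-1, (10, 15))
        with pytest.raises(FragdivError):
            calibrate_event_times(5, (15, 10))


class TestMakeScenario:
    def test_scenario_1b_binds_per_population_sizes(self):
        design = AbcDesign(focal_pops=["A", "B"], outgroup="O",
                           sample_sizes={"A": 4, "B": 4, "O": 4},
                           marker="snp", n_loci=5)
        params = dict(t1=100.0, t2=400.0, tb1=20.0, ne_br=2000.0,
                      ne_sc=3000.0, ne_current_A=60.0, ne_current_B=900.0)
        spec = make_scenario("1b", design, params)
        assert spec.current_size("A") == 60.0
        assert spec.current_size("B") == 900.0
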