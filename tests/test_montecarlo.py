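"""Monte Carlo propagation of the chronic hazard index."""

import math

import numpy as np
import pytest

from citrusrisk import (
    DistributionSpec,
    McConfig,
    PesticideInfo,
    PopulationProfile,
    ReferenceSet,
    ResidueRecord,
    ResidueTable,
    config_from_survey,
    run_chronic_mc,
    sensitivity_rank_correlation,
    summarize_mc,
)
from citrusrisk.errors import ConfigurationError, ValidationError
from citrusrisk.montecarlo import draws_frame, lognormal_fit_detected


@pytest.fixture
def one_pesticide_refs():
    return ReferenceSet([PesticideInfo("imazalil", ld50=227, adi=0.025, arfd=0.05)])


def point(name, value):
    return DistributionSpec(name, "point", {"value": value})


class TestRunChronicMc:
    def test_point_masses_reproduce_deterministic_hi(self, one_pesticide_refs):
        config = McConfig(
            specs=[point("fi", 0.04), point("bw", 70.0), point("conc:imazalil", 0.5)],
            n_iter=100,
            seed=1,
        )
        result = run_chronic_mc(config, one_pesticide_refs)
        expected = 0.5 * 0.04 / (70.0 * 0.025)
        assert np.all(result.hi_draws == result.hi_draws[0])
        assert result.summary["median"] == pytest.approx(expected, rel=1e-15)
        assert result.summary["sd"] == 0.0

    def test_same_seed_bitwise_identical(self, one_pesticide_refs):
        config = McConfig(
            specs=[
                DistributionSpec("fi", "lognormal", {"median": 0.04, "gsd": 1.5}),
                DistributionSpec("bw", "normal", {"mean": 70, "sd": 10}),
                DistributionSpec("conc:imazalil", "lognormal", {"median": 0.5, "gsd": 2.0}),
            ],
            n_iter=2000,
            seed=42,
        )
        r1 = run_chronic_mc(config, one_pesticide_refs)
        r2 = run_chronic_mc(config, one_pesticide_refs)
        assert np.array_equal(r1.hi_draws, r2.hi_draws)
        assert r1.summary == r2.summary

    def test_missing_spec_names_variable(self, one_pesticide_refs):
        with pytest.raises(ConfigurationError, match="fi"):
            run_chronic_mc(
                McConfig(specs=[point("bw", 70), point("conc:imazalil", 0.5)], n_iter=10),
                one_pesticide_refs,
            )
        with pytest.raises(ConfigurationError, match="conc"):
            run_chronic_mc(
                McConfig(specs=[point("fi", 0.04), point("bw", 70)], n_iter=10),
                one_pesticide_refs,
            )

    def test_body_weight_truncated_positive(self, one_pesticide_refs):
        config = McConfig(
            specs=[
                point("fi", 0.04),
                DistributionSpec("bw", "normal", {"mean": 5.0, "sd": 20.0}),
                point("conc:imazalil", 0.5),
            ],
            n_iter=5000,
            seed=7,
        )
        result = run_chronic_mc(config, one_pesticide_refs)
        assert (result.input_draws["bw"] > 0).all()
        assert np.isfinite(result.hi_draws).all()

    def test_lognormal_median_converges_to_closed_form(self, one_pesticide_refs):
        """With one lognormal concentration and fixed fi/bw/ADI, the HI median
        converges to m*fi/(bw*ADI); check within 3 Monte Carlo SEs."""
        m, gsd, fi, bw, adi, n = 0.5, 2.0, 0.04, 70.0, 0.025, 100_000
        config = McConfig(
            specs=[
                point("fi", fi),
                point("bw", bw),
                DistributionSpec("conc:imazalil", "lognormal", {"median": m, "gsd": gsd}),
            ],
            n_iter=n,
            seed=3,
        )
        result = run_chronic_mc(config, one_pesticide_refs)
        target = m * fi / (bw * adi)
        sigma = math.log(gsd)
        se_median = target * sigma * math.sqrt(2 * math.pi) / (2 * math.sqrt(n))
        assert abs(result.summary["median"] - target) < 3 * se_median

    def test_adi_uniform_override(self, one_pesticide_refs):
        config = McConfig(
            specs=[
                point("fi", 0.04),
                point("bw", 70.0),
                point("conc:imazalil", 0.5),
                DistributionSpec("adi:imazalil", "uniform", {"low": 0.02, "high": 0.03}),
            ],
            n_iter=4000,
            seed=5,
        )
        result = run_chronic_mc(config, one_pesticide_refs)
        lo = 0.5 * 0.04 / (70 * 0.03)
        hi = 0.5 * 0.04 / (70 * 0.02)
        assert result.hi_draws.min() >= lo - 1e-12
        assert result.hi_draws.max() <= hi + 1e-12


class TestSummaries:
    def test_basic_statistics(self):
        s = summarize_mc(np.array([1.0, 2.0, 3.0]))
        assert s["median"] == 2.0
        assert s["mean"] == 2.0
        assert summarize_mc(np.full(10, 5.0))["sd"] == 0.0

    def test_right_skewed_lognormal(self):
        rng = np.random.default_rng(0)
        draws = rng.lognormal(0, 1, 50_000)
        s = summarize_mc(draws)
        assert s["mean"] > s["median"]
        assert s["skewness"] > 0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_mc(np.array([]))


class TestSensitivity:
    def test_signs_of_ingestion_and_body_weight(self, one_pesticide_refs):
        config = McConfig(
            specs=[
                DistributionSpec("fi", "lognormal", {"median": 0.04, "gsd": 1.5}),
                DistributionSpec("bw", "normal", {"mean": 70, "sd": 10}),
                DistributionSpec("conc:imazalil", "lognormal", {"median": 0.5, "gsd": 2.0}),
            ],
            n_iter=20_000,
            seed=9,
        )
        result = run_chronic_mc(config, one_pesticide_refs)
        assert result.sensitivity["fi"] > 0  # more intake, more risk
        assert result.sensitivity["bw"] < 0  # heavier body, less risk

    def test_perfect_monotone_gives_rho_one(self):
        x = np.linspace(1, 10, 100)
        hi = np.exp(x)  # monotone transform of the single input
        rho = sensitivity_rank_correlation({"x": x}, hi)
        assert rho["x"] == pytest.approx(1.0)

    def test_dummy_variable_is_null(self, one_pesticide_refs):
        """An input outside the formula correlates with HI only by chance:
        |rho| stays within ~3/sqrt(n) of zero."""
        n = 10_000
        config = McConfig(
            specs=[
                DistributionSpec("fi", "lognormal", {"median": 0.04, "gsd": 1.5}),
                point("bw", 70.0),
                DistributionSpec("conc:imazalil", "lognormal", {"median": 0.5, "gsd": 2.0}),
                DistributionSpec("dummy", "uniform", {"low": 0.0, "high": 1.0}),
            ],
            n_iter=n,
            seed=13,
        )
        result = run_chronic_mc(config, one_pesticide_refs)
        assert abs(result.sensitivity["dummy"]) < 3.5 / math.sqrt(n)

    def test_constant_input_flagged_nan(self):
        rho = sensitivity_rank_correlation(
            {"const": np.full(10, 2.0)}, np.arange(10, dtype=float)
        )
        assert math.isnan(rho["const"])

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity_rank_correlation({"x": np.array([1.0, 2.0])}, np.array([1.0, 2.0]))


class TestSurveyWiring:
    def test_lognormal_fit_matches_median_and_log_sd(self):
        rng = np.random.default_rng(21)
        data = rng.lognormal(math.log(0.3), math.log(2.0), 500)
        median, gsd = lognormal_fit_detected(data)
        assert median == pytest.approx(np.median(data))
        assert math.log(gsd) == pytest.approx(np.std(np.log(data), ddof=1))

    def test_single_detection_degenerates_to_point(self):
        median, gsd = lognormal_fit_detected(np.array([0.7]))
        assert (median, gsd) == (0.7, 1.0)

    def test_config_from_survey_covers_all_detected(self, survey_table, refs):
        profile = PopulationProfile("adults", bw=70, fi=0.04, lp=0.3)
        config = config_from_survey(survey_table, profile, n_iter=500, seed=2)
        detected = set(survey_table.detections["pesticide"])
        spec_names = {s.variable for s in config.specs}
        assert {f"conc:{p}" for p in detected} <= spec_names
        result = run_chronic_mc(config, refs)
        frame = draws_frame(result)
        assert len(frame) == 500
        assert "hi" in frame.columns
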