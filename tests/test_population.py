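"""Synthetic study populations: generation modes, moments, summaries, IO."""

import numpy as np
import pandas as pd
import pytest

from pubsel.population import (
    EmptySelectionError,
    InvalidConfigError,
    PopulationConfig,
    generate_population,
    make_distribution,
    quality_summary,
    read_population,
    write_population,
)

UNIFORM = {"kind": "uniform", "low": 0.0, "high": 100.0}


@pytest.fixture(scope="module")
def uniform_population():
    config = PopulationConfig(n=100_000, mode="sign_first", prop_positive=0.5, seed=1)
    return generate_population(config)


class TestSignFirst:
    def test_moments_match_the_configured_mix(self, uniform_population):
        """n=100000, prop 0.5, uniform qualities: binomial and uniform-moment
        checks at 3 sigma."""
        frac_pos = (uniform_population["sign"] == "positive").mean()
        assert frac_pos == pytest.approx(0.5, abs=0.005)
        assert uniform_population["quality"].mean() == pytest.approx(50.0, abs=0.3)

    def test_flags_start_unset(self, uniform_population):
        assert uniform_population["submitted"].isna().all()
        assert uniform_population["accepted"].isna().all()

    def test_per_sign_distributions_can_differ(self):
        config = PopulationConfig(
            n=20_000,
            quality_dist_pos={"kind": "truncnorm", "mean": 30.0, "sd": 10.0},
            quality_dist_neg={"kind": "truncnorm", "mean": 70.0, "sd": 10.0},
            seed=3,
        )
        pop = generate_population(config)
        mean_pos = pop.loc[pop["sign"] == "positive", "quality"].mean()
        mean_neg = pop.loc[pop["sign"] == "negative", "quality"].mean()
        assert mean_neg - mean_pos > 30
        assert not config.identical_distributions

    def test_identical_distribution_flag(self):
        config = PopulationConfig(n=10, seed=0)
        assert config.identical_distributions


class TestQualityFirst:
    def test_symmetric_coupling_gives_half_positive(self):
        """Uniform quality with the coupling centred at 50 splits signs evenly."""
        config = PopulationConfig(
            n=100_000,
            mode="quality_first",
            coupling_location=50.0,
            coupling_scale=15.0,
            seed=2,
        )
        pop = generate_population(config)
        assert (pop["sign"] == "positive").mean() == pytest.approx(0.5, abs=0.005)

    def test_positive_fraction_monotone_in_quality(self):
        """Higher-quality bins contain a larger share of positive outcomes."""
        config = PopulationConfig(
            n=200_000, mode="quality_first", coupling_scale=15.0, seed=5
        )
        pop = generate_population(config)
        bins = pd.cut(pop["quality"], np.arange(0, 101, 10))
        frac = (
            (pop["sign"] == "positive").groupby(bins, observed=True).mean().to_numpy()
        )
        assert np.all(np.diff(frac) > -0.01)  # monotone up to binomial noise
        assert frac[-1] > frac[0] + 0.5


@pytest.mark.parametrize(
    "spec",
    [
        UNIFORM,
        {"kind": "uniform", "low": 20.0, "high": 60.0},
        {"kind": "truncnorm", "mean": 50.0, "sd": 15.0},
        {"kind": "truncnorm", "mean": -10.0, "sd": 30.0},
        {"kind": "beta", "a": 2.0, "b": 5.0},
        {"kind": "point", "at": 42.0},
    ],
    ids=lambda s: s["kind"],
)
def test_all_distributions_respect_the_quality_range(spec):
    dist = make_distribution(spec)
    draws = dist.sample(np.random.default_rng(0), 5000)
    assert np.all((draws >= 0.0) & (draws <= 100.0))


def test_seeded_determinism():
    config = PopulationConfig(n=1000, seed=11)
    a = generate_population(config)
    b = generate_population(config)
    pd.testing.assert_frame_equal(a, b)
    c = generate_population(config, seed=12)
    assert not a["quality"].equals(c["quality"])


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=0),
            dict(n=10, mode="outcome_first"),
            dict(n=10, prop_positive=1.5),
            dict(n=10, quality_dist_pos={"kind": "gamma", "a": 1}),
            dict(n=10, quality_dist_neg={"kind": "truncnorm", "mean": 50, "sd": -1}),
            dict(n=10, quality_dist_pos={"kind": "uniform", "low": -5, "high": 50}),
            dict(n=10, mode="quality_first", coupling_scale=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            PopulationConfig(**kwargs)

    def test_unknown_fields_rejected(self):
        with pytest.raises(InvalidConfigError):
            PopulationConfig.from_dict({"n": 10, "effect_size": 0.3})

    def test_config_dict_round_trip(self):
        config = PopulationConfig(n=50, prop_positive=0.3, seed=9)
        assert PopulationConfig.from_dict(config.to_dict()) == config


class TestQualitySummary:
    def test_two_study_arithmetic(self):
        studies = pd.DataFrame(
            {
                "quality": [40.0, 60.0],
                "sign": ["positive", "negative"],
                "submitted": pd.array([pd.NA, pd.NA], dtype="boolean"),
                "accepted": pd.array([pd.NA, pd.NA], dtype="boolean"),
            }
        )
        out = quality_summary(studies)
        assert out.loc["all", "n"] == 2
        assert out.loc["all", "mean"] == pytest.approx(50.0)

    def test_uniform_standard_deviation(self, uniform_population):
        """A uniform [0,100] population has sd 100/sqrt(12) ~= 28.87."""
        out = quality_summary(uniform_population)
        assert out.loc["all", "sd"] == pytest.approx(28.87, abs=0.3)

    def test_missing_sign_is_flagged_not_fabricated(self):
        studies = pd.DataFrame(
            {
                "quality": [55.0, 65.0],
                "sign": ["positive", "positive"],
                "submitted": pd.array([True, True], dtype="boolean"),
                "accepted": pd.array([True, False], dtype="boolean"),
            }
        )
        out = quality_summary(studies, by_sign=True)
        assert out.loc["negative", "n"] == 0
        assert np.isnan(out.loc["negative", "mean"])
        assert out.loc["positive", "mean"] == pytest.approx(60.0)

    def test_submitted_only_filter(self):
        studies = pd.DataFrame(
            {
                "quality": [10.0, 90.0],
                "sign": ["positive", "negative"],
                "submitted": pd.array([False, True], dtype="boolean"),
                "accepted": pd.array([False, True], dtype="boolean"),
            }
        )
        out = quality_summary(studies, submitted_only=True)
        assert out.loc["all", "n"] == 1
        assert out.loc["all", "mean"] == pytest.approx(90.0)

    def test_empty_selection_raises(self):
        studies = pd.DataFrame(
            {
                "quality": [10.0],
                "sign": ["positive"],
                "submitted": pd.array([False], dtype="boolean"),
                "accepted": pd.array([False], dtype="boolean"),
            }
        )
        with pytest.raises(EmptySelectionError):
            quality_summary(studies, submitted_only=True)
        with pytest.raises(EmptySelectionError):
            quality_summary(studies.iloc[:0])


def test_csv_round_trip(tmp_path):
    config = PopulationConfig(n=200, seed=4)
    pop = generate_population(config)
    path = tmp_path / "pop.csv"
    write_population(pop, path, config=config)
    loaded = read_population(path)
    pd.testing.assert_frame_equal(loaded, pop)
    sidecar = tmp_path / "pop.csv.json"
    assert sidecar.exists()
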