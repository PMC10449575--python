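"""Paired-measurement scoring: percent change, dual utilities, trial handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apoia_biostim import (
    ApoiaScorer,
    TrialDataset,
    ZeroControlError,
    percent_change,
    read_measurements_csv,
    score_indicator,
    score_trial,
    write_measurements_csv,
)
from apoia_biostim.scoring import measurements_to_frame

from conftest import make_indicator, make_measurement


class TestPercentChange:
    @pytest.mark.parametrize(
        "control, treatment, expected",
        [(100.0, 100.0, 0.0), (50.0, 75.0, 50.0), (80.0, 60.0, -25.0)],
    )
    def test_formula(self, control, treatment, expected):
        assert percent_change(control, treatment) == pytest.approx(expected, abs=1e-12)

    def test_zero_control_refused(self):
        with pytest.raises(ZeroControlError):
            percent_change(0.0, 10.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        control=st.floats(min_value=1e-3, max_value=1e6),
        treatment=st.floats(min_value=0, max_value=1e6),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_equivariance(self, control, treatment, scale):
        base = percent_change(control, treatment)
        scaled = percent_change(control * scale, treatment * scale)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestScoreIndicator:
    def test_identical_arms_give_baseline_utility(self, enzyme_indicator):
        r = score_indicator(
            enzyme_indicator,
            make_measurement([100.0, 110.0, 90.0], arm="control"),
            make_measurement([100.0, 110.0, 90.0], arm="biostimulant"),
        )
        assert r.index1_percent_change == pytest.approx(0.0, abs=1e-12)
        assert r.utility_impact == pytest.approx(0.7, abs=1e-12)

    def test_treatment_at_top_threshold_hits_top_knot_utility(self, enzyme_indicator):
        r = score_indicator(
            enzyme_indicator,
            make_measurement([150.0], arm="control"),
            make_measurement([200.0], arm="biostimulant"),
        )
        assert r.index2_level == 200.0
        top_utility = enzyme_indicator.performance_table[-1].utility
        assert r.utility_performance == pytest.approx(top_utility, abs=1e-12)

    def test_beyond_threshold_clamps_to_top_knot(self, enzyme_indicator):
        r = score_indicator(
            enzyme_indicator,
            make_measurement([150.0], arm="control"),
            make_measurement([250.0], arm="biostimulant"),
        )
        assert r.utility_performance == pytest.approx(
            enzyme_indicator.performance_table[-1].utility, abs=1e-12
        )

    def test_negative_good_improvement_raises_impact_utility(self):
        compaction = make_indicator(
            indicator_id="soil_compaction",
            direction="negative-good",
            impact_points=((-50.0, 1.0), (0.0, 0.7), (50.0, 0.3)),
            performance_points=((0.0, 1.0), (2.4, 0.7), (6.0, 0.1)),
            explanatory_range=(0.0, 6.0),
            performance_baseline_level=2.4,
            units="MPa",
        )
        r = score_indicator(
            compaction,
            make_measurement([3.0], arm="control", indicator_id="soil_compaction"),
            make_measurement([2.4], arm="biostimulant", indicator_id="soil_compaction"),
        )
        assert r.utility_impact > 0.7

    def test_missing_control_skips_impact_keeps_performance(self, enzyme_indicator):
        r = score_indicator(
            enzyme_indicator, None, make_measurement([120.0], arm="biostimulant")
        )
        assert r.utility_impact is None
        assert r.utility_performance == pytest.approx(0.7, abs=1e-12)
        assert any("missing control" in f for f in r.flags)

    def test_zero_control_flagged_not_raised(self, enzyme_indicator):
        r = score_indicator(
            enzyme_indicator,
            make_measurement([0.0], arm="control"),
            make_measurement([50.0], arm="biostimulant"),
        )
        assert r.utility_impact is None
        assert any("zero control" in f for f in r.flags)

    def test_unit_mismatch_rejected(self, enzyme_indicator):
        bad = make_measurement([100.0], arm="biostimulant").model_copy(
            update={"unit": "furlongs"}
        )
        with pytest.raises(ValueError, match="unit mismatch"):
            score_indicator(enzyme_indicator, None, bad)

    def test_median_summarizer_resists_outlier(self, enzyme_indicator):
        control = make_measurement([100.0, 100.0, 100.0], arm="control")
        treatment = make_measurement([100.0, 100.0, 10000.0], arm="biostimulant")
        r = score_indicator(enzyme_indicator, control, treatment, summarizer="median")
        assert r.index1_percent_change == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        base=st.floats(min_value=10, max_value=200),
        lift_a=st.floats(min_value=0, max_value=1.0),
        lift_b=st.floats(min_value=0, max_value=1.0),
    )
    def test_effect_monotonicity(self, base, lift_a, lift_b):
        """Raising the treatment arm of a positive-good indicator never lowers utility."""
        enzyme_indicator = make_indicator()
        lo, hi = sorted((lift_a, lift_b))
        control = make_measurement([base], arm="control")
        u = [
            score_indicator(
                enzyme_indicator,
                control,
                make_measurement([base * (1 + lift)], arm="biostimulant"),
            ).utility_impact
            for lift in (lo, hi)
        ]
        assert u[0] <= u[1] + 1e-9


class TestScoreTrial:
    def _trial(self, values_by_indicator, farm_id="farm_01"):
        measurements = []
        for iid, (c, t) in values_by_indicator.items():
            measurements.append(make_measurement(c, arm="control", indicator_id=iid, farm_id=farm_id))
            measurements.append(make_measurement(t, arm="biostimulant", indicator_id=iid, farm_id=farm_id))
        return TrialDataset(farm_id=farm_id, measurements=measurements)

    def test_scores_only_indicators_with_data(self, tiny_config):
        trial = self._trial({"beta_glycosidase": ([100.0], [120.0])})
        results = score_trial(tiny_config, trial)
        assert [r.indicator_id for r in results] == ["beta_glycosidase"]

    def test_unknown_indicator_rejected(self, tiny_config):
        trial = self._trial({"mystery_variable": ([1.0], [2.0])})
        with pytest.raises(ValueError, match="mystery_variable"):
            score_trial(tiny_config, trial)

    def test_empty_dataset_gives_empty_results(self, tiny_config):
        assert score_trial(tiny_config, TrialDataset(farm_id="farm_01")) == []

    def test_full_default_config_minus_plant_health_scores_29(self, config):
        values = {
            ind.indicator_id: ([100.0], [110.0])
            for ind in config.indicators
            if ind.theme_id != "plant_health"
        }
        results = score_trial(config, self._trial(values))
        assert len(results) == 29

    def test_uniform_positive_effect_lifts_all_positive_good_utilities(self, config):
        values = {
            ind.indicator_id: ([100.0], [120.0])
            for ind in config.indicators
            if ind.direction == "positive-good" and ind.theme_id != "plant_health"
        }
        results = score_trial(config, self._trial(values))
        assert results and all(r.utility_impact > 0.7 for r in results)


class TestScorerTransformer:
    def test_transform_matches_functional_surface(self, tiny_config):
        trial = TrialDataset(
            farm_id="farm_01",
            measurements=[
                make_measurement([100.0, 105.0], arm="control"),
                make_measurement([118.0, 122.0], arm="biostimulant"),
            ],
        )
        expected = score_trial(tiny_config, trial)
        scorer = ApoiaScorer(config=tiny_config).fit()
        out = scorer.transform(measurements_to_frame([trial]))
        assert len(out) == len(expected) == 1
        assert out.loc[0, "utility_impact"] == pytest.approx(expected[0].utility_impact)

    def test_sklearn_param_interface(self, tiny_config):
        scorer = ApoiaScorer()
        assert set(scorer.get_params()) == {"config", "summarizer"}
        scorer.set_params(config=tiny_config, summarizer="median")
        assert scorer.fit().summarizer == "median"

    def test_unfitted_transform_refused(self):
        with pytest.raises(RuntimeError):
            ApoiaScorer().transform(pd.DataFrame())


class TestCsvRoundTrip:
    def test_round_trip_preserves_scores(self, tiny_config, tmp_path):
        trial = TrialDataset(
            farm_id="farm_01",
            measurements=[
                make_measurement([100.0, 105.0, 95.0], arm="control"),
                make_measurement([118.0, 122.0, 120.0], arm="biostimulant"),
            ],
        )
        path = tmp_path / "measurements.csv"
        write_measurements_csv([trial], path)
        (loaded,) = read_measurements_csv(path)
        a = score_trial(tiny_config, trial)
        b = score_trial(tiny_config, loaded)
        assert [r.utility_impact for r in a] == [r.utility_impact for r in b]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("farm_id,indicator_id,value\nf,beta_glycosidase,1\n", encoding="utf-8")
        with pytest.raises(ValueError, match="missing columns"):
            read_measurements_csv(path)
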