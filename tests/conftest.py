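import pytest

from apoia_biostim import (
    CorrespondencePoint,
    FieldMeasurement,
    IndicatorDefinition,
    SystemConfig,
    ThemeDefinition,
    default_config,
)


@pytest.fixture(scope="session")
def config() -> SystemConfig:
    return default_config()


def make_indicator(
    indicator_id="beta_glycosidase",
    direction="positive-good",
    impact_points=((-50.0, 0.3), (0.0, 0.7), (50.0, 1.0)),
    performance_points=((0.0, 0.1), (120.0, 0.7), (200.0, 1.0)),
    explanatory_range=(0.0, 200.0),
    baseline_utility=0.7,
    performance_baseline_level=120.0,
    units="mg p-nitrophenol·kg soil⁻¹·h⁻¹",
) -> IndicatorDefinition:
    return IndicatorDefinition(
        indicator_id=indicator_id,
        name=indicator_id,
        theme_id="soil_biology",
        units=units,
        direction=direction,
        explanatory_range=explanatory_range,
        impact_table=[
            CorrespondencePoint(calculated_index=x, utility=u) for x, u in impact_points
        ],
        performance_table=[
            CorrespondencePoint(calculated_index=x, utility=u) for x, u in performance_points
        ],
        baseline_utility=baseline_utility,
        performance_baseline_level=performance_baseline_level,
    )


def make_measurement(values, arm="control", indicator_id="beta_glycosidase", farm_id="farm_01"):
    return FieldMeasurement(
        farm_id=farm_id,
        indicator_id=indicator_id,
        arm=arm,
        replicate_values=list(values),
    )


@pytest.fixture
def enzyme_indicator() -> IndicatorDefinition:
    return make_indicator()


@pytest.fixture
def tiny_config(enzyme_indicator) -> SystemConfig:
    compaction = make_indicator(
        indicator_id="soil_compaction",
        direction="negative-good",
        impact_points=((-50.0, 1.0), (0.0, 0.7), (50.0, 0.3)),
        performance_points=((0.0, 1.0), (2.4, 0.7), (6.0, 0.1)),
        explanatory_range=(0.0, 6.0),
        performance_baseline_level=2.4,
        units="MPa",
    )
    compaction = compaction.model_copy(update={"theme_id": "soil_physics"})
    return SystemConfig(
        themes=[
            ThemeDefinition(
                theme_id="soil_biology", name="soil biology", indicator_ids=["beta_glycosidase"]
            ),
            ThemeDefinition(
                theme_id="soil_physics", name="soil physics", indicator_ids=["soil_compaction"]
            ),
        ],
        indicators=[enzyme_indicator, compaction],
    )
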