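"""Construction of the built-in biostimulant indicator system.

Correspondence-table knots here are defensible agronomic defaults, not
published calibrations: impact tables map percent change (control vs
treatment) with the mandatory baseline anchor at (0 %, 0.7); performance
tables span each indicator's explanatory range with the technical
suitability level anchored at 0.7.  Users are expected to override them
with locally calibrated tables via ``load_config``.
"""

from __future__ import annotations

from .schema import (
    CorrespondencePoint,
    IndicatorDefinition,
    SystemConfig,
    ThemeDefinition,
)

BASELINE = 0.7

# indicator_id, display name, units, direction, explanatory range (lo, hi)
_CROP_PRODUCTION = [
    ("stand_quality", "Stand quality", "plants·m⁻²", "positive-good", (0.0, 40.0)),
    ("plant_vigor_1", "Plant vigor 1 (pods or grains per plant)", "count·plant⁻¹", "positive-good", (0.0, 120.0)),
    ("plant_vigor_2", "Plant vigor 2 (leaves per plant, internodes)", "count·plant⁻¹", "positive-good", (0.0, 60.0)),
    ("plant_vigor_3", "Plant vigor 3 (length of branches and stems)", "cm", "positive-good", (0.0, 250.0)),
    ("plant_vigor_4", "Plant vigor 4 (average plant height)", "cm", "positive-good", (0.0, 300.0)),
    ("rooting", "Root development", "root dry mass g·plant⁻¹", "positive-good", (0.0, 50.0)),
    ("product_quality", "Product quality (1000-seed weight; TRS for sugarcane)", "g or kg·t⁻¹", "positive-good", (0.0, 400.0)),
    ("crop_productivity", "Crop productivity", "bags·ha⁻¹ or t·ha⁻¹", "positive-good", (0.0, 300.0)),
    ("net_revenue", "Net revenue", "$·ha⁻¹", "positive-good", (0.0, 5000.0)),
]

_SOIL_CHEMISTRY = [
    ("soil_ph", "Soil pH", "pH (CaCl₂)", "positive-good", (3.5, 8.0)),
    ("phosphorus", "Available phosphorus (P)", "mg·dm⁻³", "positive-good", (0.0, 120.0)),
    ("potassium", "Exchangeable potassium (K)", "mmolc·dm⁻³", "positive-good", (0.0, 10.0)),
    ("ca_mg", "Exchangeable Ca+Mg", "mmolc·dm⁻³", "positive-good", (0.0, 100.0)),
    ("cec", "Cation exchange capacity (CEC)", "mmolc·dm⁻³", "positive-good", (0.0, 200.0)),
    ("total_bases", "Total bases (SB)", "mmolc·dm⁻³", "positive-good", (0.0, 150.0)),
    ("base_saturation", "Base saturation (V%)", "%", "positive-good", (0.0, 100.0)),
    ("potential_acidity", "Potential acidity (H+Al)", "mmolc·dm⁻³", "negative-good", (0.0, 120.0)),
    ("organic_matter", "Soil organic matter", "g·dm⁻³", "positive-good", (0.0, 80.0)),
]

_SOIL_PHYSICS = [
    ("soil_compaction", "Soil compaction (penetration resistance)", "MPa", "negative-good", (0.0, 6.0)),
    ("bulk_density", "Bulk density", "g·cm⁻³", "negative-good", (0.8, 2.0)),
    ("water_infiltration", "Water infiltration rate", "mm·h⁻¹", "positive-good", (0.0, 200.0)),
    ("aggregate_stability", "Aggregate stability (MWD)", "mm", "positive-good", (0.0, 5.0)),
    ("water_retention", "Soil water retention", "% v/v", "positive-good", (0.0, 60.0)),
]

_SOIL_BIOLOGY = [
    ("arylsulfatase", "Arylsulfatase activity", "mg p-nitrophenol·kg soil⁻¹·h⁻¹", "positive-good", (0.0, 120.0)),
    ("beta_glycosidase", "β-Glycosidase activity", "mg p-nitrophenol·kg soil⁻¹·h⁻¹", "positive-good", (0.0, 200.0)),
    ("acid_phosphatase", "Acid phosphatase activity", "mg p-nitrophenol·kg soil⁻¹·h⁻¹", "positive-good", (0.0, 1200.0)),
    ("microbial_biomass_c", "Microbial biomass carbon", "mg C·kg soil⁻¹", "positive-good", (0.0, 800.0)),
    ("basal_respiration", "Soil basal respiration", "mg C-CO₂·kg soil⁻¹·day⁻¹", "positive-good", (0.0, 50.0)),
    ("metabolic_quotient", "Metabolic quotient (qCO₂)", "mg C-CO₂·mg⁻¹ Cmic·h⁻¹ ×10⁻³", "negative-good", (0.0, 10.0)),
]

# Names of the plant-health indicators are configurable placeholders: the
# theme is structurally complete but inert until assessment data arrive.
_PLANT_HEALTH = [
    (f"plant_health_{i:02d}", f"Plant health indicator {i:02d}", "index units", "positive-good", (0.0, 100.0))
    for i in range(1, 11)
]

_THEMES = [
    ("crop_production", "crop production", _CROP_PRODUCTION),
    ("soil_chemistry", "soil chemistry", _SOIL_CHEMISTRY),
    ("soil_physics", "soil physics", _SOIL_PHYSICS),
    ("soil_biology", "soil biology", _SOIL_BIOLOGY),
    ("plant_health", "plant health", _PLANT_HEALTH),
]


def _impact_table(direction: str) -> list[CorrespondencePoint]:
    # percent-change knots; +/-50 % bounds the utility response, anchor at 0 %
    if direction == "positive-good":
        pts = [(-50.0, 0.3), (0.0, BASELINE), (50.0, 1.0)]
    else:
        pts = [(-50.0, 1.0), (0.0, BASELINE), (50.0, 0.3)]
    return [CorrespondencePoint(calculated_index=x, utility=u) for x, u in pts]


def _performance_table(direction: str, lo: float, hi: float) -> tuple[list[CorrespondencePoint], float]:
    # technical suitability placed at 60 % of the range for positive-good
    # indicators (benchmarks usually sit in the upper half) and 40 % for
    # negative-good ones (damage thresholds sit in the lower half)
    if direction == "positive-good":
        anchor = lo + 0.6 * (hi - lo)
        pts = [(lo, 0.1), (anchor, BASELINE), (hi, 1.0)]
    else:
        anchor = lo + 0.4 * (hi - lo)
        pts = [(lo, 1.0), (anchor, BASELINE), (hi, 0.1)]
    return [CorrespondencePoint(calculated_index=x, utility=u) for x, u in pts], anchor


def build() -> SystemConfig:
    themes: list[ThemeDefinition] = []
    indicators: list[IndicatorDefinition] = []
    for theme_id, theme_name, rows in _THEMES:
        themes.append(
            ThemeDefinition(
                theme_id=theme_id,
                name=theme_name,
                indicator_ids=[r[0] for r in rows],
            )
        )
        for iid, name, units, direction, (lo, hi) in rows:
            perf_table, anchor = _performance_table(direction, lo, hi)
            indicators.append(
                IndicatorDefinition(
                    indicator_id=iid,
                    name=name,
                    theme_id=theme_id,
                    units=units,
                    direction=direction,
                    explanatory_range=(lo, hi),
                    impact_table=_impact_table(direction),
                    performance_table=perf_table,
                    baseline_utility=BASELINE,
                    performance_baseline_level=anchor,
                )
            )
    return SystemConfig(
        metadata={
            "system": "APOIA-Biostimulant",
            "description": "multi-attribute biostimulant field-trial assessment",
        },
        themes=themes,
        indicators=indicators,
    )
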