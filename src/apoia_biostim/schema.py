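"""Indicator-system schema: themes, indicators, correspondence tables.

The system expresses heterogeneous field variables on a common 0-1 utility
scale.  Each indicator carries two correspondence tables:

* an *impact* table over percent change (control -> treatment), and
* a *performance* table over the measured level in the treatment arm,
  judged against agronomic benchmarks.

Both tables are anchored at a baseline utility (0.7 by convention), which
represents stability (zero change) for impact and technical suitability for
performance.  Configurations are plain YAML/JSON documents so they can be
diffed and versioned; :func:`default_config` ships the built-in
five-theme, 39-indicator biostimulant assessment system.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Literal, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

SCHEMA_VERSION = 1

Direction = Literal["positive-good", "negative-good"]

__all__ = [
    "CalibrationFinding",
    "CorrespondencePoint",
    "IndicatorDefinition",
    "SystemConfig",
    "ThemeDefinition",
    "ConfigError",
    "default_config",
    "dump_config",
    "load_config",
    "validate_calibration",
]


class ConfigError(ValueError):
    """Raised when an indicator-system document violates the schema."""


class CorrespondencePoint(BaseModel):
    """One knot of a correspondence table: (calculated index, utility)."""

    calculated_index: float
    utility: float = Field(ge=0.0, le=1.0)

    model_config = {"frozen": True}


class ThemeDefinition(BaseModel):
    theme_id: str
    name: str
    indicator_ids: list[str] = Field(min_length=1)

    model_config = {"frozen": True}


class IndicatorDefinition(BaseModel):
    """One measurable variable of the assessment system.

    ``direction`` states whether larger raw values are agronomically
    favorable (``positive-good``, e.g. enzyme activity) or unfavorable
    (``negative-good``, e.g. soil compaction).  ``explanatory_range``
    bounds the performance explanatory variable in indicator units; the
    performance correspondence table must live inside it.
    """

    indicator_id: str
    name: str
    theme_id: str
    units: str
    direction: Direction = "positive-good"
    explanatory_range: tuple[float, float]
    impact_table: list[CorrespondencePoint] = Field(min_length=2)
    performance_table: list[CorrespondencePoint] = Field(min_length=2)
    baseline_utility: float = Field(default=0.7, gt=0.0, lt=1.0)
    performance_baseline_level: float | None = None

    model_config = {"frozen": True}

    @field_validator("explanatory_range")
    @classmethod
    def _range_ordered(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not lo < hi:
            raise ValueError(f"explanatory_range lower must be < upper, got {v}")
        return v

    @model_validator(mode="after")
    def _tables_strictly_increasing(self) -> "IndicatorDefinition":
        for label, table in (("impact", self.impact_table), ("performance", self.performance_table)):
            xs = [p.calculated_index for p in table]
            if any(b <= a for a, b in zip(xs, xs[1:])):
                raise ValueError(
                    f"{self.indicator_id}: {label}_table calculated_index values "
                    f"must be strictly increasing, got {xs}"
                )
        return self


class SystemConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    metadata: dict[str, str] = Field(default_factory=dict)
    themes: list[ThemeDefinition]
    indicators: list[IndicatorDefinition]

    @model_validator(mode="after")
    def _cross_references(self) -> "SystemConfig":
        by_id: dict[str, IndicatorDefinition] = {}
        for ind in self.indicators:
            if ind.indicator_id in by_id:
                raise ValueError(f"duplicate indicator_id: {ind.indicator_id!r}")
            by_id[ind.indicator_id] = ind
        seen_in_theme: dict[str, str] = {}
        for theme in self.themes:
            for iid in theme.indicator_ids:
                if iid not in by_id:
                    raise ValueError(
                        f"theme {theme.theme_id!r} references unknown indicator {iid!r}"
                    )
                if iid in seen_in_theme:
                    raise ValueError(
                        f"indicator {iid!r} assigned to both themes "
                        f"{seen_in_theme[iid]!r} and {theme.theme_id!r}"
                    )
                seen_in_theme[iid] = theme.theme_id
        return self

    # -- convenience lookups -------------------------------------------------

    def indicator(self, indicator_id: str) -> IndicatorDefinition:
        for ind in self.indicators:
            if ind.indicator_id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def theme_of(self, indicator_id: str) -> ThemeDefinition:
        for theme in self.themes:
            if indicator_id in theme.indicator_ids:
                return theme
        raise KeyError(indicator_id)


# ---------------------------------------------------------------------------
# Loading / dumping


def load_config(source: Union[str, Path, IO[str], dict]) -> SystemConfig:
    """Parse and validate an indicator-system document (YAML or JSON).

    ``source`` may be a path, an open text stream, a raw document string,
    or an already-parsed mapping.  Raises :class:`ConfigError` naming the
    offending indicator or field on any schema violation.
    """
    if isinstance(source, dict):
        doc = source
    else:
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            text = Path(source).read_text(encoding="utf-8")
        elif isinstance(source, str):
            text = source
        else:
            text = source.read()
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    try:
        return SystemConfig.model_validate(doc)
    except Exception as exc:  # pydantic.ValidationError carries field paths
        raise ConfigError(str(exc)) from exc


def dump_config(config: SystemConfig, fmt: Literal["yaml", "json"] = "yaml") -> str:
    """Serialize a config to a round-trippable text document."""
    doc = config.model_dump(mode="json")
    if fmt == "json":
        return json.dumps(doc, indent=2, ensure_ascii=False)
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Calibration checks


class CalibrationFinding(BaseModel):
    indicator_id: str
    check: Literal["probability", "sensitivity"]
    message: str

    model_config = {"frozen": True}

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.check}] {self.indicator_id}: {self.message}"


def _monotone_direction(utilities: list[float]) -> str:
    """'increasing', 'decreasing', 'flat' or 'none' over successive knots."""
    diffs = [b - a for a, b in zip(utilities, utilities[1:])]
    if all(d == 0 for d in diffs):
        return "flat"
    if all(d >= 0 for d in diffs):
        return "increasing"
    if all(d <= 0 for d in diffs):
        return "decreasing"
    return "none"


def validate_calibration(ind: IndicatorDefinition) -> list[CalibrationFinding]:
    """Run the probability and sensitivity calibration checks on one indicator.

    The *probability* check verifies the explanatory-variable thresholds
    bracket the performance table's domain and that utility monotonicity
    agrees with the declared direction.  The *sensitivity* check verifies
    the impact table carries (or can be anchored at) the baseline point at
    zero change, and that the utility response has nonzero amplitude.
    An empty list means the indicator is calibrated.
    """
    findings: list[CalibrationFinding] = []

    def add(check: str, message: str) -> None:
        findings.append(
            CalibrationFinding(indicator_id=ind.indicator_id, check=check, message=message)
        )

    lo, hi = ind.explanatory_range
    xs = [p.calculated_index for p in ind.performance_table]
    if xs[0] < lo or xs[-1] > hi:
        add(
            "probability",
            f"performance table domain [{xs[0]}, {xs[-1]}] exceeds explanatory "
            f"thresholds [{lo}, {hi}]",
        )

    expected = "increasing" if ind.direction == "positive-good" else "decreasing"
    for label, table in (("impact", ind.impact_table), ("performance", ind.performance_table)):
        trend = _monotone_direction([p.utility for p in table])
        if trend == "none" or (trend != "flat" and trend != expected):
            add(
                "probability",
                f"direction/monotonicity conflict: {label} utilities are {trend} "
                f"but direction is {ind.direction}",
            )

    # sensitivity: baseline anchor on the impact table (at 0 % change)
    impact_xs = [p.calculated_index for p in ind.impact_table]
    if not (impact_xs[0] <= 0.0 <= impact_xs[-1]):
        add("sensitivity", "missing baseline anchor: impact table does not span 0 % change")
    else:
        # knots on either side of zero change must sit on the correct side
        # of the baseline so the injected anchor preserves monotonicity
        sign = 1.0 if ind.direction == "positive-good" else -1.0
        for p in ind.impact_table:
            if p.calculated_index == 0.0 and abs(p.utility - ind.baseline_utility) > 1e-9:
                add(
                    "sensitivity",
                    f"impact table knot at 0 % has utility {p.utility}, conflicting "
                    f"with baseline_utility {ind.baseline_utility}",
                )
            elif sign * p.calculated_index > 0 and p.utility < ind.baseline_utility - 1e-9:
                add(
                    "sensitivity",
                    f"baseline anchor conflict: knot at {p.calculated_index} % has "
                    f"utility {p.utility} below the baseline {ind.baseline_utility}",
                )
            elif sign * p.calculated_index < 0 and p.utility > ind.baseline_utility + 1e-9:
                add(
                    "sensitivity",
                    f"baseline anchor conflict: knot at {p.calculated_index} % has "
                    f"utility {p.utility} above the baseline {ind.baseline_utility}",
                )

    for label, table in (("impact", ind.impact_table), ("performance", ind.performance_table)):
        us = [p.utility for p in table]
        if max(us) - min(us) == 0.0:
            add("sensitivity", f"zero-amplitude {label} table: utility response is flat")

    return findings


# ---------------------------------------------------------------------------
# Default built-in system

from . import _default_system  # noqa: E402  (circular-safe: module only builds data)


def default_config() -> SystemConfig:
    """The built-in five-theme, 39-indicator biostimulant assessment system.

    Themes and indicator counts: crop production (9), soil chemistry (9),
    soil physics (5), soil biology (6), plant health (10 configurable
    placeholders).  Correspondence tables other than the documented enzyme
    thresholds are shipped as defensible agronomic defaults, all anchored
    at utility 0.7, and are meant to be overridden by user calibration.
    """
    return _default_system.build()
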