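"""Scoring of paired control/treatment field measurements.

Each indicator yields two calculated indices:

* **index 1 (impact)** -- percent change of the summarized level from the
  control arm to the treatment arm, ``100 * (treatment - control) / control``;
* **index 2 (technical performance)** -- the summarized treatment-arm level
  itself, in indicator units.

Both are mapped through the indicator's utility curves to the 0-1 scale.
Replicates are summarized by the arithmetic mean per arm by default; the
median is available for outlier-prone profiles (e.g. penetrometer
transects).  A zero control level makes percent change undefined: the
impact index is refused and flagged rather than computed against a
fabricated denominator.

:class:`ApoiaScorer` packages the whole step as a scikit-learn style
transformer over long-format measurement tables, so scoring composes with
sklearn pipelines; :func:`score_indicator` / :func:`score_trial` are the
equivalent functional surface.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from sklearn.base import BaseEstimator, TransformerMixin

from .curves import UtilityCurve, build_curve
from .schema import IndicatorDefinition, SystemConfig, default_config

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["farm_id", "indicator_id", "arm", "replicate", "value", "unit"]

__all__ = [
    "ApoiaScorer",
    "FieldMeasurement",
    "IndicatorResult",
    "MEASUREMENT_COLUMNS",
    "TrialDataset",
    "ZeroControlError",
    "measurements_to_frame",
    "percent_change",
    "read_measurements_csv",
    "score_indicator",
    "score_trial",
    "write_measurements_csv",
]


class ZeroControlError(ZeroDivisionError):
    """Percent change is undefined for a zero control level."""


class FieldMeasurement(BaseModel):
    farm_id: str
    indicator_id: str
    arm: Literal["control", "biostimulant"]
    replicate_values: list[float] = Field(min_length=1)
    unit: str | None = None

    model_config = {"frozen": True}

    @field_validator("replicate_values")
    @classmethod
    def _finite(cls, v: list[float]) -> list[float]:
        if not all(math.isfinite(x) for x in v):
            raise ValueError("replicate values must be finite")
        return v


class TrialDataset(BaseModel):
    """All measurements for one farm, both arms, across indicators."""

    farm_id: str
    metadata: dict[str, str] = Field(default_factory=dict)
    measurements: list[FieldMeasurement] = Field(default_factory=list)

    def by_indicator(self) -> dict[str, dict[str, FieldMeasurement]]:
        out: dict[str, dict[str, FieldMeasurement]] = {}
        for m in self.measurements:
            out.setdefault(m.indicator_id, {})[m.arm] = m
        return out


class IndicatorResult(BaseModel):
    farm_id: str
    indicator_id: str
    theme_id: str
    index1_percent_change: float | None = None
    index2_level: float | None = None
    utility_impact: float | None = None
    utility_performance: float | None = None
    flags: list[str] = Field(default_factory=list)


def percent_change(control: float, treatment: float) -> float:
    """Percent change from the control to the treatment summarized level."""
    if control == 0:
        raise ZeroControlError("control level is zero; percent change undefined")
    return 100.0 * (treatment - control) / control


_SUMMARIZERS: dict[str, Callable[[list[float]], float]] = {
    "mean": lambda v: float(np.mean(v)),
    "median": lambda v: float(np.median(v)),
}


def score_indicator(
    ind: IndicatorDefinition,
    m_control: FieldMeasurement | None,
    m_treatment: FieldMeasurement,
    summarizer: str = "mean",
    curves: tuple[UtilityCurve, UtilityCurve] | None = None,
) -> IndicatorResult:
    """Score one indicator from its paired arm measurements.

    A missing control arm skips the impact index (flagged) while the
    performance index is still computed from the treatment arm.  A declared
    unit mismatch between data and indicator definition is an error.
    """
    summ = _SUMMARIZERS[summarizer]
    for m in (m_control, m_treatment):
        if m is None:
            continue
        if m.indicator_id != ind.indicator_id:
            raise ValueError(
                f"measurement for {m.indicator_id!r} scored against {ind.indicator_id!r}"
            )
        if m.unit is not None and m.unit != ind.units:
            raise ValueError(
                f"{ind.indicator_id}: unit mismatch {m.unit!r} vs declared {ind.units!r}"
            )

    impact_curve, perf_curve = curves if curves is not None else (
        build_curve(ind, "impact"),
        build_curve(ind, "performance"),
    )

    result = IndicatorResult(
        farm_id=m_treatment.farm_id, indicator_id=ind.indicator_id, theme_id=ind.theme_id
    )
    level_t = summ(m_treatment.replicate_values)
    result.index2_level = level_t
    result.utility_performance = perf_curve.evaluate(level_t)

    if m_control is None:
        result.flags.append("missing control arm: impact index skipped")
        return result

    level_c = summ(m_control.replicate_values)
    try:
        pc = percent_change(level_c, level_t)
    except ZeroControlError:
        result.flags.append("zero control level: impact index undefined")
        return result
    result.index1_percent_change = pc
    result.utility_impact = impact_curve.evaluate(pc)
    return result


def score_trial(
    config: SystemConfig, data: TrialDataset, summarizer: str = "mean"
) -> list[IndicatorResult]:
    """Score every indicator with data in one trial.

    Indicators in the config without any measurement are omitted, with one
    logged flag each; unknown indicator ids in the data raise ``ValueError``
    listing the offenders.
    """
    known = {ind.indicator_id for ind in config.indicators}
    offenders = sorted({m.indicator_id for m in data.measurements} - known)
    if offenders:
        raise ValueError(f"unknown indicator ids in trial data: {offenders}")

    grouped = data.by_indicator()
    if not grouped:
        logger.warning("trial %s contains no measurements", data.farm_id)

    results: list[IndicatorResult] = []
    for ind in config.indicators:
        arms = grouped.get(ind.indicator_id)
        if arms is None or "biostimulant" not in arms:
            logger.info("no data for indicator %s on farm %s", ind.indicator_id, data.farm_id)
            continue
        results.append(
            score_indicator(
                ind, arms.get("control"), arms["biostimulant"], summarizer=summarizer
            )
        )
    return results


class ApoiaScorer(BaseEstimator, TransformerMixin):
    """Transform long-format paired measurements into indicator utilities.

    Parameters
    ----------
    config : SystemConfig or None
        Indicator system to score against; the built-in default when None.
    summarizer : {"mean", "median"}
        Per-arm replicate summary statistic.

    After :meth:`fit`, ``impact_curves_`` and ``performance_curves_`` hold
    the built utility curves keyed by indicator id.  :meth:`transform`
    accepts a DataFrame with columns ``farm_id, indicator_id, arm,
    replicate, value`` (``unit`` optional) and returns one row per scored
    (farm, indicator) pair.
    """

    def __init__(self, config: SystemConfig | None = None, summarizer: str = "mean"):
        self.config = config
        self.summarizer = summarizer

    def fit(self, X=None, y=None) -> "ApoiaScorer":
        if self.summarizer not in _SUMMARIZERS:
            raise ValueError(f"summarizer must be one of {sorted(_SUMMARIZERS)}")
        self.config_ = self.config if self.config is not None else default_config()
        self.impact_curves_ = {
            ind.indicator_id: build_curve(ind, "impact") for ind in self.config_.indicators
        }
        self.performance_curves_ = {
            ind.indicator_id: build_curve(ind, "performance")
            for ind in self.config_.indicators
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            raise RuntimeError("ApoiaScorer must be fitted before transform")
        required = {"farm_id", "indicator_id", "arm", "value"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"measurement table missing columns: {sorted(missing)}")
        rows = []
        for dataset in frame_to_trials(X):
            for r in self.score_trial(dataset):
                rows.append(r.model_dump())
        out = pd.DataFrame(
            rows,
            columns=[
                "farm_id",
                "indicator_id",
                "theme_id",
                "index1_percent_change",
                "index2_level",
                "utility_impact",
                "utility_performance",
                "flags",
            ],
        )
        return out

    def score_trial(self, data: TrialDataset) -> list[IndicatorResult]:
        known = {ind.indicator_id for ind in self.config_.indicators}
        offenders = sorted({m.indicator_id for m in data.measurements} - known)
        if offenders:
            raise ValueError(f"unknown indicator ids in trial data: {offenders}")
        grouped = data.by_indicator()
        results = []
        for ind in self.config_.indicators:
            arms = grouped.get(ind.indicator_id)
            if arms is None or "biostimulant" not in arms:
                continue
            results.append(
                score_indicator(
                    ind,
                    arms.get("control"),
                    arms["biostimulant"],
                    summarizer=self.summarizer,
                    curves=(
                        self.impact_curves_[ind.indicator_id],
                        self.performance_curves_[ind.indicator_id],
                    ),
                )
            )
        return results


# ---------------------------------------------------------------------------
# Long-format CSV dialect: one row per replicate


def frame_to_trials(df: pd.DataFrame) -> list[TrialDataset]:
    """Group a long-format measurement table into per-farm trial datasets."""
    trials: list[TrialDataset] = []
    for farm_id, farm_df in df.groupby("farm_id", sort=True):
        measurements = []
        for (iid, arm), g in farm_df.groupby(["indicator_id", "arm"], sort=True):
            g = g.sort_values("replicate") if "replicate" in g.columns else g
            unit = None
            if "unit" in g.columns and g["unit"].notna().any():
                units = g["unit"].dropna().unique()
                if len(units) > 1:
                    raise ValueError(f"{farm_id}/{iid}/{arm}: conflicting units {list(units)}")
                unit = str(units[0])
            measurements.append(
                FieldMeasurement(
                    farm_id=str(farm_id),
                    indicator_id=str(iid),
                    arm=str(arm),
                    replicate_values=[float(v) for v in g["value"]],
                    unit=unit,
                )
            )
        trials.append(TrialDataset(farm_id=str(farm_id), measurements=measurements))
    return trials


def measurements_to_frame(trials: list[TrialDataset]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for m in t.measurements:
            for i, v in enumerate(m.replicate_values, start=1):
                rows.append(
                    {
                        "farm_id": t.farm_id,
                        "indicator_id": m.indicator_id,
                        "arm": m.arm,
                        "replicate": i,
                        "value": v,
                        "unit": m.unit,
                    }
                )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def read_measurements_csv(path) -> list[TrialDataset]:
    """Read the strict-header, UTF-8, one-row-per-replicate CSV dialect."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return frame_to_trials(df)


def write_measurements_csv(trials: list[TrialDataset], path) -> None:
    measurements_to_frame(trials).to_csv(path, index=False, encoding="utf-8")
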