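"""Aggregation of indicator utilities into theme and overall indices, plus reporting.

Theme indices are unweighted arithmetic means of the member indicators'
utilities, computed only over indicators with data.  The overall indices
are pooled means over the whole scored indicator set -- not means of theme
means, which differ when themes contribute unequal numbers of indicators;
both are exposed, the pooled value being authoritative.

``render_report`` emits the summary expression: a per-theme bar chart of
impact and technical-performance indices with the 0.7 baseline drawn as a
horizontal line and overall bars alongside, per-theme indicator charts,
and machine-readable CSV/JSON results.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .scoring import IndicatorResult
from .schema import SystemConfig

__all__ = ["AssessmentResult", "ThemeResult", "aggregate", "render_report"]


class ThemeResult(BaseModel):
    theme_id: str
    name: str
    impact_index: float | None = None
    performance_index: float | None = None
    n_indicators_scored: int = 0


class AssessmentResult(BaseModel):
    farm_id: str
    baseline: float = 0.7
    indicator_results: list[IndicatorResult]
    theme_results: list[ThemeResult]
    overall_impact: float | None = None
    overall_performance: float | None = None
    # mean of theme means, logged alongside the authoritative pooled value
    overall_impact_theme_mean: float | None = None
    overall_performance_theme_mean: float | None = None

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AssessmentResult":
        return cls.model_validate_json(text)


def _mean_or_none(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def aggregate(results: list[IndicatorResult], config: SystemConfig) -> AssessmentResult:
    """Aggregate per-indicator utilities into theme and overall indices.

    Themes with no scored indicators are reported with ``None`` indices and
    excluded from the overall means.  Overall indices are pooled over all
    scored indicators (equal indicator weighting).
    """
    farm_ids = {r.farm_id for r in results}
    if len(farm_ids) > 1:
        raise ValueError(f"aggregate() expects a single farm, got {sorted(farm_ids)}")
    farm_id = farm_ids.pop() if farm_ids else ""

    by_theme: dict[str, list[IndicatorResult]] = {}
    for r in results:
        by_theme.setdefault(r.theme_id, []).append(r)

    theme_results: list[ThemeResult] = []
    for theme in config.themes:
        members = by_theme.get(theme.theme_id, [])
        impacts = [r.utility_impact for r in members if r.utility_impact is not None]
        perfs = [r.utility_performance for r in members if r.utility_performance is not None]
        theme_results.append(
            ThemeResult(
                theme_id=theme.theme_id,
                name=theme.name,
                impact_index=_mean_or_none(impacts),
                performance_index=_mean_or_none(perfs),
                n_indicators_scored=len(members),
            )
        )

    pooled_impact = [r.utility_impact for r in results if r.utility_impact is not None]
    pooled_perf = [r.utility_performance for r in results if r.utility_performance is not None]
    theme_impacts = [t.impact_index for t in theme_results if t.impact_index is not None]
    theme_perfs = [t.performance_index for t in theme_results if t.performance_index is not None]

    baseline = config.indicators[0].baseline_utility if config.indicators else 0.7
    return AssessmentResult(
        farm_id=farm_id,
        baseline=baseline,
        indicator_results=list(results),
        theme_results=theme_results,
        overall_impact=_mean_or_none(pooled_impact),
        overall_performance=_mean_or_none(pooled_perf),
        overall_impact_theme_mean=_mean_or_none(theme_impacts),
        overall_performance_theme_mean=_mean_or_none(theme_perfs),
    )


def results_table(a: AssessmentResult) -> pd.DataFrame:
    """One row per scored indicator: indices, utilities and flags."""
    return pd.DataFrame(
        [
            {
                "farm_id": r.farm_id,
                "theme_id": r.theme_id,
                "indicator_id": r.indicator_id,
                "index1_percent_change": r.index1_percent_change,
                "index2_level": r.index2_level,
                "utility_impact": r.utility_impact,
                "utility_performance": r.utility_performance,
                "flags": "; ".join(r.flags),
            }
            for r in a.indicator_results
        ]
    )


def render_report(a: AssessmentResult, out_dir: str | Path) -> dict[str, Path]:
    """Render the report bundle into ``out_dir``; returns the emitted paths.

    Bundle contents: ``summary.png`` (theme + overall bars with baseline
    line), one ``theme_<id>.png`` per scored theme, ``results.csv`` and
    ``assessment.json``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    scored = [t for t in a.theme_results if t.n_indicators_scored > 0]
    labels = [t.name for t in scored] + ["overall"]
    impacts = [t.impact_index for t in scored] + [a.overall_impact]
    perfs = [t.performance_index for t in scored] + [a.overall_performance]

    fig, ax = plt.subplots(figsize=(1.8 * max(len(labels), 3) + 2, 4.5))
    x = np.arange(len(labels))
    w = 0.38
    ax.bar(x - w / 2, [v if v is not None else 0 for v in impacts], w,
           color="tab:blue", label="impact index")
    ax.bar(x + w / 2, [v if v is not None else 0 for v in perfs], w,
           color="m", label="technical performance index")
    ax.axhline(a.baseline, color="red", lw=1.5, label=f"baseline ({a.baseline:g})")
    ax.set_xticks(x, labels, rotation=20, ha="right")
    ax.set_ylim(0, 1)
    ax.set_ylabel("utility index (0–1)")
    ax.set_title(f"Assessment summary — {a.farm_id}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    summary_path = out_dir / "summary.png"
    fig.savefig(summary_path, dpi=120)
    plt.close(fig)
    paths["summary"] = summary_path

    by_theme: dict[str, list[IndicatorResult]] = {}
    for r in a.indicator_results:
        by_theme.setdefault(r.theme_id, []).append(r)
    for theme in scored:
        members = by_theme.get(theme.theme_id, [])
        fig, ax = plt.subplots(figsize=(1.2 * max(len(members), 3) + 2, 4))
        x = np.arange(len(members))
        ax.bar(x - w / 2, [r.utility_impact or 0 for r in members], w, color="tab:blue")
        ax.bar(x + w / 2, [r.utility_performance or 0 for r in members], w, color="m")
        ax.axhline(a.baseline, color="red", lw=1.5)
        ax.set_xticks(x, [r.indicator_id for r in members], rotation=30, ha="right")
        ax.set_ylim(0, 1)
        ax.set_ylabel("utility index (0–1)")
        ax.set_title(f"{theme.name} — {a.farm_id}")
        fig.tight_layout()
        p = out_dir / f"theme_{theme.theme_id}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"theme_{theme.theme_id}"] = p

    csv_path = out_dir / "results.csv"
    results_table(a).to_csv(csv_path, index=False, encoding="utf-8")
    paths["results_csv"] = csv_path

    json_path = out_dir / "assessment.json"
    json_path.write_text(a.to_json(), encoding="utf-8")
    paths["assessment_json"] = json_path
    return paths
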