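# apoia-biostim

Multi-attribute utility scoring of biostimulant field trials.

Agronomists evaluating a biostimulant in commercial fields face a pile of
heterogeneous measurements — enzyme activities, penetrometer readings,
exchangeable cations, yields, revenue — from paired control vs treated
fields. This package implements the APOIA-style multi-attribute indicator
approach to that problem: every variable is mapped onto a common 0–1
**utility scale** through calibrated correspondence curves, so indicators
can be averaged into theme-level and overall indices and compared across
farms and crops.

## The model

The built-in system has **5 analytical themes and 39 indicators**: crop
production (9), soil chemistry (9), soil physics (5), soil biology (6) and
plant health (10, shipped as configurable placeholders). Each indicator
*i* yields two calculated indices from a paired trial:

- **impact (index 1)** — the percent change from the control arm to the
  treated arm, `I1 = 100 · (x_T − x_C) / x_C`, where `x_C`, `x_T` are the
  per-arm replicate means;
- **technical performance (index 2)** — the treated-arm level `x_T`
  itself, judged against agronomic benchmarks.

Both indices pass through monotone utility curves `u(·) ∈ [0, 1]` built
from the indicator's correspondence table (piecewise-linear by default, a
baseline-constrained least-squares polynomial optionally). The curves are
anchored at the **baseline utility 0.7**: `u(I1 = 0) = 0.7` for impact
(zero change = stability), and `u(benchmark level) = 0.7` for performance
(technical suitability). Curves clamp to their endpoint utilities outside
the explanatory thresholds, and indicators are direction-aware: for a
negative-good variable such as soil compaction, a *decrease* raises
utility.

Theme indices are unweighted means of member utilities; the overall
indices are pooled means over all scored indicators. Cross-case analytics
operate on the farms × indicators utility matrix: pairwise-complete
Pearson correlations with two-sided significance at α = 0.05, and PCA on
the correlation matrix with Kaiser-criterion retention (eigenvalue > 1,
variance fraction = λ/k).

A synthetic-trial generator plants known multiplicative treatment effects
with lognormal replicate noise so every stage is testable without field
data.

## Worked example

```python
import apoia_biostim as ab

config = ab.default_config()                    # 5 themes, 39 indicators
spec = ab.paper_like_spec(config, seed=7)       # 8 farms, plant health unassessed
trials = ab.generate(spec, config)

assessment = ab.aggregate(ab.score_trial(config, trials[0]), config)
for t in assessment.theme_results:
    if t.n_indicators_scored:
        print(f"{t.name:18s} impact={t.impact_index:.2f} "
              f"performance={t.performance_index:.2f} (n={t.n_indicators_scored})")
print(f"{'overall':18s} impact={assessment.overall_impact:.2f} "
      f"performance={assessment.overall_performance:.2f}")
```

prints

```
crop production    impact=0.81 performance=0.77 (n=9)
soil chemistry     impact=0.75 performance=0.75 (n=9)
soil physics       impact=0.82 performance=0.79 (n=5)
soil biology       impact=0.83 performance=0.79 (n=6)
overall            impact=0.80 performance=0.77
```

Impact indices above the 0.7 baseline mean the treated fields outperformed
their paired controls on that theme; here the preset plants favorable
effects, so all four assessed themes sit in the 0.75–0.83 band.
`ab.render_report(assessment, "out/")` writes the summary chart (theme and
overall bars with the 0.7 baseline line), per-theme charts, and CSV/JSON
results. For cross-farm analytics, score all farms with
`ab.ApoiaScorer(config=config).fit().transform(frame)`, pivot with
`ab.index_matrix`, then `ab.pearson_matrix(m)` and `ab.pca_kaiser(m)`.

`ApoiaScorer` and `KaiserPCA` follow the scikit-learn estimator API
(`fit`/`transform`, `get_params`), so they compose with sklearn pipelines.

## Documentation

See `docs/methods.md` for the scoring model, calibration checks, default
correspondence tables, the synthetic-data generator's assumptions, and
known limitations.
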