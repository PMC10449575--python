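# Methods

## Scoring model

The package implements a multi-attribute utility system for paired
control-vs-treatment field trials. Each indicator is a measurable field
variable assigned to one of five analytical themes (crop production, soil
chemistry, soil physics, soil biology, plant health). For an indicator
with per-arm replicate summaries `x_C` (control) and `x_T` (treatment):

- impact index: `I1 = 100 · (x_T − x_C) / x_C` (percent change);
- technical performance index: `I2 = x_T` (treated-arm level, indicator units).

Each index is mapped to a utility in [0, 1] through the indicator's
correspondence curve. The baseline utility 0.7 is an axiom of the system,
not a fitted quantity: it encodes "no impact" on impact curves and
"technical suitability" on performance curves, and is enforced by exact
knot injection when a curve is built. Replicates are summarized by the
arithmetic mean per arm (the median is available for outlier-prone
profiles such as penetrometer transects).

### Utility curves

The default curve is the monotone piecewise-linear interpolant through the
correspondence-table knots. This is deliberate: it is the unique
assumption-free monotone curve through a correspondence table, reproduces
every knot exactly, and keeps calibration auditable — the table *is* the
curve. A least-squares polynomial fit constrained to pass exactly through
the baseline anchor is available (`fit_kind="least-squares"`, default
degree ≤ 3, equality constraint eliminated via a nullspace
reparameterization) for parity experiments with spreadsheet-style fitted
equations; it reproduces the anchor exactly and the other knots only
within residuals, and monotonicity between knots is not guaranteed for it.

Extrapolation clamps to the endpoint utilities: utilities are bounded and
correspondence tables terminate at the explanatory thresholds. All outputs
are additionally clipped to [0, 1]. Monotonicity checks use an absolute
tolerance of 1e-9.

### Calibration checks

`validate_calibration` returns findings rather than raising:

- *probability* check — the explanatory-variable thresholds must bracket
  the performance table's domain, and the utility trend of both tables
  must agree with the declared direction (non-decreasing for
  positive-good, non-increasing for negative-good; flat tables are noted
  by the sensitivity check instead);
- *sensitivity* check — the impact table must span 0 % change so the
  baseline anchor can be injected, knots on either side of zero must sit
  on the correct side of the baseline utility (otherwise the injected
  anchor would break monotonicity), and the utility response must have
  nonzero amplitude.

The shipped default system passes both checks for all 39 indicators.

### Degenerate inputs

A zero control level makes percent change undefined; the impact index is
refused with an explicit flag rather than computed against a substitute
denominator, which would manufacture impact. A missing control arm skips
the impact index (flagged) while performance is still scored. Tables with
fewer than two knots raise; declared unit mismatches between data and
configuration raise (units are compared by string equality — there is no
conversion engine).

## Default configuration

Indicator names follow standard agronomic practice for each theme; the
plant-health theme ships as ten configurable placeholders so it is
structurally complete but inert until assessment data arrive. The
documented enzyme thresholds (e.g. β-glycosidase 0–200
mg p-nitrophenol·kg soil⁻¹·h⁻¹) are used directly. All other
correspondence tables are defensible defaults, not published
calibrations, and are meant to be overridden per campaign via
`load_config`:

- impact tables: knots at (−50 %, 0.3), (0 %, 0.7), (+50 %, 1.0)
  (mirrored for negative-good indicators) — a ±50 % change saturates the
  utility response;
- performance tables: anchored at 0.7 at the technical-suitability level,
  placed at 60 % of the explanatory range for positive-good indicators
  (benchmarks usually sit in the upper half of the agronomic range) and
  40 % for negative-good ones (damage thresholds sit in the lower half).

Configurations are YAML/JSON documents carrying a `schema_version` key;
`dump_config`/`load_config` round-trip exactly.

## Aggregation

Theme indices are unweighted arithmetic means of member utilities over
indicators with data; themes without data are reported absent. The overall
indices are pooled means over the whole scored indicator set. The pooled
mean and the mean of theme means differ whenever themes contribute unequal
indicator counts; both are computed and exposed, the pooled value being
authoritative (equal indicator weighting throughout — the system defines
no weights).

## Analytics

Correlations are pairwise-complete Pearson r with two-sided t-test
p-values (`t = r·√((n−2)/(1−r²))`), a significance flag at α = 0.05 and r²
reported alongside. No multiple-testing correction is applied by default;
this is stated in the result metadata so downstream users can apply one.
Pairs need ≥ 3 complete observations; constant columns leave r undefined
(NaN, flagged).

PCA is an eigendecomposition of the Pearson correlation matrix (columns
standardized with sample variance, ddof = 1), so eigenvalues sum to the
number of columns. The Kaiser criterion retains components with eigenvalue
strictly greater than 1; ties at exactly 1.0 are excluded. Variance
fractions are λ/k. Eigenvalues within 1e-12 of zero are snapped to zero
(eigh can return tiny negatives for rank-deficient input). Missing values
are refused unless per-column mean imputation is requested, in which case
the fitted model is flagged.

## Synthetic trials

The generator emulates paired side-by-side field trials: per indicator, a
control mean, a coefficient of variation, and a multiplicative treatment
effect (`treatment mean = control mean · (1 + effect)`), so the expected
percent change at the mean level equals `100·effect` by construction —
which is what makes planted-effect recovery a meaningful check. Replicates
default to lognormal noise (field measurements are positive-valued;
parameterized so the arm mean is exact: σ² = ln(1+CV²),
μ = ln(mean) − σ²/2), with a resampled truncated normal as the additive
alternative. Defaults: 3 replicates per arm, CV = 0.10. Generation is
bit-reproducible under the spec seed; `recovery_study` re-generates with
seeds `seed + rep`.

The `paper_like_spec` preset emulates a successful eight-farm campaign
with the plant-health theme unassessed: beneficial effects of +23 % (soil
biology), +18 % (crop production and physics) and +9 % (chemistry), sign
flipped for negative-good indicators, CV = 0.08, control levels at each
indicator's suitability benchmark. It is illustrative — theme impact
indices land in the 0.75–0.85 band typical of a favorable campaign — not a
reproduction of any particular field study.

What the generator does **not** emulate: spatial heterogeneity within
fields, correlated errors across indicators (soil chemistry variables are
independent here but strongly coupled in reality), crop-specific indicator
subsets, measurement censoring, or inter-annual variation. Passing
recovery and pipeline tests therefore demonstrates correctness of the
scoring arithmetic and aggregation under the stated noise model, not
validity of any particular field campaign's conclusions.

## Problem sizes

The test suite and the acceptance script run at desk scale: 8 synthetic
farms, 29 scored indicators per farm, 3 replicates per arm; recovery
studies use up to 1000 regenerated single-farm trials. The full pipeline
(generate → score → aggregate → report → analytics) completes in seconds
on one CPU.

## Known limitations

- Correspondence tables beyond the documented enzyme thresholds are
  package defaults; any real campaign must supply its own calibration.
- The least-squares curve mode does not constrain monotonicity between
  knots.
- No unit conversion; units match by string equality.
- Aggregation assumes equal indicator weights; no sensitivity analysis of
  the 0.7 baseline choice is provided.
- Pearson significance is unadjusted for the number of pairs tested.
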