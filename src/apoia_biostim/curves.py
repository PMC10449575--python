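"""Utility curves: monotone mappings from calculated indices to the 0-1 scale.

The default curve is a monotone piecewise-linear interpolant through the
correspondence-table knots with the baseline anchor injected exactly.  A
constrained least-squares polynomial fit is available behind
``fit_kind="least-squares"`` for parity experiments with spreadsheet-style
"best fit" equations; it reproduces the anchor exactly by construction and
the remaining knots within fitted residuals.

Outside the knot domain the curve clamps to the endpoint utilities:
utilities are bounded and correspondence graphs terminate at the
explanatory thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .schema import CorrespondencePoint, IndicatorDefinition, validate_calibration

MONOTONE_TOL = 1e-9

__all__ = ["CalibrationError", "DegenerateTableError", "UtilityCurve", "build_curve"]


class DegenerateTableError(ValueError):
    """Correspondence table has fewer than two usable knots."""


class CalibrationError(ValueError):
    """Correspondence table fails a calibration requirement."""


@dataclass(frozen=True)
class UtilityCurve:
    """A monotone calculated-index -> utility mapping, clamped to [0, 1].

    Attributes
    ----------
    xs, us : knot coordinates after anchor injection, strictly increasing in x.
    fit_kind : "interpolating" (default) or "least-squares".
    coefficients : polynomial coefficients (ascending degree) when fitted.
    domain : evaluation window; outside it the endpoint utility is returned.
    """

    xs: np.ndarray
    us: np.ndarray
    fit_kind: Literal["interpolating", "least-squares"] = "interpolating"
    coefficients: np.ndarray | None = None
    domain: tuple[float, float] = field(default=(0.0, 1.0))

    def __call__(self, x) -> np.ndarray | float:
        return self.evaluate(x)

    def evaluate(self, x) -> np.ndarray | float:
        """Evaluate the curve at scalar or array ``x``; result clamped to [0, 1].

        ``x`` below the domain returns the utility at the lower edge, above it
        the utility at the upper edge.  Non-finite input raises ``ValueError``.
        """
        arr = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("calculated index must be finite")
        clipped = np.clip(arr, self.domain[0], self.domain[1])
        if self.fit_kind == "interpolating":
            out = np.interp(clipped, self.xs, self.us)
        else:
            out = np.polynomial.polynomial.polyval(clipped, self.coefficients)
        out = np.clip(out, 0.0, 1.0)
        if arr.ndim == 0:
            return float(out)
        return out

    def as_table(self) -> list[CorrespondencePoint]:
        """The knot list (anchor included) as correspondence points."""
        return [
            CorrespondencePoint(calculated_index=float(x), utility=float(np.clip(u, 0.0, 1.0)))
            for x, u in zip(self.xs, self.us)
        ]


def _anchor_point(ind: IndicatorDefinition, which: str) -> tuple[float, float]:
    if which == "impact":
        return 0.0, ind.baseline_utility
    if ind.performance_baseline_level is not None:
        return float(ind.performance_baseline_level), ind.baseline_utility
    # fall back to the table knot nearest the baseline utility
    best = min(ind.performance_table, key=lambda p: abs(p.utility - ind.baseline_utility))
    return float(best.calculated_index), ind.baseline_utility


def build_curve(
    ind: IndicatorDefinition,
    which: Literal["impact", "performance"],
    fit_kind: Literal["interpolating", "least-squares"] = "interpolating",
    degree: int | None = None,
) -> UtilityCurve:
    """Build the utility curve for one of an indicator's two tables.

    The baseline anchor -- (0 % change, baseline utility) for impact curves,
    (technical suitability level, baseline utility) for performance curves --
    is injected as an exact knot.  Raises :class:`DegenerateTableError` for
    tables with fewer than two points and :class:`CalibrationError` when the
    table knots are non-monotone in utility for the declared direction.
    """
    table = ind.impact_table if which == "impact" else ind.performance_table
    if len(table) < 2:
        raise DegenerateTableError(
            f"{ind.indicator_id}/{which}: need at least 2 correspondence points"
        )
    conflicts = [
        f
        for f in validate_calibration(ind)
        if f.check == "probability" and "monotonicity" in f.message and which in f.message
    ]
    if conflicts:
        raise CalibrationError(str(conflicts[0]))

    xs = np.array([p.calculated_index for p in table], dtype=float)
    us = np.array([p.utility for p in table], dtype=float)

    ax, au = _anchor_point(ind, which)
    hit = np.isclose(xs, ax, rtol=0.0, atol=1e-12)
    if hit.any():
        us = us.copy()
        us[hit] = au  # anchor exact even if the table knot drifted
    else:
        idx = int(np.searchsorted(xs, ax))
        xs = np.insert(xs, idx, ax)
        us = np.insert(us, idx, au)

    domain = (float(xs[0]), float(xs[-1]))

    if fit_kind == "interpolating":
        return UtilityCurve(xs=xs, us=us, fit_kind="interpolating", domain=domain)

    coeffs = _anchored_polyfit(xs, us, ax, au, degree=degree)
    return UtilityCurve(
        xs=xs, us=us, fit_kind="least-squares", coefficients=coeffs, domain=domain
    )


def _anchored_polyfit(
    xs: np.ndarray, us: np.ndarray, ax: float, au: float, degree: int | None = None
) -> np.ndarray:
    """Least-squares polynomial through the knots, constrained to the anchor.

    Solves min ||V c - u||^2 subject to v(ax) . c = au by eliminating the
    constraint: write c = c0 + N t with c0 a particular solution and N a
    nullspace basis of the single constraint row, then solve the reduced
    unconstrained problem.
    """
    if degree is None:
        degree = min(3, len(xs) - 1)
    V = np.polynomial.polynomial.polyvander(xs, degree)
    a_row = np.polynomial.polynomial.polyvander(np.array([ax]), degree)[0]
    # particular solution of a_row . c = au
    c0 = a_row * (au / (a_row @ a_row))
    # nullspace of the 1 x (d+1) constraint
    _, _, vt = np.linalg.svd(a_row[None, :])
    N = vt[1:].T
    t, *_ = np.linalg.lstsq(V @ N, us - V @ c0, rcond=None)
    return c0 + N @ t
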