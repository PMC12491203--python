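"""Cubic-spline time normalization of joint-angle segments.

Walking speed and cadence differ between subjects, so raw gait cycles have
variable sample counts.  Each segmented cycle is resampled onto a fixed
normalized time base (0–100% of the cycle, 101 points by default) with a
piecewise-cubic interpolating spline

    s(x) = a_i + b_i (x - x_i) + c_i (x - x_i)^2 + d_i (x - x_i)^3

on each knot interval [x_i, x_{i+1}], with function values and first and
second derivatives continuous at interior knots.  Not-a-knot end
conditions are used: they reproduce cubic polynomials exactly and avoid
the artificial end flattening of natural splines.  Evaluation is strictly
interpolation — querying outside the knot span raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class CubicSplineModel:
    """Fitted piecewise-cubic interpolant with exposed knot coefficients."""

    knots: np.ndarray        # x_i, strictly increasing
    coefficients: np.ndarray  # shape (n_knots - 1, 4): rows (a_i, b_i, c_i, d_i)
    _spline: CubicSpline

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        # tiny tolerance for round-off at the span edges
        eps = 1e-12 * max(1.0, abs(hi - lo))
        if np.any(x < lo - eps) or np.any(x > hi + eps):
            raise ValueError(
                f"query outside knot span [{lo}, {hi}]: interpolation only"
            )
        return self._spline(np.clip(x, lo, hi))


def fit_cubic_spline(xs: np.ndarray, ys: np.ndarray) -> CubicSplineModel:
    """Fit a not-a-knot interpolating cubic spline through ``(xs, ys)``.

    Requires at least 4 points and strictly increasing abscissae.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.ndim != 1 or xs.shape != ys.shape:
        raise ValueError("xs and ys must be one-dimensional and equal length")
    if len(xs) < 4:
        raise ValueError(f"need >= 4 points for a cubic spline, got {len(xs)}")
    if not np.all(np.isfinite(xs)) or not np.all(np.isfinite(ys)):
        raise ValueError("xs and ys must be finite")
    d = np.diff(xs)
    if np.any(d <= 0):
        bad = int(np.argmax(d <= 0))
        raise ValueError(
            f"abscissae must be strictly increasing (violation near index {bad})"
        )
    spline = CubicSpline(xs, ys, bc_type="not-a-knot")
    # scipy stores coefficients highest order first: c[k, i] multiplies
    # (x - x_i)^(3-k); reorder to (a, b, c, d) per segment.
    coef = spline.c[::-1].T.copy()
    return CubicSplineModel(knots=xs, coefficients=coef, _spline=spline)


def resample_to_cycle(
    ys: np.ndarray,
    n_points: int,
    xs: np.ndarray | None = None,
) -> np.ndarray:
    """Resample one gait-cycle segment to ``n_points`` normalized samples.

    ``xs`` defaults to the sample index.  The output endpoints equal the
    segment's endpoint values exactly (the query grid spans the knot span,
    never beyond it).
    """
    ys = np.asarray(ys, dtype=float)
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    if xs is None:
        xs = np.arange(len(ys), dtype=float)
    model = fit_cubic_spline(xs, ys)
    grid = np.linspace(xs[0], xs[-1], n_points)
    out = np.asarray(model(grid), dtype=float)
    # exact endpoint equality (interpolation property, protect from round-off)
    out[0], out[-1] = ys[0], ys[-1]
    return out
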