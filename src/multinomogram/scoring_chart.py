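"""Standardized points system ("scoring chart") for a multinomial model.

Coefficients are rescaled so the single largest covariate effect spans
exactly 100 points:

    r = 100 / max_{j,k} |beta_jk * (x_up_j - x_low_j)|,
    beta*_jk = r * beta_jk,
    Points_jk(x) = beta*_jk * x - min(beta*_jk * x_up_j, beta*_jk * x_low_j),

so every points value lies in [0, 100] with 0 at the covariate's most
favorable end regardless of the coefficient's sign.  Per category,

    bl_k  = r * alpha_k + sum_j min(beta*_jk x_up_j, beta*_jk x_low_j)
    bl*_k = bl_k - min_k bl_k                      (so min_k bl*_k = 0)
    Total_k = bl*_k + sum_j Points_jk(x_j)

and the linear predictor is recovered exactly from the total:
``l_k = (Total_k + min_k bl_k) / r``.  Exponentiating gives the value on
the chart's Exp axis, and the sum of those values over non-reference
categories is the quantity marked on the nomogram's S axis.

All arithmetic is kept at full precision; rounding points to integers is
a display concern (see the renderer), with error bounded by half a point
per covariate plus baseline, i.e. ``|delta l| <= (J+1)*0.5/r``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    CovariateProfile,
    ModelSpec,
    ModelValidationError,
    RangeError,
    category_probabilities,
    linear_predictors,
)

__all__ = [
    "ScoringChart",
    "CaseReading",
    "build_scoring_chart",
    "rescaling_factor",
    "points",
    "baselines",
    "total_points",
    "exp_axis_value",
    "chart_S",
    "total_label_for_l",
    "case_reading",
]


def rescaling_factor(model: ModelSpec) -> float:
    """Points per log-odds unit: ``r = 100 / max_{j,k} |beta_jk (x_up - x_low)|``."""
    spans = np.abs(model.coefficients * (model.highs - model.lows))
    m = float(spans.max()) if spans.size else 0.0
    if m == 0.0:
        raise ModelValidationError(
            "all coefficients are zero over their covariate ranges; "
            "the 0-100 points scale is undefined"
        )
    return 100.0 / m


@dataclass(frozen=True)
class ScoringChart:
    """The complete points system derived from one model.

    ``point_min`` holds ``min(beta*_jk x_up, beta*_jk x_low)`` per (k, j) —
    the subtracted offset that anchors each points scale at zero —
    and ``point_span`` the achieved width ``|beta*_jk (x_up - x_low)|``
    (the largest span is exactly 100).  ``total_range`` per category is the
    achievable [min, max] of Total_k over the covariate box.
    """

    model: ModelSpec
    r: float
    beta_star: np.ndarray          # (K-1, J)
    point_min: np.ndarray          # (K-1, J)
    point_span: np.ndarray         # (K-1, J)
    bl: np.ndarray                 # (K-1,)
    bl_star: np.ndarray            # (K-1,)
    min_bl: float
    total_range: np.ndarray        # (K-1, 2)
    model_fingerprint: str = field(default="", compare=False)


def baselines(model: ModelSpec, r: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-category baseline scores ``(bl, bl*, min_k bl)``.

    A tie in ``min_k bl_k`` needs no breaking: the subtraction is
    well-defined and simply zeroes every tied category's ``bl*``.
    """
    beta_star = r * model.coefficients
    point_min = np.minimum(beta_star * model.highs, beta_star * model.lows)
    bl = r * model.intercepts + point_min.sum(axis=1)
    min_bl = float(bl.min())
    return bl, bl - min_bl, min_bl


def build_scoring_chart(model: ModelSpec) -> ScoringChart:
    """Assemble the full points system (Steps: rescale, points, baselines)."""
    r = rescaling_factor(model)
    beta_star = r * model.coefficients
    point_min = np.minimum(beta_star * model.highs, beta_star * model.lows)
    point_span = np.abs(beta_star * (model.highs - model.lows))
    bl, bl_star, min_bl = baselines(model, r)
    # Points_jk is 0 at one end of the box and point_span at the other, so
    # Total_k ranges over [bl*_k, bl*_k + sum_j span_jk].
    lo = bl_star
    hi = bl_star + point_span.sum(axis=1)
    return ScoringChart(
        model=model, r=r, beta_star=beta_star,
        point_min=point_min, point_span=point_span,
        bl=bl, bl_star=bl_star, min_bl=min_bl,
        total_range=np.column_stack([lo, hi]),
        model_fingerprint=model.fingerprint(),
    )


def points(chart: ScoringChart, j: int, k: int, x: float, *, clamp: bool = False) -> float:
    """Points for covariate ``j`` toward non-reference category ``k`` at
    value ``x``; always in [0, 100] for in-range ``x``."""
    c = chart.model.covariates[j]
    x = float(x)
    if clamp:
        x = min(max(x, c.low), c.high)
    elif not c.low <= x <= c.high:
        raise RangeError(
            f"covariate {c.name!r} value {x} outside range [{c.low}, {c.high}]"
        )
    return float(chart.beta_star[k, j] * x - chart.point_min[k, j])


def total_points(chart: ScoringChart, profile: CovariateProfile, *, clamp: bool = False) -> np.ndarray:
    """Total points per non-reference category:
    ``Total_k = bl*_k + sum_j Points_jk(x_j)``."""
    model = chart.model
    l = linear_predictors(model, profile, clamp=clamp)  # validates alignment/range
    totals = chart.bl_star + np.array(
        [
            sum(points(chart, j, k, profile.x[j], clamp=True) for j in range(model.J))
            for k in range(model.K - 1)
        ]
    )
    # Step 6 identity: the total is an affine relabeling of the linear predictor
    assert np.allclose((totals + chart.min_bl) / chart.r, l, rtol=0, atol=1e-8)
    return totals


def exp_axis_value(chart: ScoringChart, total: float) -> float:
    """Exp-axis value under a total: ``exp((Total + min_bl)/r) = exp(l_k)``."""
    lo = float(chart.total_range[:, 0].min())
    hi = float(chart.total_range[:, 1].max())
    tol = 1e-9 * max(1.0, abs(lo), abs(hi))
    if not lo - tol <= total <= hi + tol:
        raise RangeError(f"total {total} outside achievable range [{lo}, {hi}]")
    return math.exp((total + chart.min_bl) / chart.r)


def chart_S(chart: ScoringChart, totals: np.ndarray) -> float:
    """The S-axis label: the sum of exp-axis values over the non-reference
    categories, ``S = sum_k exp((Total_k + min_bl)/r) = sum_k exp(l_k)``."""
    totals = np.asarray(totals, dtype=float)
    if totals.shape != (chart.model.K - 1,):
        raise ValueError(
            f"need one total per non-reference category "
            f"({chart.model.K - 1}), got shape {totals.shape}"
        )
    return float(sum(exp_axis_value(chart, t) for t in totals))


def total_label_for_l(chart: ScoringChart, l: float) -> float:
    """Relabel a linear-predictor value in Total Points units:
    ``Total = r*l - min_bl`` (inverse of the recovery identity)."""
    return chart.r * float(l) - chart.min_bl


@dataclass(frozen=True)
class CaseReading:
    """One subject worked through the chart: points per covariate and
    category, per-category totals and exp-axis values, the S label, and
    the probabilities the nomogram read-off reproduces."""

    categories: tuple[str, ...]          # non-reference
    covariate_names: tuple[str, ...]
    points: np.ndarray                   # (K-1, J)
    totals: np.ndarray                   # (K-1,)
    exp_values: np.ndarray               # (K-1,)
    S: float
    pi: np.ndarray                       # (K,) in model category order
    all_categories: tuple[str, ...]


def case_reading(chart: ScoringChart, profile: CovariateProfile, *, clamp: bool = False) -> CaseReading:
    """Work one covariate profile through the full chart route."""
    model = chart.model
    state = category_probabilities(model, profile, clamp=clamp)
    x = np.clip(profile.x, model.lows, model.highs) if clamp else profile.x
    pts = np.array(
        [
            [points(chart, j, k, x[j], clamp=True) for j in range(model.J)]
            for k in range(model.K - 1)
        ]
    )
    totals = total_points(chart, profile, clamp=clamp)
    exp_vals = np.array([exp_axis_value(chart, t) for t in totals])
    return CaseReading(
        categories=model.nonreference_categories,
        covariate_names=model.covariate_names,
        points=pts,
        totals=totals,
        exp_values=exp_vals,
        S=chart_S(chart, totals),
        pi=state.pi,
        all_categories=model.categories,
    )
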