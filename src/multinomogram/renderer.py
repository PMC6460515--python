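"""Deterministic SVG rendering of nomograms and scoring charts.

Output is plain SVG 1.1 text built from pure functions of the inputs:
identical (layout, chart, case, config) always yield byte-identical
documents, so renders can be snapshot-tested and diffed.  Fonts are
referenced by generic family only to keep the bytes platform-independent.

The nomogram view draws the three parallel vertical axes — L (labeled in
Total Points, optionally with raw linear-predictor sub-labels), O
(probabilities), S (sum of exponentiated linear predictors) — and, when a
case is supplied, one straight isopleth per non-reference category from
its mark on L through the shared mark on S.

The scoring-chart view draws the 0-100 Points ruler, one row per
(covariate, category) pair mapping covariate values to points, baseline
points per category, and the Total Points and Exp axes at the bottom.
Covariates whose coefficient for some category is zero still get a row
(annotated as carrying 0 points) so every category has a structurally
identical set of rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .nomogram_geometry import (
    NomogramLayout,
    make_ticks,
    position_on_L,
    position_on_S,
    _nice_linear,
    _decade_values,
    _fmt,
)
from .scoring_chart import CaseReading, ScoringChart, total_label_for_l

__all__ = ["RenderConfig", "render_nomogram", "render_scoring_chart", "ConsistencyError"]


class ConsistencyError(ValueError):
    """Layout and chart were built from different models."""


@dataclass(frozen=True)
class RenderConfig:
    """Page geometry and labeling options (dimensions in SVG user units)."""

    width: float = 640.0
    height: float = 480.0
    margin: float = 56.0
    font_size: float = 11.0
    decimals: int = 4
    show_case_overlay: bool = True
    show_raw_l_labels: bool = False
    integer_points: bool = False
    row_order: str = "covariate-major"  # or "category-major"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.margin < 0:
            raise ValueError("page dimensions must be positive")
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")
        if self.row_order not in ("covariate-major", "category-major"):
            raise ValueError(f"unknown row_order {self.row_order!r}")


def coord(v: float) -> str:
    """Canonical coordinate formatting; -0.0 normalized so output is stable."""
    s = f"{v:.4f}"
    return "0.0000" if s == "-0.0000" else s


def text_bbox(x: float, y: float, text: str, font_size: float, anchor: str = "start"):
    """Rough bounding box (x0, y0, x1, y1) for collision checks; width
    estimated at 0.62 em per character."""
    w = 0.62 * font_size * len(text)
    if anchor == "middle":
        x0 = x - w / 2
    elif anchor == "end":
        x0 = x - w
    else:
        x0 = x
    return (x0, y - font_size, x0 + w, y + 0.25 * font_size)


class _SVG:
    def __init__(self, width: float, height: float, font_size: float):
        self.parts: list[str] = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{coord(width)}" height="{coord(height)}" '
            f'viewBox="0 0 {coord(width)} {coord(height)}" '
            f'font-family="sans-serif" font-size="{coord(font_size)}">',
        ]

    def line(self, x1, y1, x2, y2, cls, dashed=False, **attrs):
        extra = ' stroke-dasharray="4 3"' if dashed else ""
        for k, v in attrs.items():
            extra += f' {k.replace("_", "-")}="{v}"'
        self.parts.append(
            f'<line class="{cls}" x1="{coord(x1)}" y1="{coord(y1)}" '
            f'x2="{coord(x2)}" y2="{coord(y2)}" stroke="black"{extra}/>'
        )

    def text(self, x, y, s, cls, anchor="start"):
        self.parts.append(
            f'<text class="{cls}" x="{coord(x)}" y="{coord(y)}" '
            f'text-anchor="{anchor}">{_escape(s)}</text>'
        )

    def circle(self, x, y, r, cls):
        self.parts.append(
            f'<circle class="{cls}" cx="{coord(x)}" cy="{coord(y)}" '
            f'r="{coord(r)}" fill="black"/>'
        )

    def done(self) -> str:
        return "\n".join(self.parts + ["</svg>"]) + "\n"


def _escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _check_same_model(layout: NomogramLayout, chart: ScoringChart) -> None:
    if layout.model_fingerprint and chart.model_fingerprint:
        if layout.model_fingerprint != chart.model_fingerprint:
            raise ConsistencyError(
                "layout and scoring chart come from different models "
                f"({layout.model_fingerprint} vs {chart.model_fingerprint})"
            )


# ---------------------------------------------------------------------------
# nomogram

def render_nomogram(
    layout: NomogramLayout,
    chart: ScoringChart,
    case: CaseReading | None = None,
    config: RenderConfig | None = None,
) -> str:
    """Render the three-axis nomogram as SVG text.

    Axis x-positions follow the layout's geometry (L at 0, O at d_LO, S at
    d, scaled to the page); tick heights are the geometry operations'
    outputs scaled by a single vertical factor, so a parser can recompute
    every coordinate from the layout alone.
    """
    config = config or RenderConfig()
    _check_same_model(layout, chart)

    top = config.margin + 3.4 * config.font_size
    plot_w = config.width - 2 * config.margin
    plot_h = config.height - config.margin - top
    xs = config.margin + plot_w * (0.0 / layout.d)  # L axis
    xo = config.margin + plot_w * (layout.d_LO / layout.d)
    xr = config.margin + plot_w  # S axis
    vs = plot_h / layout.h
    y0 = config.height - config.margin  # shared baseline (axis height 0)

    def Y(pos: float) -> float:
        return y0 - vs * pos

    svg = _SVG(config.width, config.height, config.font_size)
    svg.text(config.width / 2, config.margin, "Multinomial nomogram", "title", "middle")

    for x, name in ((xs, "L"), (xo, "O"), (xr, "S")):
        svg.line(x, Y(0.0), x, Y(layout.h), f"axis axis-{name}")
    svg.text(xs, top - 1.6 * config.font_size, "Total points", "axis-name")
    svg.text(xo, top - 1.6 * config.font_size, "Probability", "axis-name", "middle")
    svg.text(xr, top - 1.6 * config.font_size, "S = Σ exp(lp)", "axis-name", "end")

    # L axis labeled in Total Points units via the affine relabeling
    t_lo = total_label_for_l(chart, layout.l_low)
    t_up = total_label_for_l(chart, layout.l_up)
    for t in _nice_linear(min(t_lo, t_up), max(t_lo, t_up), 11):
        l = (t + chart.min_bl) / chart.r
        pos = position_on_L(layout, l, clamp=True)
        svg.line(xs - 4, Y(pos), xs, Y(pos), "tick tick-L", data_pos=coord(pos))
        svg.text(xs - 6, Y(pos) + 0.35 * config.font_size, _fmt(t), "ticklabel-L", "end")
    if config.show_raw_l_labels:
        for tk in make_ticks("L", layout):
            svg.line(xs, Y(tk.position), xs + 4, Y(tk.position), "tick tick-Lraw",
                     data_pos=coord(tk.position))
            svg.text(xs + 6, Y(tk.position) + 0.35 * config.font_size, tk.label,
                     "ticklabel-Lraw")

    for tk in make_ticks("O", layout):
        svg.line(xo - 4, Y(tk.position), xo, Y(tk.position), "tick tick-O",
                 data_pos=coord(tk.position))
        svg.text(xo + 3, Y(tk.position) + 0.35 * config.font_size, tk.label, "ticklabel-O")

    for tk in make_ticks("S", layout):
        svg.line(xr, Y(tk.position), xr + 4, Y(tk.position), "tick tick-S",
                 data_pos=coord(tk.position))
        svg.text(xr - 6, Y(tk.position) + 0.35 * config.font_size, tk.label,
                 "ticklabel-S", "end")

    if case is not None and config.show_case_overlay:
        r = chart.r
        totals = case.totals
        if config.integer_points:
            totals = totals.round()
        l_vals = (totals + chart.min_bl) / r
        s = -math.log1p(sum(math.exp(v) for v in l_vals))
        ys = Y(position_on_S(layout, s, clamp=True))
        for lab, l in zip(case.categories, l_vals):
            yl = Y(position_on_L(layout, l, clamp=True))
            svg.line(xs, yl, xr, ys, "isopleth", dashed=True)
            svg.circle(xs, yl, 2.0, "case-mark")
        svg.circle(xr, ys, 2.5, "case-mark")
        # stacked legend: isopleths for near-tied categories overlap, so
        # per-line labels would collide
        ly = top + 1.4 * config.font_size
        for lab, t in zip(case.categories, totals):
            svg.text(xs + 0.12 * plot_w, ly, f"{lab}: {t:.1f} pts", "case-legend")
            ly += 1.3 * config.font_size

    return svg.done()


# ---------------------------------------------------------------------------
# scoring chart

def render_scoring_chart(
    chart: ScoringChart,
    case: CaseReading | None = None,
    config: RenderConfig | None = None,
) -> str:
    """Render the scoring chart as SVG text.

    Top: a 0-100 Points ruler.  Middle: one row per (covariate, category)
    with covariate-value ticks at their points positions.  Bottom: the
    per-category baseline points, the Total Points axis, and the Exp axis
    related to it by ``exp((Total + min_bl)/r)``.
    """
    config = config or RenderConfig()
    model = chart.model
    Km1, J = model.K - 1, model.J

    if config.row_order == "covariate-major":
        rows = [(j, k) for j in range(J) for k in range(Km1)]
    else:
        rows = [(j, k) for k in range(Km1) for j in range(J)]

    label_w = 0.40 * config.width
    x0 = label_w
    x1 = config.width - config.margin
    ruler_y = config.margin + 2.0 * config.font_size
    row_h = 2.1 * config.font_size
    rows_y0 = ruler_y + 2.0 * row_h
    bottom_y = rows_y0 + (len(rows) + Km1) * row_h + 2.0 * row_h
    # room below the Exp axis for the stacked per-category case readings
    height = bottom_y + 2.3 * row_h + (5.0 + 1.3 * (Km1 + 2)) * config.font_size

    def x_pts(p: float) -> float:
        return x0 + (x1 - x0) * p / 100.0

    svg = _SVG(config.width, height, config.font_size)
    svg.text(config.width / 2, config.margin, "Scoring chart", "title", "middle")

    # Points ruler: spans exactly [0, 100]
    svg.line(x_pts(0.0), ruler_y, x_pts(100.0), ruler_y, "axis axis-points")
    svg.text(x0 - 8, ruler_y + 0.35 * config.font_size, "Points", "axis-name", "end")
    for p in range(0, 101, 10):
        svg.line(x_pts(p), ruler_y, x_pts(p), ruler_y - 4, "tick tick-points",
                 data_pos=coord(float(p)))
        svg.text(x_pts(p), ruler_y - 6, str(p), "ticklabel-points", "middle")

    fmt_pts = (lambda v: _fmt(round(v))) if config.integer_points else _fmt

    y = rows_y0
    for j, k in rows:
        cov = model.covariates[j]
        cat = model.nonreference_categories[k]
        svg.text(x0 - 8, y + 0.35 * config.font_size, f"{cov.name} → {cat}",
                 "rowlabel", "end")
        span = chart.point_span[k, j]
        span_px = (x1 - x0) * span / 100.0
        if span == 0.0:
            svg.text(x_pts(0.0), y + 0.35 * config.font_size, "0 points", "zero-row")
        elif span_px < 3.0 * config.font_size:
            # too narrow for per-value labels; annotate the extent instead
            svg.line(x_pts(0.0), y, x_pts(span), y, f"row row-{j}-{k}")
            svg.text(x_pts(span) + 4, y + 0.35 * config.font_size,
                     f"0–{_fmt(round(span, 2))} pts", "narrow-row")
        else:
            svg.line(x_pts(0.0), y, x_pts(span), y, f"row row-{j}-{k}")
            if cov.kind == "binary":
                values = [0.0, 1.0]
            else:
                # label density limited by the row's pixel width
                nmax = max(2, int(span_px / (3.2 * config.font_size)) + 1)
                values = _nice_linear(cov.low, cov.high, nmax)
            for v in values:
                p = chart.beta_star[k, j] * v - chart.point_min[k, j]
                svg.line(x_pts(p), y, x_pts(p), y - 4, "tick tick-row",
                         data_pos=coord(p))
                svg.text(x_pts(p), y - 5, _fmt(v), "ticklabel-row", "middle")
        if span > 0.0:
            if case is not None and config.show_case_overlay:
                p = case.points[k, j]
                svg.line(x_pts(p), ruler_y, x_pts(p), y, "case-drop", dashed=True)
                svg.circle(x_pts(p), y, 2.0, "case-mark")
        y += row_h

    y += row_h
    for k, cat in enumerate(model.nonreference_categories):
        svg.text(x0 - 8, y + 0.35 * config.font_size,
                 f"Baseline points → {cat}", "rowlabel", "end")
        svg.text(x_pts(0.0), y + 0.35 * config.font_size,
                 fmt_pts(chart.bl_star[k]), "baseline-value")
        y += row_h

    # Total Points axis spanning the achievable totals across categories
    t_lo = float(chart.total_range[:, 0].min())
    t_hi = float(chart.total_range[:, 1].max())

    def x_tot(t: float) -> float:
        return x0 + (x1 - x0) * (t - t_lo) / (t_hi - t_lo)

    y_tot = y + 1.5 * row_h
    svg.line(x_tot(t_lo), y_tot, x_tot(t_hi), y_tot, "axis axis-total")
    svg.text(x0 - 8, y_tot + 0.35 * config.font_size, "Total points", "axis-name", "end")
    for t in _nice_linear(t_lo, t_hi, 11):
        svg.line(x_tot(t), y_tot, x_tot(t), y_tot - 4, "tick tick-total",
                 data_pos=coord(t))
        svg.text(x_tot(t), y_tot - 6, _fmt(t), "ticklabel-total", "middle")

    # Exp axis: values exp((Total + min_bl)/r) at 1-2-5 mantissas
    y_exp = y_tot + 1.8 * row_h
    svg.line(x_tot(t_lo), y_exp, x_tot(t_hi), y_exp, "axis axis-exp")
    svg.text(x0 - 8, y_exp + 0.35 * config.font_size, "Exp(lp)", "axis-name", "end")
    e_lo = math.exp((t_lo + chart.min_bl) / chart.r)
    e_hi = math.exp((t_hi + chart.min_bl) / chart.r)
    last_edge = -math.inf
    for v in _decade_values(e_lo, e_hi, (1.0, 2.0, 5.0)):
        t = chart.r * math.log(v) - chart.min_bl
        x = x_tot(t)
        half_w = 0.31 * config.font_size * len(_fmt(v)) + 2
        if x - half_w < last_edge:  # label would collide with the previous one
            continue
        last_edge = x + half_w
        svg.line(x, y_exp, x, y_exp - 4, "tick tick-exp", data_pos=coord(t))
        svg.text(x, y_exp + 1.7 * config.font_size, _fmt(v), "ticklabel-exp", "middle")

    if case is not None and config.show_case_overlay:
        totals = case.totals.round() if config.integer_points else case.totals
        for k, cat in enumerate(case.categories):
            t = float(totals[k])
            t = min(max(t, t_lo), t_hi)
            svg.line(x_tot(t), y_tot, x_tot(t), y_exp, "case-total", dashed=True)
        s_val = sum(math.exp((float(t) + chart.min_bl) / chart.r) for t in totals)
        # totals for near-tied categories sit on top of each other, so list
        # them in a stacked block instead of labeling each dashed line
        ly = y_exp + 3.6 * config.font_size
        for k, cat in enumerate(case.categories):
            svg.text(x0, ly, f"{cat}: Total = {float(totals[k]):.1f}, "
                     f"exp(lp) = {case.exp_values[k]:.4f}", "case-reading")
            ly += 1.3 * config.font_size
        svg.text(x0, ly, f"S = {s_val:.4f}", "case-S")

    return svg.done()
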