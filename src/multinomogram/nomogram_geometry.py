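"""Parallel-scale nomogram geometry for the identity ``o = l + s``.

Three vertical axes: L (left, at x=0) carries the linear predictor ``l_k``,
S (right, at x=d) carries the log normalizer ``s``, and O (middle, at
x=d_LO) carries the log probability ``o_k = ln pi_k``.  With axis scalings

    m1 = h / (l_up - l_low),   m3 = h / (s_up - s_low),
    m2 = m1 * m3 / (m1 + m3),  d_LO = d * m1 / (m1 + m3),

a straight line (isopleth) through the marks for ``l_k`` on L and ``s`` on
S crosses O exactly at the mark for ``o_k``, so the probability of category
k can be read off geometrically.  All axes share a common baseline: height
0 at each axis's lower range value, measured upward.

The S axis is *positioned* on the log scale ``s = -ln(1 + g)`` but
*labeled* by the sum of exponentiated linear predictors
``g = sum_p exp(l_p)``; the O axis is positioned on ``ln p`` but labeled by
the probability ``p``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model_core import ModelSpec, RangeError

__all__ = [
    "NomogramLayout",
    "Tick",
    "TickStyle",
    "build_layout",
    "layout_for_model",
    "position_on_L",
    "position_on_S",
    "position_on_O",
    "s_label_to_s",
    "s_to_s_label",
    "read_probability",
    "default_ranges",
    "make_ticks",
]


class ConfigurationError(ValueError):
    """Invalid layout parameters (non-positive sizes, empty ranges)."""


@dataclass(frozen=True)
class NomogramLayout:
    """Geometry of one nomogram: axis sizes, ranges and scaling factors.

    ``h`` and ``d`` are in arbitrary length units (the renderer maps them
    to page units); ``m1``, ``m2``, ``m3`` are lengths per log unit.
    ``o_low = l_low + s_low`` is the lower end of the middle axis on the
    log-probability scale; the O axis spans probabilities
    ``[exp(o_low), min(1, exp(l_up + s_up))]``.
    """

    h: float
    d: float
    l_low: float
    l_up: float
    s_low: float
    s_up: float
    m1: float
    m2: float
    m3: float
    d_LO: float
    o_low: float
    model_fingerprint: str | None = field(default=None, compare=False)

    @property
    def o_up(self) -> float:
        return self.l_up + self.s_up


def build_layout(
    h: float,
    d: float,
    l_range: tuple[float, float],
    s_range: tuple[float, float],
    *,
    model_fingerprint: str | None = None,
) -> NomogramLayout:
    """Place the three axes for given height, width, and value ranges.

    Both published forms of the L-to-O distance,
    ``d - d/(m1/m3 + 1)`` and ``d*m1/(m1+m3)``, are algebraically equal;
    the construction asserts their agreement.
    """
    l_low, l_up = map(float, l_range)
    s_low, s_up = map(float, s_range)
    if not (h > 0 and d > 0):
        raise ConfigurationError(f"h and d must be positive, got h={h}, d={d}")
    if not (l_low < l_up and s_low < s_up):
        raise ConfigurationError(
            f"empty axis range: l=[{l_low}, {l_up}], s=[{s_low}, {s_up}]"
        )
    m1 = h / (l_up - l_low)
    m3 = h / (s_up - s_low)
    m2 = m1 * m3 / (m1 + m3)
    d_LO = d - d / (m1 / m3 + 1.0)
    assert math.isclose(d_LO, d * m1 / (m1 + m3), rel_tol=1e-12)
    return NomogramLayout(
        h=float(h), d=float(d),
        l_low=l_low, l_up=l_up, s_low=s_low, s_up=s_up,
        m1=m1, m2=m2, m3=m3, d_LO=d_LO, o_low=l_low + s_low,
        model_fingerprint=model_fingerprint,
    )


def _check(value: float, low: float, up: float, name: str, clamp: bool) -> float:
    if clamp:
        return min(max(value, low), up)
    # tolerate float round-off at the ends
    tol = 1e-9 * max(1.0, abs(low), abs(up))
    if value < low - tol or value > up + tol:
        raise RangeError(f"{name}={value} outside axis range [{low}, {up}]")
    return min(max(value, low), up)


def position_on_L(layout: NomogramLayout, l: float, *, clamp: bool = False) -> float:
    """Height of the mark for linear predictor ``l``: ``m1*(l - l_low)``."""
    l = _check(float(l), layout.l_low, layout.l_up, "l", clamp)
    return layout.m1 * (l - layout.l_low)


def position_on_S(layout: NomogramLayout, s: float, *, clamp: bool = False) -> float:
    """Height of the mark for log normalizer ``s``: ``m3*(s - s_low)``."""
    s = _check(float(s), layout.s_low, layout.s_up, "s", clamp)
    return layout.m3 * (s - layout.s_low)


def position_on_O(layout: NomogramLayout, p: float, *, clamp: bool = False) -> float:
    """Height of the mark for probability ``p``: ``m2*(ln p - o_low)``."""
    p = float(p)
    if not 0.0 < p <= 1.0:
        raise RangeError(f"probability must be in (0, 1], got {p}")
    o = math.log(p)
    o = _check(o, layout.o_low, min(0.0, layout.o_up), "ln p", clamp)
    return layout.m2 * (o - layout.o_low)


def s_label_to_s(g: float) -> float:
    """Convert an S-axis label ``g = sum_p exp(l_p)`` to its position value
    ``s = -ln(1 + g)``."""
    if g <= 0:
        raise ValueError(f"S-axis label must be positive, got {g}")
    return -math.log1p(g)


def s_to_s_label(s: float) -> float:
    """Inverse of :func:`s_label_to_s`: ``g = exp(-s) - 1``."""
    return math.expm1(-s)


def read_probability(layout: NomogramLayout, l: float, s: float) -> float:
    """Read a probability off the nomogram with an explicit isopleth.

    Draws the straight line through the mark for ``l`` on the L axis (x=0)
    and the mark for ``s`` on the S axis (x=d), intersects it with the
    vertical O axis at x=d_LO, and converts the intersection height back
    through the O scale.  By the parallel-scale construction the result
    equals ``exp(l + s)``.
    """
    yL = position_on_L(layout, l)
    yS = position_on_S(layout, s)
    yO = yL + (yS - yL) * layout.d_LO / layout.d
    return math.exp(yO / layout.m2 + layout.o_low)


def _vertex_matrix(model: ModelSpec) -> np.ndarray:
    corners = itertools.product(*((c.low, c.high) for c in model.covariates))
    return np.array(list(corners), dtype=float)


def default_ranges(
    model: ModelSpec,
    *,
    margin: float = 0.0,
    profiles: np.ndarray | None = None,
    max_enumerable: int = 20,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Axis ranges covering everything the model can produce.

    By default the covariate box (all combinations of each covariate's low
    and high bound) is enumerated.  Each linear predictor is coordinate-wise
    monotone, so the l extremes occur at box vertices, and
    ``g = sum_p exp(l_p)`` is convex in x, so its maximum — hence the s
    minimum — is also attained at a vertex.  The s *maximum* can sit in the
    box interior (coefficient columns of mixed sign across categories), so
    the upper s limit uses the covering bound
    ``g >= sum_p exp(min_x l_p)``; it is exact whenever all categories
    attain their minimum at a common vertex (e.g. any K=2 model) and
    slightly generous otherwise, guaranteeing every in-range profile is
    readable.  If ``profiles`` (an n x J array of observed covariate rows)
    is given, ranges come from those observed subjects instead, mirroring
    development-data-based axis limits.  For J > ``max_enumerable`` the box
    has too many vertices and conservative coordinate-wise bounds are used
    (with a warning).

    ``margin`` widens each range by that fraction of its span on both ends.
    """
    if profiles is not None:
        X = np.atleast_2d(np.asarray(profiles, dtype=float))
    elif model.J <= max_enumerable:
        X = _vertex_matrix(model)
    else:
        warnings.warn(
            f"J={model.J} covariates: too many box vertices to enumerate; "
            "falling back to coordinate-wise bounds (s range conservative)",
            stacklevel=2,
        )
        B = model.coefficients
        lo_term = np.minimum(B * model.lows, B * model.highs).sum(axis=1)
        up_term = np.maximum(B * model.lows, B * model.highs).sum(axis=1)
        l_lo_k = model.intercepts + lo_term
        l_up_k = model.intercepts + up_term
        l_low, l_up = float(l_lo_k.min()), float(l_up_k.max())
        s_low = float(-logsumexp(np.concatenate(([0.0], l_up_k))))
        s_up = float(-logsumexp(np.concatenate(([0.0], l_lo_k))))
        return _widen((l_low, l_up), (s_low, s_up), margin)

    L = model.intercepts + X @ model.coefficients.T  # (n, K-1)
    l_low, l_up = float(L.min()), float(L.max())
    if l_low == l_up:
        raise ConfigurationError(
            "model produces a single linear-predictor value over the covariate "
            "box (all coefficients zero?); supply explicit axis ranges"
        )
    S = -logsumexp(np.hstack([np.zeros((L.shape[0], 1)), L]), axis=1)
    s_low = float(S.min())
    if profiles is not None:
        s_up = float(S.max())
    else:
        # g is convex, so its box minimum may be interior; bound it below by
        # the sum of per-category minima (exact when those share a vertex)
        s_up = float(-logsumexp(np.concatenate(([0.0], L.min(axis=0)))))
    return _widen((l_low, l_up), (s_low, s_up), margin)


def _widen(l_range, s_range, margin):
    if margin < 0:
        raise ConfigurationError("margin must be >= 0")
    (a, b), (c, d) = l_range, s_range
    da, dc = margin * (b - a), margin * (d - c)
    return (a - da, b + da), (c - dc, d + dc)


def layout_for_model(
    model: ModelSpec,
    h: float = 10.0,
    d: float = 10.0,
    *,
    l_range: tuple[float, float] | None = None,
    s_range: tuple[float, float] | None = None,
    margin: float = 0.0,
    profiles: np.ndarray | None = None,
) -> NomogramLayout:
    """Build a layout whose axis ranges cover a model's achievable values."""
    if l_range is None or s_range is None:
        lr, sr = default_ranges(model, margin=margin, profiles=profiles)
        l_range = l_range or lr
        s_range = s_range or sr
    return build_layout(h, d, l_range, s_range, model_fingerprint=model.fingerprint())


# ---------------------------------------------------------------------------
# tick marks

@dataclass(frozen=True)
class Tick:
    """One tick: height above the axis's lower end, display label, and the
    underlying value on the axis's *positioning* scale (l, s, or ln p)."""

    position: float
    label: str
    value: float


@dataclass(frozen=True)
class TickStyle:
    """Tick density controls; labels use 1-2-5 "nice number" sequences.

    ``min_sep_frac``: minimum separation between kept ticks as a fraction
    of the axis height.  The S axis compresses severely near g -> 0 (where
    positions go like -g) and the O axis can compress for narrow ranges;
    ticks closer than this are greedily thinned, keeping the lower one.
    """

    max_linear_ticks: int = 11
    per_decade: tuple[float, ...] = (1.0, 2.0, 5.0)
    min_sep_frac: float = 0.05


def _thin(ticks: list["Tick"], h: float, frac: float) -> list["Tick"]:
    if frac <= 0:
        return ticks
    kept: list[Tick] = []
    for tk in sorted(ticks, key=lambda t: t.position):
        if not kept or tk.position - kept[-1].position >= frac * h:
            kept.append(tk)
    return kept


def _fmt(v: float) -> str:
    if v == 0:
        return "0"
    if abs(v) >= 1e5 or abs(v) < 1e-4:
        return f"{v:g}"
    s = f"{v:.10f}".rstrip("0").rstrip(".")
    return s


def _nice_linear(lo: float, hi: float, nmax: int) -> list[float]:
    """At most nmax round values covering [lo, hi] with a 1/2/2.5/5 step."""
    span = hi - lo
    raw = span / max(nmax - 1, 1)
    mag = 10.0 ** math.floor(math.log10(raw))
    for mult in (1.0, 2.0, 2.5, 5.0, 10.0):
        step = mult * mag
        if span / step <= nmax - 1:
            break
    first = math.ceil(lo / step - 1e-9) * step
    vals = []
    v = first
    while v <= hi + 1e-9 * max(1.0, abs(hi)):
        vals.append(round(v, 12) + 0.0)  # +0.0 normalizes -0.0
        v += step
    return vals


def _decade_values(lo: float, hi: float, per_decade: tuple[float, ...]) -> list[float]:
    """Values m*10^e in [lo, hi] for m in per_decade, ascending."""
    out = []
    e = math.floor(math.log10(lo)) - 1
    while 10.0 ** e <= hi:
        for m in per_decade:
            v = m * 10.0 ** e
            if lo - 1e-15 <= v <= hi * (1 + 1e-12):
                out.append(v)
        e += 1
    return sorted(set(out))


def make_ticks(axis: str, layout: NomogramLayout, style: TickStyle | None = None) -> list[Tick]:
    """Tick marks for one axis, every position within [0, h].

    L: linear in the predictor value.  O: round probabilities (1-2-5 per
    decade) between ``exp(o_low)`` and the attainable top, positioned on
    the log scale.  S: labeled by ``g = sum exp(l_p)`` at 1-2-5 log-spaced
    values, positioned via ``s = -ln(1+g)`` — larger labels sit lower.
    """
    style = style or TickStyle()
    if axis == "L":
        vals = _nice_linear(layout.l_low, layout.l_up, style.max_linear_ticks)
        return [Tick(position_on_L(layout, v), _fmt(v), v) for v in vals]
    if axis == "O":
        p_lo = math.exp(layout.o_low)
        p_hi = math.exp(min(0.0, layout.o_up))
        ps = _decade_values(p_lo, p_hi, style.per_decade)
        if p_hi == 1.0 and 1.0 not in ps:
            ps.append(1.0)
        ticks = [Tick(position_on_O(layout, p), _fmt(p), math.log(p)) for p in ps]
        return _thin(ticks, layout.h, style.min_sep_frac)
    if axis == "S":
        g_lo = s_to_s_label(layout.s_up)  # s decreasing in g
        g_hi = s_to_s_label(layout.s_low)
        gs = _decade_values(max(g_lo, 1e-12), g_hi, style.per_decade)
        ticks = []
        for g in gs:
            s = s_label_to_s(g)
            if layout.s_low - 1e-12 <= s <= layout.s_up + 1e-12:
                ticks.append(Tick(position_on_S(layout, s, clamp=True), _fmt(g), s))
        return _thin(ticks, layout.h, style.min_sep_frac)
    raise ValueError(f"axis must be 'L', 'S' or 'O', got {axis!r}")
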