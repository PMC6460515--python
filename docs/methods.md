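# Methods

## Model

The package operates on a *given* multinomial logistic model with K ≥ 2
outcome categories and J ≥ 1 covariates. With category K as reference,

    lp_k(x) = α_k + β_k′ x,                       k = 1, …, K−1,
    π_k(x)  = exp(lp_k) / (1 + Σ_p exp(lp_p)),    k < K,
    π_K(x)  = 1 / (1 + Σ_p exp(lp_p)).

Nothing is estimated: intercepts and coefficients come from a publication
or an external fit, at whatever precision they were reported. Probabilities
computed from rounded published coefficients therefore differ from the
source model's own predictions; the packaged delivery model reproduces its
published case probabilities only to within a few percentage points, which
is a property of the published rounding, not of this implementation.

Writing l_k = lp_k(x) and s = −ln(1 + Σ_p exp l_p) gives the additive
decomposition ln π_k = l_k + s (with l_K ≡ 0), which both artifacts
exploit. s and the probabilities are evaluated with log-sum-exp over
(0, l_1, …, l_{K−1}), so user-supplied models with extreme coefficients
neither overflow nor lose the leading 1.

## Nomogram geometry

Axes L (x = 0), O (x = d_LO) and S (x = d) are vertical, share a common
baseline (height 0 at each axis's lower range value, measured upward), and
carry the values l, ln π and s with scalings

    m1 = h/(l_up − l_low),  m3 = h/(s_up − s_low),  m2 = m1·m3/(m1 + m3),
    d_LO = d·m1/(m1 + m3)  ( = d − d/(m1/m3 + 1), asserted equal ).

Under these choices the straight line through the marks for l_k and s
crosses O at the mark for l_k + s, so `read_probability` performs the
geometric construction literally — build the line, intersect it with
x = d_LO, invert the O scale — and agrees with exp(l+s) to ~10⁻¹⁵ in the
test sweeps. The read-off is invariant to the choice of h and d.

Conventions that the construction leaves open and this package fixes:

* S tick positions use m3·(s_t − s_low), symmetric with the L formula; any
  other anchor would place ticks outside [0, h].
* The O axis is anchored at o_low ≡ l_low + s_low **on the log scale**,
  with probability labels spanning [exp(o_low), min(1, exp(l_up + s_up))]
  and positions m2·(ln p − o_low). The collinearity identity o = l + s
  only holds on the log scale, so no further transformation is applied to
  o_low.
* The S axis is *labeled* by g = Σ_p exp(lp_p) but *positioned* on
  s = −ln(1+g); larger labels sit lower. The label map and its inverse
  g = exp(−s) − 1 round-trip to 10⁻¹².

### Default axis ranges

When no explicit ranges are given they are derived from the covariate box
(every covariate at its declared low/high bound, 2^J vertices, capped at
J = 20):

* l_low, l_up: exact — each linear predictor is coordinate-wise monotone,
  so its extremes sit at vertices.
* s_low: exact — g is a sum of exponentials of affine functions, hence
  convex in x, so its maximum (the s minimum) is attained at a vertex.
* s_up: the maximum of s is the *minimum* of a convex function and may lie
  in the interior of the box whenever a covariate's coefficients differ in
  sign across categories. It is bounded by g ≥ Σ_p exp(min_x lp_p), which
  is exact when all categories attain their minima at a common vertex
  (always true for K = 2) and slightly generous otherwise. The generosity
  costs a little unused axis length but guarantees that every in-range
  profile can be read off the chart.

Alternatively, observed covariate rows can be supplied and the ranges are
then taken from those subjects, mirroring the common practice of sizing
axes by the development data. Beyond J = 20 covariates a coordinate-wise
fallback (with a warning) produces conservative bounds. A model whose
linear predictors are constant over the box has no usable range and raises
an error asking for explicit ranges.

Ticks use 1-2-5 "nice number" sequences: linear steps on L, round
probabilities per decade on O, round g labels per decade on S. Because the
S scale compresses severely as g → 0, ticks closer than 5 % of the axis
height are thinned greedily (keeping the lower one); every surviving tick
stores a position that recomputes exactly from its value.

## Scoring chart

The rescaling factor r = 100 / max_{j,k} |β_jk (x_up_j − x_low_j)| makes
the single largest covariate effect span exactly 100 points, and

    Points_jk(x) = β*_jk·x − min(β*_jk·x_up_j, β*_jk·x_low_j),
    β*_jk = r·β_jk,

anchors every scale at 0 at the covariate's most favorable end regardless
of the coefficient's sign, so all points lie in [0, 100]. Baselines
bl_k = r·α_k + Σ_j min(β*_jk x_up_j, β*_jk x_low_j) are standardized to
bl*_k = bl_k − min_k bl_k (a tie in the minimum needs no breaking — the
subtraction simply zeroes every tied category). Totals
Total_k = bl*_k + Σ_j Points_jk(x_j) recover the linear predictor exactly
through l_k = (Total_k + min_k bl_k)/r, which is also the map used to
relabel the nomogram's L axis in total-points units and to place the Exp
axis, exp((Total + min_bl)/r). The achievable total range per category is
[bl*_k, bl*_k + Σ_j span_jk], from the same box-vertex reasoning as the
axis ranges.

All chart arithmetic keeps full double precision. Rounding points to
integers is purely a display option; it perturbs each linear predictor by
at most (J+1)·0.5/r (half a point per covariate plus the baseline), so the
induced absolute probability error is below exp((J+1)·0.5/r) − 1 — checked
empirically on random models. Covariate–category cells with a zero
coefficient keep a structurally identical (zero-width) row so every
category can be scored the same way.

## Rendering

SVG 1.1 text is the single canonical output: deterministic (identical
inputs give identical bytes; fonts referenced by generic family only),
diffable, and testable — every tick element carries its axis position in a
`data-pos` attribute, so a parser can verify the drawing against the
geometry operations digit for digit. Layout and chart both carry a model
fingerprint; rendering a layout against a chart from a different model is
an error. Label density adapts to available space (row labels thin with
the row's pixel width; rows narrower than ~3 em are annotated with their
extent instead of per-value ticks). Case overlays list per-category totals
in a stacked block rather than labeling each isopleth, because categories
with near-tied linear predictors produce isopleths too close to label
individually — as in the packaged model's worked case. PDF/PNG conversion
is left to external tools.

## Synthetic models

`generate_random_model(seed, K, J)` draws intercepts from N(0, 1) and
coefficients from N(0, 0.7); each covariate is binary with probability 1/2
or continuous with low ~ U(−2, 1) and width ~ U(0.5, 4). These magnitudes
give linear predictors and probabilities spanning the clinically typical
range (roughly 10⁻⁴ to ~1) without routinely saturating the softmax, which
is what the geometric and points identities need to be exercised
meaningfully. The generator emulates the *structure* of fitted prediction
models, not real data: coefficients are independent across categories and
covariates, there is no collinearity between covariates, no interaction or
spline terms, and no sampling noise — so passing sweeps demonstrate the
exactness of the construction for any first-order model, not the clinical
validity of any particular one.

Profile sampling is uniform over each covariate's range (Bernoulli(1/2)
for binary), i.e. profiles cover the whole declared box rather than a
realistic population density.

## Verification sizes and tolerances

The property sweeps use 1000 seeded (model, profile) instances for the
collinearity and chart round-trip identities (tolerance 10⁻⁹ relative;
observed ~10⁻¹⁵), 300 for the points-system invariants (span = 100 within
10⁻⁹, totals identity within 10⁻¹⁰), 100 binary models for the logistic
reduction (10⁻¹²), and 100 instances against a 50-digit decimal
re-evaluation of the softmax (10⁻¹⁴). Probabilities must sum to 1 within
10⁻¹² everywhere.

## Limitations

* First-order main-effects models only; interaction or spline terms would
  need per-term axes and are not constructed.
* Multi-level categorical covariates must be supplied pre-coded as binary
  dummies.
* The package reports no uncertainty: confidence intervals, calibration
  and discrimination belong to model development, which is out of scope.
* Chart accuracy in actual use is limited by drawing and reading
  precision; the package quantifies only the integer-rounding part of that
  error.
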