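# Methods

## Radar-chart geometry

A site's standardized resource profile is drawn as `n` equal-angle
sectors (angle `2π/n`), one per resource, with the z-scored, shifted
abundance as the sector radius. Radii are placed in ascending order, so
the boundary's radial (non-arc) segments total exactly
`2(r_max − r_min)`; unsorted placement would instead sum cyclic adjacent
differences and is not offered. Closed forms:

    S = (π/n) Σ r_j²            total sector area
    L = 2(r_max − r_min) + (2π/n) Σ r_j

`RE = 4πS/L²` is then a true isoperimetric quotient: 1 exactly when all
radii are equal (the chart is a circle) and strictly below 1 otherwise.
An alternative `as_printed` mode sums one *full circle* per resource
(`π r²`, `2π r`); under it an evenly balanced profile scores `RE = 1/n`,
which contradicts the index's meaning as "area over the area of the
circle with the same perimeter", so `sector` is the default and
`as_printed` is retained only for comparison. Both closed forms are
verified in the tests against an independent polygonal discretization of
the boundary (10⁵ angular steps, relative error < 1e-6).

### Standardization and the positivity shift

Radii must be positive. Columns are z-scored (sample sd by default;
population sd available via `sd_mode` since either convention is
defensible) and shifted by a constant, default +2. A z-score at or below
−shift is an **error**, not a clip: silently clipping would flatten the
low tail and inflate RE. For data whose minimum z-score falls below −2
(routine at n ≈ 100 with approximately normal resources), `shift="auto"`
selects the smallest integer ≥ 2 that keeps every radius positive —
the same "smallest sufficient integer" rule that motivates the +2
default — and is the pipeline default. RR's max-normalization and RE's
scale invariance keep the indices comparable across shift values, though
RD values are only directly comparable between runs using the same
shift.

## Synthetic site tables

The generator emulates a 97-site grassland survey spanning desert,
steppe and meadow. What it reproduces:

- **Correlated resources.** Column `j` is `λ_j f + √(1−λ_j²) ε` on the
  standardized scale (`f` a latent fertility axis, default loadings
  0.8/0.8/0.7/0.6 for MAP/TOC/TN/TP), affinely mapped to natural units
  (MAP 300 ± 110 mm; TOC 20 ± 7, TN 1.8 ± 0.6, TP 0.55 ± 0.15 g/kg).
  Imperfect loadings allow water-rich but nutrient-poor sites. Values
  are floored at 0.1% of the column mean so natural units stay positive
  in extreme tails.
- **Plateauing responses.** AGB and SR follow three-parameter logistics
  of the computed RD with Gaussian noise; SR is rounded with floor 1.
  Defaults: SR `a=13, k=7, m=0.50`; AGB `a=50, k=7, m=0.68`; noise sd
  1.2 species and 4 g/m². The midpoint order `m_SR < m_AGB` encodes
  richness saturating before productivity. Equal rates `k` were chosen
  deliberately: they keep the analytic DI bounded between
  `e^{±k(m_AGB−m_SR)}` so its quadratic smooth localizes the DI = 1
  crossing between the two midpoints, and `k = 7` keeps desert-site AGB
  at a few g/m² rather than near zero, so the raw SR/AGB ratio behind
  the coupling degree is not dominated by additive noise at the dry end.
  Asymptotes target realistic magnitudes (SR ≈ 8–14, AGB ≈ 40–50 g/m² at
  fertile sites) without copying any particular survey.
- **A sign-switching interaction.** SR receives
  `γ(rank) · resid_AGB / a_AGB · a_SR`, where `γ` ramps linearly from
  `+γ₀` at the lowest-RD site to `−γ₀` at the highest (γ₀ = 1 by
  default): sites with above-curve biomass carry extra species under
  scarcity (facilitation) and fewer under abundance (competition), per
  the stress-gradient hypothesis. Placing the interaction on SR given
  AGB matches the downstream partial analysis, which predicts SR from
  RD and AGB.

What it does **not** reproduce: spatial autocorrelation, species-level
abundances (so Simpson's dominance is exposed as a standalone statistic,
not wired to the generator), climate time series, observation error in
the resources, or any non-Gaussian residual structure. Passing tests
therefore demonstrate that the *procedure* recovers a known structure of
this kind, not that real grasslands follow it.

Determinism: the resource matrix is drawn from `default_rng(seed)` and
the community noise from a spawned child of the same seed, so
resources-only runs and full runs agree on the resource draws.

## Curve fitting and model comparison

Linear and quadratic fits are ordinary least squares; the logistic
`y = a/(1+e^{−k(x−m)})` is nonlinear least squares (`scipy.curve_fit`,
bounds `a, k > 0`) initialized at `a₀ = max y`, `m₀ = median x`,
`k₀ = 4·slope(y~x)/a₀` with five jittered restarts; the best RSS wins
and non-convergence is returned as a flagged fit. AIC uses the Gaussian
form `n ln(RSS/n) + 2(p+1)`, counting the error variance as a parameter.
The "key coefficient" p-value is the slope (linear), quadratic term
(quadratic) or rate `k` (logistic, from its asymptotic standard error
on n−3 df).

## DI, tipping point, coupling degree

SR (a count) and AGB (g/m²) are incommensurable, so DI is computed from
fits on **min–max-normalized** responses (default). A `zscore` mode
rescales raw-fit derivatives by 1/sd — fitting a 3-parameter logistic
directly to a vertically shifted (negative-valued) response is not
possible, and only the derivative scale matters for DI — and `raw` is
available. DI is evaluated at the observed RD values by default (one
point per site, mirroring per-site DI dots; a uniform grid is a config
option), a quadratic is regressed through the points, and the tipping
point is the in-range root of `quadratic = 1` at which DI passes from
above to below 1; no such root returns null rather than an extrapolated
value.

The coupling degree `C = 2√(SR·P)/(SR+P)` depends only on the SR/AGB
ratio, and the drift of that ratio along RD — biomass outgrowing
richness past the richness plateau — is the signal, so the pipeline
computes C on the **raw** pairwise values (min–max normalization forces
both responses through 0 → 1 and mechanically *raises* C along the
gradient, reversing the statistic's meaning). Pairs with `SR + P = 0`
are excluded; the trend is the OLS slope of C on RD.

## Grouping, partial effects, windows

- Quantile groups: sites sorted by RD; first `g−1` groups of
  `floor(n/g)`, the last takes the remainder (97 → 19/19/19/19/21). Ties
  are broken by stable input order.
- Cumulative groups: lowest (or highest) `ceil(f·n)` sites for
  increasing fractions, nested by construction.
- Partial effects: all variables z-scored, then `AGB ~ RD + SR` and
  `SR ~ RD + AGB` by OLS (statsmodels); coefficients are reported with
  t-based 95% CIs. Per-band effects are separate refits within each
  band, not interaction terms.
- Moving windows: `block` (disjoint runs of `w` sites with an
  overlapping final window when `w ∤ n`; the default, matching the
  enumerated layout 1–10, 11–20, …, 88–97) or `sliding` (step 1) for a
  dense profile. Within each window the partial correlation
  `r(AGB, SR | RD)` uses the first-order closed form with a t test on
  n−3 df. Degenerate windows are flagged, not dropped. No
  multiple-testing correction is applied across groups or windows.

## Numerical and degenerate-input policy

Zero-variance resource columns, non-positive radii, non-finite scales,
unnormalized abundance vectors and undersized samples raise errors
naming the offending quantity. The AGB-derivative threshold for dropping
DI grid points is 1e-12; quadratic root finding treats `|c₂|` below
1e-12 (relative) as linear. Validation drops flagged site rows with a
warning and aborts past 10% invalid.

## Problem sizes

The test suite and the acceptance script run entirely on generated
tables: 97 sites per replicate, 20 replicates for tipping-point
recovery, 100 for the sign-structure rates, 100 random radius vectors at
10⁵ discretization steps for the geometry oracle, and n = 2000–5000 for
large-sample structural checks — sizes at which every Monte-Carlo bound
used in the tests is comfortably stable.

## Known limitations

RD is relative to the site set analysed (RR's max-normalization and the
z-scores are sample-dependent), so indices from different surveys are
not directly comparable. The tipping point inherits the bias of
quadratic smoothing when DI is strongly convex over the observed range.
The logistic family has no intercept, so responses with a nonzero lower
plateau are better served by the quadratic fit. The generator's
interaction ramp is linear in RD *rank*, not RD value — a deliberate
simplification that fixes the crossover at the median site.
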