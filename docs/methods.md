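# Methods

## Scope and data model

The unit of observation is a leaf (lamina length *L* cm, width *W* cm,
optionally area *A* cm² and dry mass g), keyed to a shoot and a species.
Aggregation produces one record per shoot: leaf count *N*<sub>T</sub>,
total area *A*<sub>T</sub> = ΣA, total dry mass *M*<sub>T</sub> (from leaf
masses, or from a pooled per-shoot weighing table — both occur in practice
because leaves are often dried and weighed together), the sum of leaf
widths *L*<sub>KS</sub> and the maximum leaf length *W*<sub>KS</sub>. The
two composite labels are swapped in parts of the literature; the fitted
product *L*<sub>KS</sub>·*W*<sub>KS</sub> is invariant to the labelling, so
the choice affects reporting only. Shoots with a single leaf are retained:
the shoot-level proportionality degenerates gracefully to the per-leaf
product.

## Leaf geometry

Outlines are ordered planar boundary rings in cm, implicitly closed (a
duplicated closing vertex is dropped), winding-agnostic. Area is the
absolute shoelace area. Length and width use a caliper convention: the
length axis is the direction of the maximum pairwise point distance (the
convex-hull diameter, found exactly by an O(h²) scan of hull vertices); *L*
is the extent of projections on that axis and *W* the extent on its normal.
This is parameter-free and matches the intuitive long axis of elongated
laminae, but it is not the midrib: for strongly curved laminae the two
differ, so a `principal` convention (leading principal component of the
boundary) is available as an alternative. Note the caliper *L* of a
rectangle is its diagonal, so the ratio *A*/(*L·W*) of a rectangle is below
1 under this convention; for smooth convex laminae (the realistic case) the
convention matches physical length/width, and a sampled ellipse converges
to *A*/(*L·W*) = π/4.

Degenerate inputs are rejected explicitly: fewer than 3 distinct points and
self-intersecting rings are invalid; collinear rings (detected by a rank
test on centred coordinates) and zero-area rings are degenerate.

## Distribution fitting

Per-shoot traits are fitted by maximum likelihood to three families.
Normal and log-normal MLEs are closed-form (MLE variance, ddof 0). The
two-parameter Weibull

  f(x) = (δ/λ)(x/λ)^{δ−1} exp(−(x/λ)^δ)

is fitted by profiling the scale analytically, λ(δ) = (mean xᵟ)^{1/δ},
which reduces the problem to a one-dimensional root find on the shape
score; the bracket starts at the method-of-moments shape (matched through
the coefficient of variation) and expands geometrically until a sign
change. This removes initialisation sensitivity and gives a deterministic
optimum whose analytic gradient is below 1e−6 in both parameters. Constant
samples are rejected as non-identifiable.

Goodness of fit uses the plain one-sample Kolmogorov–Smirnov test against
the fitted CDF with the asymptotic p-value. With estimated parameters this
test is anti-conservative; the plain version remains the default because it
is the field's standard reporting, and a parametric-bootstrap p-value mode
(`ks_test(method="bootstrap")`) is provided for rigor. Leaf counts are
integers but are fitted as continuous, consistent with density-overlay
reporting practice. Weibull shapes classify skewness around the δ = 3.6
landmark where the density's third moment changes sign (< 3.6 right-skewed,
> 3.6 left-skewed). Trait summaries report both SD and SE, since published
figure annotations are ambiguous between the two readings.

## Scaling fits

All fits operate on logs; natural log internally. *k*, *α* and *β* are
base-invariant; the reported log-scale RMSE and intercept *γ* are divided
by ln(base) when a base is configured (default natural).

- Proportional (slope fixed at 1): log *k* = mean(log *y* − log *x*), i.e.
  *k* is the geometric mean ratio. RMSE uses n−1 residual degrees of
  freedom; r² = 1 − SSE/SST on the log scale and is not clamped (a terrible
  fixed-slope fit can be negative); MAPE is computed on the original scale.
- OLS power law: standard least squares of log *y* on log *x* (n−2 dof).
- RMA power law: *α* = sign(*r*)·sd(log *y*)/sd(log *x*), line through the
  centroid. Zero correlation leaves the slope sign undefined and is
  reported as an error rather than silently resolved.

Method selection follows dimensional homogeneity: OLS when the two
variables share a physical dimension (*A* vs *LW*; *A*<sub>T</sub> vs
*L*<sub>KS</sub>*W*<sub>KS</sub>), RMA otherwise (*A*<sub>T</sub> vs
*N*<sub>T</sub>; *A*<sub>T</sub> vs *M*<sub>T</sub>).

## Bootstrap inference

Cases are resampled with replacement — leaf rows for the per-leaf fit,
shoot rows for shoot-level fits, which is the only self-consistent unit of
resampling for each model. Default B = 3000 replicates; CIs are percentile
intervals taken as order statistics (`closest_observation`), which makes
them exactly equivariant under monotone transforms — the CI of *k* is the
antilog of the CI of log *k*. Two-group comparisons difference
independently resampled replicate vectors index-by-index at equal B (the
standard two-sample bootstrap; an all-pairs mode is available for unequal
B) and declare significance when the difference CI excludes zero. The
isometry test asks whether the CI of *α* contains 1. Replicates on which a
fit is non-identifiable (e.g. an RMA resample with zero correlation) are
dropped and counted; more than 1% failures aborts the inference. One master
seed per run derives a logged sub-seed for every bootstrap task in a fixed
order, so reports are bit-reproducible.

Estimators expose a vectorised `fit_many` over resample matrices, which the
bootstrap uses when present (column-wise moments; a 500-repeat coverage
experiment at B = 1000 runs in seconds); foreign estimators fall back to a
clone-and-refit loop.

## Synthetic populations

The generator emulates a leaf census of S shoots: leaf counts fixed or
drawn from a ceiling-discretised Weibull (echoing the right-skewed counts
of real surveys; the ceiling adds ≈ 0.5 to the configured mean); smallest
leaf area per shoot log-uniform over a range (so shoots span sizes evenly
on the log scale, matching the log-log regression design); within-shoot
areas ascending as a geometric series; lengths solved from
*A* = *k·L·W* with *W* = *c·L*<sup>b</sup>; measurement-style log-normal
noise multiplied onto recorded areas *after* dimensions are laid down, so
per-leaf *A*/(*L·W*) scatters around *k* while the noiseless limit keeps
the identity exact to machine precision. The Montgomery ratio is constant
(*k*₀) or declines with lamina length, *k* = *k*₀(*L*/*L*₀)^{−η},
mimicking larger leaves gaining less area per unit *L·W*; η is a free
knob whose effect the sensitivity tests measure rather than assert. Mass
attaches either per leaf (m = m₀Aᶿ with log-normal noise, pooled per
shoot) or directly per shoot (M_T = m₀A_Tᶿ), the latter emulating surveys
that weigh each shoot's leaves together.

Four structural conditions jointly force exact isometry of *A*<sub>T</sub>
against *L*<sub>KS</sub>·*W*<sub>KS</sub>: constant leaf count, geometric
series, common ratio, power-law width allometry. The default configuration
satisfies all four, and with zero noise the fitted OLS slope equals 1 to
1e−6 (observed: machine precision) — the generator's headline oracle. Each
condition can be broken individually (Weibull counts; per-shoot ratio
jitter or a fixed largest/smallest area ratio; uniform instead of
geometric areas; an affine width term), and each break measurably perturbs
the slope away from 1 (|Δα| > 5×10⁻³ at S = 200 in the sensitivity suite,
against < 10⁻⁶ when ideal).

What the generator does **not** emulate: phyllotaxy and leaf position,
within-shoot ontogenetic gradients beyond the monotone size series,
correlated measurement error between *L*, *W* and *A* (noise enters area
only), count–size correlations across shoots, and canopy interactions.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative structure, not field validity of the proportionality
for any particular taxon.

### Survey-emulation defaults

The two-species configuration (`study_conditions()`) encodes a paired
bamboo-survey design: 122 and 120 shoots; Weibull leaf counts
moment-matched to means 26.34 and 12.51 (SDs 13.14 and 6.52); shared
*k*₀ = 0.72; width–length allometry *W* = 0.15·*L* (a lamina roughly 6–7×
longer than wide, typical of *Indocalamus*-type leaves); smallest leaf
area log-uniform on 4–40 cm²; a fixed 5× largest/smallest area ratio per
shoot (so the geometric common ratio adapts to leaf count, as real shoots
require); log-scale area noise SD 0.03, chosen to reproduce the residual
scale of published per-leaf Montgomery fits (log-RMSE ≈ 0.03 < 0.05,
r² > 0.98); pooled shoot mass with θ = 1/α for generating area–mass
exponents α = 0.912 and 0.936 and mass-noise SD 0.05; m₀ = 0.0045 g cm⁻²
(LMA of order 50–100 g m⁻², fast-growing bamboo range).

## Problem sizes

Test and acceptance runs use: S = 60 shoots for the isometry oracle,
S = 200 for sensitivity, S = 120 with B = 1000 over 100 seeds for
area–mass exponent recovery (recovery rate ≥ 90%, observed ≈ 94%), 500
repeats at B = 1000 for CI coverage (band 0.92–0.975) and 400 repeats for
the two-group type-I rate (band 0.02–0.09), n = 5000 for Weibull MLE
recovery within 5%, and the full two-species survey emulation at B = 3000.
These sizes keep every experiment's Monte Carlo error well inside its
acceptance band.

## Known limitations

- The caliper length convention differs from a midrib length on curved
  laminae; outline-based *k* values are convention-dependent at the few-
  percent level for asymmetric shapes.
- Plain KS p-values after parameter estimation are anti-conservative;
  treat family selection by KS p as descriptive, or use the bootstrap mode.
- RMA slopes are ratio-of-SD estimators: heavy noise on the predictor axis
  attenuates nothing but inflates sd(x), biasing |α| downward; the survey
  emulation keeps noise small relative to the size spread so the bias is
  well inside the bootstrap CI.
- The two-group test assumes independent groups; it is not a paired test.
- With fewer than 3 shoots per species, shoot-level fits are reported as
  unavailable rather than attempted.
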