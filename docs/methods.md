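# Methods

## The model

Cluster-level counts from a georeferenced household survey are modelled as
binomial with a logit-linear mean and an i.i.d. Gaussian random intercept
per administrative region:

    Y_ki | Z_k ~ Binomial(n_ki, π_ki)
    logit(p_ki) = β₀ + Σ_j β_j d_j(x_ki) + Z_k,   Z_k ~ N(0, σ²)

`p` is the *true* prevalence; the questionnaire's imperfection maps it to
the observed-positive probability through the fold
`π = Se·p + (1−Sp)(1−p)`. The random effect is non-spatial by design: the
intended use case is one where the empirical variogram of residuals shows
no spatial structure, and the variogram diagnostic is shipped precisely so
users can check that premise on their own data. A cluster-level random
intercept is available (`random_effect="cluster"`) for over-dispersion
without a regional interpretation.

### Misclassification: two adjustment modes

* `embedded` (default): Se/Sp enter the likelihood, so the binomial
  variance of the observed counts is modelled correctly. At prevalences
  near the false-positive floor `1−Sp` this matters: more than half of the
  observed positives can be false positives.
* `pre_adjust`: counts are replaced by `round(n·unfold(y/n))` before
  fitting, with `unfold(q) = (q + Sp − 1)/(Se + Sp − 1)` clamped to [0, 1].
  This mirrors the common practice of adjusting prevalences before
  modelling; it is kept because it is simple and reproducible, but it
  discards variance structure and floors many low-count clusters at 0.
  Rounding is half-away-from-zero (bankers' rounding would systematically
  favour even counts in exactly the low-count cells that dominate here);
  `floor` is available as a config option.

Identifiability requires Se + Sp > 1; both default to the questionnaire
values used throughout (Se = 0.97, Sp = 0.99).

### Likelihood and optimization

The marginal likelihood integrates each region's random effect with
adaptive Gauss–Hermite quadrature: the integrand's conditional mode is
found by bracketed root-finding on its monotone-dominated derivative
(Brent, xtol 1e−12), the curvature by a central difference of that
derivative, and the Q-point probabilists' Hermite rule is applied on the
mode-centered, curvature-scaled abscissae with log-sum-exp accumulation.
Q = 21 by default (Q must be odd; Q = 1 is the Laplace approximation); the
suite checks Q = 21 against Q = 41 at 1e−6 relative and against brute-force
trapezoid integration (1e5 nodes) at 1e−6 relative on single-region
problems. Below σ = 1e−4 the mixture is treated as degenerate (plain
binomial at Z = 0) and σ̂ is reported as 0.

Maximization is L-BFGS over (β, log σ) from a deterministic start — β from
the no-random-effect logit fit, log σ = log 0.1 — with up to two restarts
jittered by N(0, 0.5²) from a fixed restart stream. Convergence requires
optimizer success plus a gradient max-norm below 1e−5·(1 + |loglik|); the
scale factor is there because the loglik of 600 clusters is O(500) and its
finite-difference gradient noise scales with it. The covariance of the
estimates is the inverse (eigenvalue-clipped pseudo-inverse) of the
observed information, computed by central finite differences with step
1e−4·(1 + |θ_i|). With a single random-effect group σ is fixed at 0.

The fixed-effects engine is cross-checked against `statsmodels` GLM and the
full mixed fit against `lme4::glmer` (nAGQ = 21) in the test suite; both
agree to ~1e−3 or better on the default synthetic study.

## Prediction, intervals, burden

Pixel prevalence surfaces are Monte-Carlo: each draw samples
β ~ N(β̂, V̂_β) and, per region, Z from its conditional normal (mode,
inverse curvature); cells outside every surveyed region draw
Z ~ N(0, σ̂²). Cell prevalence is `logit⁻¹(β·d + Z)` — always on the true
(unfolded) scale, in both adjustment modes: maps describe disease, not
questionnaire positives. The "95% interval" is the 2.5–97.5 percentile
band of 1000 draws (the fit is frequentist; the band is a parametric
sampling band, not a posterior credible interval, though it plays the same
practical role). Draws are stored float32; the mean is accumulated in
float64 from the same draws so a zero-variance fit yields lower = mean =
upper exactly.

Burden is the cellwise product of mean prevalence and the female
population surface. Zonal aggregation assigns a cell to the polygon
containing its center (edge cells are the only discretization
sensitivity; an exhaustive partition conserves the grid total exactly,
which the suite asserts). Zone prevalence per 1000 is population-weighted
(1000·cases/population) by default; an unweighted pixel mean is a flag
away. Interval columns aggregate the lower/upper surfaces the same way.

## Covariate screening

Candidates are grouped by theme (correlated or like-natured surfaces
share a group); each member is fit as intercept + single slope by ML in
the active adjustment mode, without the random effect — the screen is a
ranking device, and omitting Z keeps it cheap and stable at low counts.
Covariates are standardized over clusters first (selection is invariant
to this affine change; slopes become comparable). Groups are compared by
AIC with ties to the first-listed member; a fit flagged non-converged
(separation is detected as |coefficient| > 15 on the standardized scale)
is excluded, and a group with no converged member is an error.

## Diagnostics

* **Variogram**: Pearson residuals `(y/n − π̂)/√(π̂(1−π̂)/n)` at cluster
  locations (deviance residuals by flag), semivariance
  `γ(h) = Σ_{N(h)} (r_i−r_j)²/(2|N(h)|)` with pairs binned by great-circle
  distance; default 10 equal-width bins to half the maximum pair distance;
  envelope from 99 label permutations at the 2.5/97.5 percentiles. The
  fitted π̂ includes the region's conditional mode.
* **Simulation check**: 500 parametric-bootstrap replicates from the
  fitted model; the observed mean and SD over clusters of `y/n` are
  compared with their simulated distributions; two-sided Monte-Carlo
  p-values use distance from the simulation median with the +1 correction
  so p ∈ (0, 1].

## The synthetic-study generator

The generator emulates the statistical structure of a national cluster
survey over gridded covariates, with every piece of ground truth retained:

* default extent 36–40°E, 6–10°N at 0.05° cells (~5.5 km); 11 Voronoi
  regions from seeded centroids; 600 clusters; cluster sizes
  Poisson(25) truncated at ≥5 (the truncation avoids degenerate
  denominators; the distribution is an assumption exposed in `Scenario`);
* four covariate surfaces, each a half-weight random linear trend plus 5
  Gaussian bumps rescaled to [0, 1]. The trend is de-weighted and the full
  bump count always used because linear trends span only a two-parameter
  family: trend-dominated fields made nominally distinct covariates
  near-duplicates (pairwise correlations above 0.9 at cluster sites),
  which is not what distinct real-world surfaces look like. Even so,
  smooth fields over one window correlate 0.5–0.9 by chance — a realistic
  and deliberate property; users of the recovery tests should expect
  collinearity-inflated slope variance;
* population density: log-normal around ~50 women/km² with 3 narrow
  high-density cores whose peaks clear the 1000/km² urban threshold while
  keeping the urban population share near one fifth — population-weighted
  cluster placement would otherwise collapse most clusters into the cores;
* true prevalence `logit⁻¹(−5.2 + β·d + Z_region)` with
  β = (0.6, −0.4, 0.3, 0.0) and σ = 0.3, giving a national true prevalence
  of ~5–8 per 1000; outcomes are Binomial at the folded probability
  (Se = 0.97, Sp = 0.99), and untreated counts an independent Binomial(y,
  0.5) thinning of lifetime counts (the two outcomes are modelled
  separately downstream, so no dependence beyond nesting is imposed);
* all randomness flows from one seed through named substreams (fields,
  regions, region_effects, clusters, outcomes), so regenerating one
  artifact never perturbs the others.

What the generator does *not* emulate: two-stage enumeration-area
sampling, GPS displacement, non-response, survey weights, and spatially
correlated residual structure. Passing recovery tests therefore show the
estimator is correct under its own assumptions at realistic sizes — not
that those assumptions hold in any particular real survey.

## Raster conventions

Cell-center registration, row 0 northernmost. Two coordinate systems:
`EPSG:4326` (distances by haversine; grid-edge lengths by per-row
cos-latitude scaling, 110.574/111.320 km per degree) and planar `km` for
toys and exact oracles. Bilinear resampling interpolates the four
surrounding source centers; zero-weight corners do not contribute (so
identity resampling is exact) and any positively weighted nodata corner
poisons the output cell. Urbanicity: urban ≥ 1000 persons/km²; peri-urban
> 250 within 15 km (great-circle, measured to urban cell centers — the
"urban extent edge" is not well defined on a raster); rural is the
complement. Cost distance is multi-source Dijkstra on the 8-connected
cell graph with edge cost = mean endpoint friction × inter-center
distance (diagonals √2-scaled); it is tested exhaustively against an
independent shortest-path oracle on small grids. I/O is ESRI ASCII grid
(square cells; nodata sentinel; a `.crs` sidecar records the coordinate
system) and GeoJSON for polygons.

## Problem sizes in the test suite

The statistical suites run at the generator's default sizes (600 clusters
for recovery and calibration; 150-cluster studies for shared fixtures;
50-replicate repetition for coverage/bias/calibration claims; 25 and 15
replicates in the acceptance script's recovery summaries). These sizes
make the Monte-Carlo error of each asserted proportion small relative to
its margin while keeping a full run in minutes on one core.

## Known limitations

* The asymptotic normal approximation behind the prediction bands is
  optimistic when σ̂ sits at the boundary or when total cases are a few
  dozen; the bands are sampling bands, not posteriors.
* At the default survey size the slope estimates are noisy (collinear
  smooth covariates; misclassification consumes over half the
  information), so pixel surfaces track the truth only loosely; precise
  surface recovery needs order-of-magnitude larger cluster sizes.
* Pre-adjust mode floors sub-threshold clusters at zero; with Sp = 0.99
  and true prevalence below 10/1000 this is most clusters, which is the
  main reason embedded mode is the default.
* Zonal aggregation drops cells whose center falls in no polygon; sliver
  gaps in user-supplied GeoJSON leak burden.
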