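# Methods

## The problem

Global biomass syntheses report, for each major biological group (36
free-living groups: 16 terrestrial, 18 marine, 2 subterranean), a total
standing biomass `B` (Gt carbon), a multiplicative 95% "fold"
uncertainty `λ`, and three reference body sizes — the minimum, median
and maximum individual mass in grams of carbon. This package turns
those group-level summaries into continuous body size–biomass spectra:
how much biomass the biosphere holds at each log10 body-size class,
globally and per habitat realm, with uncertainty.

## Within-group model

Biomass within a group is spread over log10 size `x` according to a
generalized extreme value (GEV) density with location `μ`, scale `σ`
and shape `ξ`,

    t(x) = (1 + ξ·(x−μ)/σ)^(−1/ξ)        (ξ ≠ 0)
    t(x) = exp(−(x−μ)/σ)                  (ξ = 0)
    f(x) ∝ (1/σ) · t(x)^(ξ+1) · exp(−t(x)),

truncated to a window `[log10(min) − 2, log10(max)]` and renormalized
so the group's biomass total is conserved. The GEV nests Gumbel,
Fréchet and reversed-Weibull shapes, so a group's spectrum may be
left- or right-skewed — a flexibility that one-sided families
(lognormal, gamma, exponential) lack. The two-decade extension below
the reported minimum admits undetected small species and immature
stages; offspring are typically one to two orders of magnitude lighter
than adults.

The three free parameters are estimated by quantile matching:
minimizing the sum of squared differences between the truncated
distribution's 0.05th, 50th and 99.95th percentiles and the reported
log10 minimum, median and maximum. This places ≈99.9% of the group's
biomass inside the reported size range.

### Numerical details of the fit

The objective is smooth but weakly identified: because the 99.95th
percentile target coincides with the upper truncation bound, a shallow
valley of parameter triples reproduces the three quantiles almost
equally well (they differ in how much untruncated mass sits beyond the
window, i.e. in the shape of the density near the upper bound).
Consequences and choices:

- Optimization is a damped Gauss–Newton (Levenberg–Marquardt)
  iteration over `(μ, log σ, ξ)` with `ξ` bounded to [−5, 5] and `σ`
  floored at 1e-3 log units, run from a multistart grid (`ξ0 ∈ {0,
  ±0.5, ±1, ±2, ±0.1, ±4}`, `μ0` = reported log median, `σ0` =
  span/6). The iteration is vectorized over independent problems, so
  all bootstrap refits of a group are solved simultaneously; scipy's
  scalar `least_squares` on the same objective is the cross-check
  oracle in the test suite.
- A step that improves the SSQ by less than 1e-8 freezes that problem.
  This is the convergence criterion and also prevents solutions from
  crawling along the near-tie valley; residuals are resolved to about
  1e-4 log units, far below the data's precision.
- Near-ties in SSQ (at 1e-10 granularity) are broken toward the
  smallest |ξ|, i.e. the least extreme tail shape.
- Degenerate triples (median equal to the minimum, or spans below 0.1
  decade) are representable: they resolve to corner solutions (σ at
  the floor, |ξ| at the bound) that concentrate mass near the
  degenerate quantile. These are faithful to the inputs, and the
  spectrum builder conserves their biomass exactly (below).
- An alternative reading of the estimator — match the quantiles of the
  *untruncated* GEV, then truncate — is available as
  `FitConfig(quantile_basis="untruncated")`. It removes the upper-bound
  near-ties (the system becomes exactly identified) and yields lighter
  upper tails; the default remains the truncated reading.

## Uncertainty propagation (two-step bootstrap)

Per bootstrap replicate (default 1000) and group:

1. a new median-size target is drawn from the group's *initial* fitted
   distribution by inverse-CDF sampling (the initial fit is the
   uncertainty statement about where the median biomass sits), clipped
   to the reported [min, max] so the refit's quantile targets stay
   ordered;
2. a new biomass total is drawn as `B·10^z`, `z ~ Normal(0,
   (log10 λ / 1.96)²)` — the lognormal error model under which the 95%
   interval is `[B/λ, B·λ]`. `λ` is tabulated as a multiplicative
   fold factor, so the standard deviation lives on the log scale;
3. the distribution is refit with the min/max targets (and hence the
   truncation window) held at the catalog values.

Randomness uses one root seed with per-(replicate, group) substreams
(`numpy.random.SeedSequence` spawn keys), so results are independent of
iteration order and any cell is reproducible in isolation. A refit
whose SSQ exceeds 0.3 is retried — first with a full multistart on the
same draw, then with fresh draws from the same substream (at most five
times) — before the run aborts. Whether the original analysis redrew
biomass and median jointly or independently is unknowable from the
published description; they are drawn independently here.

## Spectrum assembly

Spectra live on a uniform grid of 1160 bin centers, 40 per log unit
over [−18, 11] log10 g C. A group's biomass density (Gt C per log10
size) is evaluated as an exact bin average — biomass mass between bin
edges (CDF differences) divided by the bin width — rather than a
point evaluation of the density. Bin averaging conserves each group's
total on the grid to machine precision even when a degenerate fit is
much narrower than a bin; only support extending below −18 (one group,
by 0.8 decades of near-empty tail) is clipped, with a logged notice.
Cumulative spectra sum the groups of a realm selection (all-realms,
terrestrial, marine); envelopes are pointwise 2.5th/50th/97.5th
bootstrap percentiles (numpy's linear-interpolation convention). Modes
are strict local maxima of the median curve; runs of exactly equal
values count once, at the run center.

## Regressions

Grid bins whose *per-bin total biomass* (density × 1/40) falls below
1e-5 Gt are discarded — the cutoff sits an order of magnitude below
the least massive group's lower biomass bound, and it bounds the log
transform. The regression response is log10 of the per-bin biomass, so
the smallest retained response value is exactly −5; slopes and R² are
identical to regressing log10 density with the equivalent 4e-4 density
cutoff (the two differ by the constant log10(40)).

- Power laws: ordinary least squares of response on log10 size, per
  replicate; the exponent β and R² are summarized as means ± SDs
  across replicates.
- Size–abundance spectra: the response is shifted by −x (abundance =
  biomass / mass), giving exponent α = β − 1 exactly per replicate.
  Normalized biomass (per one-decade class) differs from abundance by
  the analytic constant log10(10^0.5 − 10^−0.5) = 0.454, so its slope
  is identical to α.
- Gaussian mixtures: sums of 1–4 curves `a·exp(−((x−b)/c)²)` fit by
  bounded trust-region least squares with an analytic Jacobian. The
  response is shifted by +6 so its minimum possible value is 1,
  keeping amplitudes positive; R² and AICc are shift-invariant.
  Reference fits on the median curve use 10 multistarts (centers
  seeded from response-weighted quantiles of x) and are warm-chained
  so the n-component RSS never exceeds the (n−1)-component RSS;
  per-replicate fits warm-start from the median-curve fit plus two
  fresh starts.
- AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k counting curve
  parameters plus one error variance (k = 3 for the line, 3n+1 for an
  n-component mixture).

The regression points are the 40-per-decade grid samples and are
therefore serially dependent; fits are descriptive summaries of the
curves (as in the source analysis), not inferential models, and no
autocorrelation correction is applied.

## Sensitivity variants

Five labelled configurations rerun the whole pipeline: A (base,
truncation −2/+0), B (−1/+1), C (−0/+0), D (ramet body-size
definition) and E (metabolically active mass only, subterranean
microbes excluded). A–C share the packaged catalog; D and E require
user-supplied catalogs with the same schema, since ramet/active-mass
size values are not part of the packaged transcription. Across A–C the
integrated biomass per replicate is identical — truncation moves
biomass along the size axis, never changes its total. Sensitivity
drivers default to 200 replicates, which pins the bootstrap mean of β
to about ±0.001 at a fraction of the base run's cost.

## Synthetic worlds and what they show

`sizespectra.synthetic` builds catalogs from known truncated-GEV
ground truth: unimodal/bimodal worlds (equal-shape groups whose
density modes sit exactly at the stated locations, so the true
cumulative curve peaks there; the shape is the zero-skewness GEV,
ξ = −0.2776, so the bumps are symmetric and "mode center" is a
well-posed target for a Gaussian-curve fit) and power-law worlds
(Gumbel groups tiled every 0.5 decades with amplitudes growing as
`10^(slope·x)`, exponential in the tiled interior). Observed
min/median/max triples are read off the generating quantiles,
optionally perturbed by ±0.1 log units of observation noise; for
interval-coverage calibration the catalog's biomass entry is drawn
once from the fold-error model (`observe_biomass=True`), since
coverage of a noiseless observation is trivially ~100%. Recovery
experiments run the full pipeline on the derived catalog and compare:
bootstrap-mean spectrum slope against the closed-form truth (recovered
within ±0.02), two-component mixture centers against the construction
modes, and 95% bootstrap intervals for total biomass against the true
total (coverage lands near the nominal 95%).

These worlds match the *statistical structure the analysis assumes* —
truncated-GEV within-group spectra, lognormal biomass error, noiseless
quantile observation. Passing recovery therefore shows the pipeline is
a consistent estimator of its own model; it says nothing about whether
real within-group spectra are GEV-shaped, whether reported sizes are
unbiased, or whether group biomasses are spatially representative.

## Known limitations

- Three data points per group cannot identify a three-parameter
  density plus truncation: distinct tail shapes fit the quantiles
  equally well, and statistics sensitive to within-window shape (the
  biomass-scale R², the exact height of the large-size mode) inherit
  that ambiguity. Slopes and the abundance-scale R² are robust to it.
- The truncated-quantile estimator rewards mass piled against the
  upper truncation bound; in the base catalog this elevates the median
  spectrum near 10^9 g (the top of the plant ranges), adding a local
  maximum above the broad ~10^7 g biomass mode. The same mechanism
  shifts fitted Gaussian-mixture centers systematically to the right
  of the underlying density modes by roughly 0.4 within-group scale
  units, as the synthetic recovery experiments quantify.
- Fold uncertainties are taken at face value; correlations between
  groups' biomass errors are not modelled.
- The packaged catalog is a transcription of printed, rounded values;
  one table row (Molluscs) required swapping two evidently transposed
  entries to restore min ≤ median.
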