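# Methods

This note records the statistical model behind `ltdsm`, the defaults
and numerical choices, what the synthetic surveys do and do not
emulate, and the known limitations. It documents how results are
computed; every number quoted anywhere is produced by the test suite or
`scripts/acceptance.py` at run time.

## Detection model

Distances are one-sided perpendicular distances from the trackline,
right-truncated at w (default 1750 m, the conventional choice for
aerial fin whale work); there is no left truncation. Detection on the
line is assumed certain, g(0) = 1: no correction for availability
(submerged animals) or perception bias is applied, so all downstream
abundances are minimum estimates.

Keys:

* half-normal g(x) = exp(−x²/2σ²), optionally multiplied by an order-2
  cosine series 1 + a₂cos(2πx/w) and rescaled by its value at 0 so
  g(0) = 1 holds exactly;
* hazard-rate g(x) = 1 − exp(−(x/σ)^−b) with shape b > 1 and no
  adjustment.

Covariates enter only through the scale, log σᵢ = β₀ + βᵀzᵢ (the MCDS
convention): sea state as a continuous regressor, subjective sighting
conditions as an unordered three-level factor. The conditional
likelihood Π g(xᵢ|zᵢ)/μᵢ, μᵢ = ∫₀ʷ g(u|zᵢ)du, is maximised over
transformed parameters (log σ, log(b−1), raw cosine coefficient) by
L-BFGS-B from five deterministic perturbed starts; adjusted functions
that go negative anywhere on [0, w] are penalised and can never be
returned. The integral μ uses 64-node Gauss–Legendre quadrature, which
is exact to well below 10⁻⁹ relative for these integrands (the test
suite checks the half-normal esw against the closed form
σ√(π/2)·erf(w/(σ√2)) to 10⁻⁶ across σ from 100 m to 5 km).

Effective strip width is esw = ∫₀ʷ ĝ, pooled with equal weight over the
observed covariate values when covariates are present; p̄ = esw/w, and
the identity esw = p̄·w holds by construction to 10⁻⁹. Standard errors
come from the delta method on the inverse observed information
(central finite differences on the transformed scale).

Goodness of fit is the Cramér–von Mises statistic on uᵢ = F̂(xᵢ) with
the standard asymptotic null. The p-value deliberately ignores the
effect of parameter estimation; when parameters are re-estimated from
the same sample the test is therefore conservative (measured rejection
rate ≈ 0 at nominal 0.05), and its nominal calibration (measured 0.044)
applies when the tested parameters are fixed. Hazard-rate fits carry a
near-zero diagnostic (fitted probability mass in the first tenth of the
strip relative to the observed share) rather than being auto-excluded;
exclusion mirrors field practice of visual inspection and stays a
caller decision.

Group-size bias: larger groups stay detectable farther out, so the mean
of detected sizes is biased upward. ln(sᵢ) is regressed on ĝ(xᵢ); if
the slope is significant at α = 0.15 (the distance-sampling
convention; configurable), E[s] = exp(â + b̂ + MSE/2), the log-normal
back-transformed prediction at certain detection; otherwise the
arithmetic mean is used. Both are always reported.

## Segmentation and effective area

On-effort GPS runs are cut, per transect, into consecutive pieces of
exactly 5 km with a terminal remainder; remainders under 1 km are
discarded (logged, exact bookkeeping is tested). Segments never span an
off-effort gap. Lengths are summed projected chords; midpoints and
boundary times are interpolated along-track. Sightings attach to the
segment whose time span contains their recording time (fallback:
nearest midpoint within the transect's effort span); sightings beyond w
or outside all effort spans are excluded, the latter with a warning.
The covered area is one-sided, A_seg = esw × L_seg — the survey design
observes a single side of the line, so no factor of two appears
anywhere.

Coordinates come from a spherical Lambert azimuthal equal-area
projection centred on the data's bounding box; over a few hundred km
the equal-area property keeps lengths and cell areas faithful, and the
projection is exposed in the I/O layer so a different centre can be
supplied.

## Terrain covariates

From a depth grid (negative below sea level, used as-is): TPI (centre
minus mean of the eight neighbours), TRI (mean absolute difference to
the eight neighbours), and Horn's slope/aspect, all on the 3×3
neighbourhood with edge cells set to no-data. Aspect is degrees
clockwise from north of the downslope direction and is no-data on flat
cells; it is treated as a plain (non-circular) covariate by the model,
a documented caveat. Distances to the shelf break and coastline are
planar Euclidean distances to shapely polylines. Segment covariates are
sampled every 0.5 km along the segment chord (bilinear interpolation
for grids, no-data samples excluded) and averaged; a segment whose
samples are all no-data gets a missing covariate and is dropped from
models that need it, with a warning. Rasters are stored as plain-text
ESRI ASCII grids.

## Density surface model

Per-segment group counts (groups, not individuals — individuals enter
only at prediction) follow

  n_seg ~ Tweedie(μ_seg, p, φ), log μ_seg = log A_seg + β₀ + Σⱼ fⱼ

with 1 < p < 2, so the law is compound Poisson–gamma: a point mass at
zero plus a continuous positive part, matching zero-heavy segment
counts. Each fⱼ is a thin-plate regression spline (Wood's low-rank
eigen-truncation of the radial basis, null-space polynomials appended,
sum-to-zero centring for identifiability); defaults k = 30 for the
spatial smooth s(x, y) and k = 10 for 1-D terms, both configurable.

Fitting is penalised IRLS with step-halving. One smoothing parameter
per term is chosen by coordinate-wise golden-section search (log₁₀λ in
[−5, 7], deterministic) minimising GCV = nD/(n − edf)² on the deviance
scale with edf = tr[(XᵀWX + S)⁻¹XᵀWX]. The Tweedie power is profiled
over the grid 1.05…1.95 (step 0.05) maximising the exact series
log-likelihood, with λ re-selected at the chosen power; φ is the
Pearson estimator. The series log-density is summed in log space
around its dominant term to 10⁻¹² relative — it matches an independent
implementation (mgcv's `ldTweedie`) to six decimals, and the fitted
surfaces agree with mgcv's thin-plate Tweedie GAM to correlation
> 0.99 on shared data (tested via Rscript). AIC is −2·loglik +
2(edf + 1), the +1 counting the dispersion. The coefficient covariance
is the Bayesian posterior form (XᵀWX + S)⁻¹φ.

Model ranking is by AIC with GCV, pseudo-R² and percent deviance
explained reported; when models sit within 2 AIC units of the best the
one with fewer covariates is selected. One caveat found while
validating: adding a pure-noise smooth lowers GCV by chance in roughly
a quarter of replicates, because the smooth's linear null space is
unpenalised — GCV shrinkage cannot remove that last degree of freedom.

## Prediction and abundance

Predictions go onto 2.5 × 2.5 km cell centres: μ_cell =
exp(η̂ + log 6.25), SE_μ = μ·SE_η (delta method), CV = 100·SE/μ. Cells
with CV ≥ 100 % are discarded before any totals — outside the
data-supported region the smooth extrapolates freely and its CV
explodes, so the mask bounds the prediction area. Totals over retained
cells use the full coefficient covariance, Var(N) = gᵀV g with
g = Σ μ_c x_c, keeping between-cell correlation. Individuals are
groups × E[s]; the default 95 % CI is N ± 1.96·SE from the model's SE
alone (detection-function and group-size uncertainty are not
propagated; a log-normal CI is available as an option). Sub-region
estimates select cells by centre-in-polygon and are exactly additive
over partitions.

## Synthetic surveys

The simulator generates what the estimator assumes: an inhomogeneous
Poisson group process over a log-linear intensity in smooth synthetic
covariates (optional Gaussian-random-field noise, optional cluster
process mimicking feeding aggregations of 15+ animals), zero-truncated
Poisson or geometric group sizes, randomly anchored and oriented
transects clipped to the domain, effort fixes at 0.5-km spacing, and
one-sided half-normal (or hazard-rate) detection with covariate-scaled
σ and right truncation. Defaults emulate a realistic aerial campaign:
a 160 × 120 km domain, ≈ 2000–3000 km of effort over 40 transects,
baseline density 0.04 groups/km² with a bank-shaped hotspot, σ = 600 m,
w = 1750 m, zt-Poisson(0.6) sizes (mean ≈ 1.33) — yielding on the order
of 100 sightings per survey. The Poisson draw discretises the intensity
on a 1-km lattice (piecewise-constant), and a group detected from
several transects is recorded once, at its nearest detection.

Not emulated: animal movement and responsive movement during the
survey, availability/perception processes (g(0) = 1 by construction),
measurement error in angles and group sizes, and real bathymetry.
Passing recovery tests therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to their violation
in field data.

## Validation scale

The replicate experiments run at desk scale on one CPU: detection
recovery over 100–200 surveys of n ≈ 300 distances, CvM calibration
over 300–500 replicates of n = 100, and the end-to-end bias/coverage
experiment over 60–100 full pipeline runs with a single spatial smooth
(k = 20) per run; these sizes give Monte-Carlo standard errors
comfortably inside the asserted bands.

## Known limitations

* Abundance is a minimum estimate: no availability/perception-bias
  correction (none was possible for the motivating survey design).
* The CI carries only the spatial model's uncertainty; a bootstrap
  combining detection, group-size and model variance is a natural
  extension but is not the default.
* GCV (not REML) smoothness selection; no spatial autocorrelation
  beyond what the smooth absorbs; no tensor or soap-film smooths.
* The CvM p-value is approximate whenever parameters were estimated
  from the tested sample (conservative in that case).
* Aspect is treated as a linear covariate despite being circular.
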