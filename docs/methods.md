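# Methods

`forestagb` estimates plot-level aboveground biomass (AGB, Mg ha⁻¹) and
its uncertainty from forest-management inventory data — the binned,
right-censored, partially sampled tree records collected by timber
concessions — and aggregates the estimates to pixels with a variance
decomposition. This note documents the models, the error-propagation
scheme, the synthetic-data generator used to test it, and the numerical
and design choices that were genuinely open.

## The estimation problem

Research-grade ("scientific") inventories measure a continuous diameter
at breast height (DBH ≥ 10 cm) for every stem. Management inventories
instead record stems in 10-cm DBH classes, pool all trees above an
opening threshold (120–200 cm) into a single open class, census only
trees above 10 or 20 cm, and sample the smallest classes on a fraction
*p* (12.5–100%) of the plot area. Tree-level allometry needs continuous
diameters and complete tree lists, so three standardisation steps bridge
the gap, each contributing an error source that is propagated by Monte
Carlo (1000 iterations per plot by default):

1. **Small-tree expansion.** A class observed with count *r* on a
   fraction *p* of the plot is expanded to the whole plot by drawing
   X ~ NegBin(r, p) — the number of failures before the *r*-th success
   at success probability *p* — and using r + X trees. This is exactly
   the Bayesian inverse of binomial thinning with retention *p*
   (E[r + X] = r/p), so expansion is unbiased for the pre-thinning
   count. Simulated trees receive taxa multinomially, pro rata of the
   composition observed in the sampled fraction (falling back to the
   whole-plot composition if a class has no observed trees).
2. **Diameter assignment.** Continuous diameters are drawn from a
   parametric size distribution conditioned on the class bounds by
   inverse-transform sampling, D = F⁻¹(F(lo) + u·(F(hi) − F(lo))). The
   default distribution is a two-parameter Weibull (scale λ = 8.593,
   shape k = 0.737) on the truncated support [10, 400] cm, the open
   class being bounded by D_max = 400 cm. The distribution family
   (Weibull / exponential / gamma), its parameters, D_min and D_max are
   all configurable; `fit_dbh_model` refits all (family, D_max)
   candidates to binned, censored counts by multinomial maximum
   likelihood and ranks them by AIC with Akaike weights.
3. **AGB₁₀₋₂₀ correction.** Where the 10–20 cm class was never sampled,
   its per-hectare biomass is predicted from a linear model
   AGB₁₀₋₂₀ = a + b·AGB₌₂₀ + c·S + d·I + ε, where S and I are the slope
   and intercept of an OLS line through the plot's cumulated biomass at
   the class upper bounds x ∈ {30, 40, 50, 60, 70} cm (cumulating from
   20 cm), and ε ~ N(0, ε²) with ε the residual standard error of the
   calibration fit. Coefficients are calibrated by OLS on plots where the
   class *was* sampled; predictions are floored at zero.

## Allometry and error sources

Tree AGB uses the pantropical power law AGB(kg) = α·(ρ·D²·H)^β with
defaults α = 0.0673, β = 0.976 and a log-scale residual sd of 0.357,
wood density ρ (g cm⁻³) resolved from a reference table at the finest
available taxonomic level, and height from the asymptotic model
H = a_H·(1 − exp(−b_H·D^c_H)) with the central-Africa parametrisation
(a_H = 50.453, b_H = 0.0471, c_H = 0.8120). None of these constants is
hard-coded in an operation; all live in configuration.

Per Monte Carlo iteration the engine draws, independently per tree,
wood density from Normal(mean, sd) truncated to the physical range
[0.08, 1.39] g cm⁻³ and an additive height residual N(0, σ_H) (heights
floored at breast height, 1.3 m); and, shared across all trees of the
iteration, a perturbation of the AGB-model coefficients
(α, β) → (α(1 + cz₁), β(1 + cz₂)) with z ~ N(0, 1) and relative sd
c = `coef_rel_sd`, plus an independent per-tree log-normal residual
exp(N(0, 0.357)). The shared/independent split matters: per-tree errors
average out with tree count (plot CV ∝ 1/√N), while the shared
coefficient draw does not, which is what puts a floor of several percent
under plot-level uncertainty regardless of plot size.

Parameter defaults and units:

| parameter | meaning | default | unit |
|---|---|---|---|
| λ, k | size-distribution scale/shape | 8.593, 0.737 | cm, – |
| D_min, D_max | truncation bounds | 10, 400 | cm |
| a_H, b_H, c_H | height model | 50.453, 0.0471, 0.8120 | m, –, – |
| σ_H | height residual sd | 5.0 | m |
| α, β | AGB power law | 0.0673, 0.976 | –, – |
| σ_ln | AGB residual sd (log scale) | 0.357 | – |
| coef_rel_sd | shared coefficient-draw sd | 0.0045 | relative |
| n_iter | Monte Carlo iterations | 1000 | – |

σ_H is not part of the published height model's printed constants; 5.0 m
is a representative residual SE for regional asymptotic H–D fits.
`coef_rel_sd` is a calibration constant by construction: it encapsulates
the (strongly correlated) posterior spread of the AGB-model coefficients
in a single relative sd, and its default was chosen so that the
classical-error plot CV (wood density + height + AGB model) on default
synthetic stands falls at the uncertainty level reported for research
plots in this forest domain (mean ≈ 8.3%, 95% range 5.2–13.1%); the
measured value with the default is ≈ 8.4%. A relative sd of 0.45% on β
translates, through E[ln(ρD²H)] ≈ 10.5, into a shared plot-level CV of
≈ 5%, which combines with the per-tree sources to the observed total.

### Within-class quantile stratification

For the trees recorded in one diameter class, the engine by default
*stratifies* the assignment quantiles: the n trees of a class receive
one uniform offset each inside the n equal-probability strata of the
class, with a fresh random permutation of strata over trees per
iteration. Each tree's marginal distribution is exactly the
class-conditional distribution (so all distributional checks — KS,
conditional means — are unchanged), but the class *total* varies far
less than under iid draws, whose variance floor (≈ 1.4% plot CV from
closed classes alone on a default stand, dominated by the many small- to
mid-diameter trees) is incompatible with the sub-percent
assignment-only uncertainty reported for well-censored inventories.
Stratification reproduces that regime (≈ 0.8% on default stands, almost
entirely from sparse large classes and the open class). The flag
`stratified_assignment` restores iid draws when disabled; the low-level
`assign_diameter` API is always iid. With assignment error toggled off,
trees take deterministic stratified midpoints ((i + ½)/n), so a run with
all error sources off is fully deterministic.

## The Monte Carlo engine

`PlotAGBModel(inventory, …).fit(n_iter, seed)` runs the chain per
iteration: expansion (NegBin) → taxon assignment → diameter assignment →
error draws → tree AGB → plot AGB; when the 10–20 cm class is absent, S
and I are recomputed on each iteration's realised tree set and the
correction model's prediction (with its ε-draw, when toggled) is added.
Each error source can be toggled individually (`ErrorToggles`), which is
how the per-source validation decomposition is produced. With every
source off, expansion uses the expected count r + round(r(1−p)/p) and
assignment the stratified midpoints, so the Monte Carlo variance is
exactly zero. Iterations producing non-finite AGB would be redrawn and
counted (none arise under the default models).

Seed discipline: a master seed feeds `numpy` `SeedSequence` substreams —
per plot keyed by (master seed, CRC32 of the plot id), per stage by named
spawn — so batch results are independent of execution order and worker
count.

`PlotAGBResults` carries the mean, variance, CV (= 100·√var/mean), the
AGB₁₀₋₂₀ / AGB₌₂₀ components, and a `summary()` table.

## Pixel aggregation

Plot estimates are grouped into square pixels (1 km, World Mercator
EPSG:3395, half-open extents, index = floor((coord − origin)/size)).
Per pixel, with plot areas wᵢ as weights:

* mean AGB = Σwᵢmᵢ/Σwᵢ;
* **intra-plot (estimation) variance** = Σwᵢvᵢ/Σwᵢ, the weighted mean of
  the plots' Monte Carlo variances;
* **inter-plot (sampling) variance** = Σwᵢ(mᵢ−m̄)²·Σwᵢ/((Σwᵢ)²−Σwᵢ²),
  the unbiased reliability-weighted variance of plot means (population
  form available via a flag; exactly zero for a single plot);
* total CV = 100·√(intra+inter)/mean; mean date is area-weighted like
  the AGB (the weighting of the date layer is a package choice — an
  unweighted mean would differ negligibly for near-simultaneous plots).

The raster export is a 5-band float64 GeoTIFF (band order: mean AGB,
plot count, mean date, inter-plot variance, intra-plot variance; nodata
−9999), written via `tifffile` with explicit GeoTIFF tags (pixel scale,
tiepoint at the raster's NW corner, EPSG code, GDAL nodata).

## Synthetic stands: what they emulate, and what they do not

The generator produces reference plots with known ground truth so the
whole chain is testable without restricted field data. Defaults define
the study conditions: 0.5-ha plots (the dominant management-plot size),
500 stems ha⁻¹ at DBH ≥ 10 cm (a typical density for the region's moist
forests; configurable), diameters iid from the default truncated
Weibull, taxa from a 50-taxon pool with geometrically decaying
abundances (ratio 0.97, a log-series-like dominance structure), taxon
wood densities from Normal(0.62, 0.12) truncated to [0.2, 1.0] g cm⁻³
with a within-taxon sd of 0.07, and uniform tree positions in a square
plot. Degradation operators mirror the information losses of management
data: floor(D/10)·10 binning, open-class pooling, per-tree binomial
thinning at the class sampling fraction (the exact inverse of the NegBin
expansion), and removal of classes below the census threshold. Named
scenario presets (`best`, `worst`, `dbh_200`, `dbh_120`, `nexp_light`,
`nexp_heavy`, `agb_cor`) encode the bracketing situations found in
commercial data.

Features of real data the generator does *not* emulate, and the
corresponding limits of what passing tests show:

* **Size-distribution tail.** Real research plots hold roughly an order
  of magnitude fewer ≥ 200 cm giants than the fitted Weibull tail
  implies (P(D ≥ 200 | D ≥ 10) ≈ 3.7·10⁻⁴ here). Assignment-only
  uncertainty with a 200-cm open class is therefore ≈ 0.8% on synthetic
  stands versus ≈ 0.4% reported on field data — the ~9% of synthetic
  plots containing a giant dominate the mean.
* **Between-plot structural heterogeneity.** All synthetic plots share
  one size distribution and taxon pool, so the AGB₁₀₋₂₀ correction model
  calibrates with a small residual ε; on real data the correction is a
  much larger error source (≈ 6% CV). The worst-case combined CV on
  synthetic stands (≈ 11%) is correspondingly below the ≈ 15% field
  value while remaining inside its reported 95% range (9.8–23.3).
* **Spatial clustering.** Tree positions are uniform; real stems
  aggregate, which slightly biases small-tree expansion on real data
  (reported slope 0.97) but not here.

## Validation design

`run_degradation_experiment` computes, per plot, a reference AGB (the
Monte Carlo mean under the classical sources WD + H + AGB on the
undegraded plot), degrades the plot under a scenario, re-estimates with
a chosen source set, and reports the across-plot mean CV with its
2.5–97.5 percentile interval plus a major-axis (MA) regression of
estimated versus reference plot means. The MA slope — the first
principal axis of the centred scatter, equivalently the line minimising
perpendicular distances — is the bias measure; its 95% CI is a
percentile bootstrap over plots (1000 resamples; the CI method is a
package choice). `decompose_error_sources` tabulates one row per
(scenario, source) pair; `standard_validation_summary` bundles the
headline quantities (classical CV, best/worst-case CV, assignment-only
and expansion-only CVs, the 10–20 cm AGB share, and the assignment MA
slope) and is what `scripts/acceptance.py` runs at 200 plots × 1000
iterations (500 plots for the AGB share; sizes chosen to make the
across-plot means stable to well under their seed-to-seed spread).

## Numerical choices and degenerate inputs

* Censored-binned MLE: Nelder–Mead on log-parameters from two starts;
  a candidate whose open class lies above D_max is skipped; fewer than
  two occupied histogram cells raises a no-fit error (unidentifiable).
* "Weighted AIC" is implemented as minimum-AIC selection with Akaike
  weights reported over the candidate set. The default assignment family
  is the Weibull; the family is a parameter because the better-fitting
  family is data-dependent.
* The size distribution is defined on raw DBH truncated to
  [D_min, D_max]; every use is conditional on a class, which makes the
  support convention nearly inert. It is config-exposed regardless.
* Empty inventories yield a flagged zero estimate rather than an error;
  a management inventory lacking the 10–20 cm class without a correction
  model is rejected at model construction.
* MA regression with zero covariance and equal axis variances has no
  defined slope and raises; bootstrap resamples that hit this
  degeneracy are skipped.
* CV is reported as 0 for a zero-mean (empty) estimate; otherwise the
  identity CV = 100·√var/mean holds to floating point on every output.

## Known limitations

* The correction model's ε on synthetic calibration understates the real
  between-plot heterogeneity (see above); applications to real data
  should recalibrate on plots where the 10–20 cm class was sampled.
* Reported pixel sampling variance assumes plots are independent within
  a pixel; transect-based sampling designs violate this mildly.
* The height model is deterministic given DBH plus a noise term; site
  effects on the H–D relation are not modelled.
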