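# Methods

This note documents the models, numerical choices and limitations behind
`trawldiv`.  The package computes four biodiversity indicators from
bottom-trawl survey data, standardizes them for effort, attributes their
spatial patterns to drivers, and classifies community-assembly processes
with a randomization null model; a synthetic survey generator with
labelled ground truth validates the whole stack.

## Survey preparation

Haul records arrive long-format (one row per haul × species × length
class; CPUE in individuals per hour).  The inclusion filters reproduce
standard survey practice: haul duration within 27–33 min (the 30-minute
standard ± 10%, bounds inclusive), depth ≥ 20 m (excludes coastal and
estuarine hauls), sites sampled in at least 80% of the survey years, and
species present in at least 20% of years.  The year thresholds
generalize as `ceil(fraction × years)` — for a 32-year series this gives
26 and 7 years respectively, and the `Fraction`-based ceiling guards
against float fuzz (0.8 × 10 must be 8, not 9).  Filters are
idempotent, and the two row-wise haul predicates commute.

CPUE-at-length is converted to biomass with `W = a·L^b` (a in g·cm⁻ᵇ)
and summed over length classes per haul × species.  The site-year cell
value is the **mean** biomass per hour across the cell's hauls (absent
species contribute zero), not the sum: means keep cells comparable
across unequal effort before the explicit effort standardization, and
the haul count per cell is retained for that step.  Species presence is
`biomass > 0` with no minimum abundance, and the species-occurrence
filter runs after site filtering.

Covariate derivation follows the conventions for temperate shelf seas:
winter = Dec–Feb, summer = Jun–Aug, seasonality = summer − winter
(positive in these systems; the sign convention is ours), salinity
variability = per-year (max − min) averaged over years, substrate
richness = categories with positive coverage (1–6), substrate evenness =
Pielou evenness of the coverage fractions.  Sparse observation fields
(e.g. a plankton color index) are interpolated to site centroids with a
tensor-product cubic B-spline surface in (lat, lon), interior knots at
coordinate quantiles (capped so the basis stays smaller than the
sample), fitted by least squares; prediction coordinates are clipped to
the observed range.  The basis nests constants and planes, so those are
reproduced exactly.

## Trait space

Eight traits describe each species: four continuous (asymptotic body
size, age at maturity, fecundity, egg size) and four categorical (body
shape, diet, spawning behavior, caudal fin shape with 5/5/6/6 levels).
The Gower dissimilarity averages per-trait contributions —
`|xᵢ−xⱼ|/range` for continuous, 0/1 mismatch for categorical — with
equal weights by default (none are given a priori).  Continuous traits
are log-transformed before range-normalization because body size and
fecundity span orders of magnitude; this is configurable.  A zero-range
continuous trait is excluded with a warning rather than dividing by
zero.

Principal coordinates analysis double-centers `−½D²` and
eigen-decomposes.  Gower dissimilarities with categorical mismatch terms
are strongly non-Euclidean (negative eigenvalues carry 10–20% of total
magnitude on representative pools), so a correction is needed; the
default is the square-root transform, which is exactly Euclidean for
Gower-type dissimilarities, preserves rank order, and yields a clean
testable contract (the embedding reproduces √Gower to machine
precision).  Cailliez and Lingoes constants are available behind the
same interface.

The working dimensionality is `m = min(m_max, s_min − 1)` with
`m_max = 4` by default, where `s_min` is the poorest community entering
the trait-richness computation — a convex hull in m dimensions needs
m + 1 affinely independent points.  Hull volumes, spanning trees and the
pool hull are all computed in this one shared m-axis basis, so community
and pool volumes are commensurable.  `m_max = 4` keeps hulls defined for
communities of ≥ 5 species while retaining most embedded variance.

## Indicators

SRic counts species with positive biomass.  SEve is Pielou's
`J = −Σp ln p / ln S`, undefined (NaN) at S = 1.  TRic is the community
hull volume divided by the pool hull volume (presence-only; biomass
enters only as a mask), undefined for S ≤ m or affinely dependent
coordinates — degenerate hulls are flagged NaN, never joggled.  TEve
follows the abundance-weighted MST construction (branch length over
summed endpoint biomass, normalized, truncated at the regular share
1/(S−1)); undefined below 3 species.  Undefined values are carried as
flagged NaN and excluded from means, because silently dropping poor
communities would bias spatial averages.  MST edges are computed on
Euclidean distances in the shared m-axis space with species in
lexicographic order, making tie-breaking deterministic.

Effort standardization fits `indicator ~ smooth(n_hauls)` with the 3-df
engine below and replaces values by `grand mean + residual`.  Residuals
of a least-squares fit are exactly orthogonal to the haul-count basis,
so standardized values are linearly uncorrelated with effort, and adding
back the grand mean keeps the indicator's units and level interpretable.
With constant haul counts the transform is the identity (with a notice).

## Smooth-model engine, trends and variable importance

All regressions use Gaussian errors and per-covariate smooth terms
restricted to three degrees of freedom — equivalent to a second-degree
polynomial, which is how the engine realizes them: a centered basis
`[x − x̄, (x − x̄)² − c]` per term, fitted by ordinary least squares.
This makes every fit exact, auditable against polynomial regression, and
dependency-light; a penalized-spline backend would report slightly
different effective dfs and F statistics but the same substance.  AIC
uses the profile Gaussian likelihood with total df = intercept + 2 per
term + variance.  Near-duplicate covariates (|r| > 0.999) are rejected
by name.

Temporal trends fit `indicator ~ smooth(year)` and test against the
intercept-only model with an exact F(2, n−3) test; residual lag-1
autocorrelation is reported as a diagnostic only, never auto-corrected
(none is expected for annual-mean series of this kind, but the number is
there to check).  Per-site trends are ordinary least-squares slopes with
two-sided p-values, flagged (not dropped) below 5 years.

Relative variable importance fits **every** subset of ≤ 12 candidate
covariates (2¹² model cap), converts AICs to Akaike weights and sums the
weights of models containing each covariate.  Two analysis profiles
mirror common practice: natural drivers only, and natural + fishing
effort.  Relationship shapes (positive / negative / unimodal) are read
from the fitted term of the **full** model (configurable), evaluated on
a grid over the observed covariate range, and reported only when
RVI ≥ 0.6; an interior minimum classifies as "none".

## Null model

The site × species presence matrix (by default the across-year union of
presences per site; a single-year mode is available, since either
reading is defensible) is randomized by the curveball algorithm:
repeated trades between random site pairs that reshuffle the species
unique to each site, preserving both row and column sums exactly and
sampling the fixed-fixed ensemble uniformly.  Each of the `n_perm`
(default 999) permutations runs an independently seeded chain of
5 × (filled cells) trades from the observed matrix, so permutations are
exchangeable and the whole computation is reproducible from one seed.

Per site, the observed TRic is ranked within its simulated distribution
using the mid-rank of the pooled sample:
`q = (#below + ties/2 + ½)/(n_perm + 1)`.  This convention is symmetric
(mean ½ under exchangeability) and places a value lying exactly at the
k/(n+1) plotting position of the simulations exactly at that quantile,
so the inclusive-IQR class boundaries are sharp.  Classes: q < 0.025
significantly underdispersed, < 0.25 underdispersed (environmental
filtering), 0.25–0.75 neither, ≤ 0.975 overdispersed (limiting
similarity), above that significantly overdispersed.  The residual is
observed − mean(simulated), a standardized-effect-size-style centering.
Percentile bands (2.5/25/75/97.5) of the simulated TRic are smoothed
against species richness with the 3-df engine for plotting against
observed values.

## Synthetic ground truth

The generator emulates a quarter-one bottom-trawl survey: a species pool
(default 77 species), a site grid with smooth environmental gradients
plus Gaussian noise (default 119 sites × 32 years), communities
assembled under a labelled process, and haul-level CPUE-at-length
records.

Species are organized along a latent fast–slow niche axis with **guild
structure**: ten guild centers at evenly spaced normal quantiles,
membership probability proportional to the normal density (so extreme
trait syndromes are rare, as with elasmobranchs in real pools), and
within-guild scatter of 0.25.  Continuous traits are log-normal with
loadings 0.85/0.85/0.70/−0.60 on the axis; categorical levels are drawn
from kernels centered on the species' axis position (assortment 2.0).
The guild design matters: convex-hull trait richness is a range
statistic, and in a unimodal pool it responds only weakly to either
filtering or limiting similarity.  Each species also gets length–weight
coefficients (b ∈ [2.8, 3.2]), an environmental optimum (axis position +
noise 0.15) and a niche breadth (log-normal around 0.5 on the
standardized environmental axis).

Assembly per site: **neutral** draws species uniformly; **filtering**
weights species by `exp(−(env − optimum)²/(2·breadth²))^strength`;
**limiting** assembles sequentially, rejecting candidates whose minimum
Gower distance to residents falls below a pool-distance quantile that
increases with strength (capped at 0.85), with up to 20 random-order
restarts because a greedy maximal packing can stall below the maximum.
Strength 0 reduces every process to neutral.  Biomasses follow a
geometric series with dominance parameter d (Pielou evenness strictly
decreasing in d), randomly ranked, perturbed per year by mean-one
log-normal noise and thinned by a presence probability.  Hauls per
site-year are `1 + Poisson(mean − 1)` (mean 2 ⇒ essentially all cells in
the observed 1–11 range); durations Normal(30, 2) min; per-species CPUE
is the community biomass divided by the expected weight per individual
over the species' log-normal length distribution, spread over 1-cm
classes and scaled by a mean-one log-normal haul effect — so the
expected biomass recovered through `W = a·L^b` equals the community
biomass exactly, and the sample mean converges to it as hauls grow.

What the generator does **not** emulate: spatial autocorrelation beyond
smooth gradients, within-rectangle haul placement (hauls are
exchangeable replicates), multi-quarter seasonality, species range
shifts over time, and observation errors such as misidentification.
Passing recovery tests therefore shows the estimators work when their
assumptions hold; it does not certify them against these real-data
complications.

## Validation experiments and problem sizes

`trawldiv.experiments` defines the standard studies (sizes chosen for
stable rates on one CPU):

- **Neutral calibration** — 500 neutral sites, 199 permutations.  Under
  uniform sampling with fixed richness, every matrix with the observed
  row sums is equally likely, so conditioning on both marginals makes
  observed and randomized matrices exchangeable: quantiles should be
  uniform and ~5% of sites should fall outside the central 95% band.
- **Process recovery** — 200 sites per scenario, 199 permutations.
  "Strong" settings: filtering strength 20 (effective niche breadth
  ≈ breadth/√20), limiting strength 1.2 (threshold at the ~0.57 pool
  distance quantile, near the packing limit for 6–9 species), both with
  m = 4 and no presence thinning.
- **Driver recovery** — 50 replicates of n = 300 with five independent
  standard-normal candidates and one true linear driver at effect/noise
  sd ratio 2.  The true driver is expected at RVI ≈ 1.  A spurious
  2-df smooth term exceeds RVI 0.6 when its likelihood-ratio
  improvement beats 4 + 2·ln 1.5 ≈ 4.81, which happens with probability
  `P(χ²₂ > 4.81) ≈ 0.09` per driver-replicate regardless of
  implementation — so the meaningful contract, and the one tested, is
  that each null driver stays below 0.6 in ≥ 90% of driver-replicates,
  not that all four do so jointly in 90% of replicates.

## Known limitations

- Smooth terms are quadratic: genuinely sigmoidal or multimodal
  driver-response shapes are approximated by their best quadratic.
- The F statistics and effective dfs are those of the fixed quadratic
  basis, not of a penalized-spline backend; comparisons across software
  should be qualitative.
- TRic in m = 4 needs ≥ 5 species; very poor communities are flagged
  undefined and excluded from null-model classification.
- The curveball chain length (5 × fill) is a convergence heuristic; it
  passes the neutral-calibration check, but extremely structured
  matrices may need longer chains.
- The null model conditions on the observed marginals; processes that
  act through prevalence itself are invisible to it.
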