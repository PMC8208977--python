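# Methods

`elemove` analyses hourly GPS telemetry of African forest elephants
(*Loxodonta cyclotis*) — or any similarly sampled large mammal — at the
landscape scale.  It derives five movement behaviors per individual per
time step (monthly and annual), segments movement into behavioral states
with a hidden Markov model, and partitions behavioral (co)variation with
Bayesian hierarchical models to yield covariate effects, repeatability,
among-individual correlations and behavioral-syndrome axes.  Because no
suitable tracking dataset is publicly deposited, the package ships a
synthetic-population generator with full ground truth; every statistical
routine is validated by recovering what that generator planted.

## Track cleaning

Fixes are taken at 1-hour intervals.  Cleaning applies a sequential speed
filter: a fix is dropped when the straight-line speed from the most recent
*retained* fix exceeds 7 km/h, so a single erroneous spike does not shadow
the valid fixes that follow it (a pairwise filter would drop both
neighbours of a spike).  The first fix is always kept and the filter is
idempotent.  Trajectories are then split into *bursts* — maximal runs with
inter-fix gaps of at most 2 h, the resolution at which hourly collars are
effectively regular — and no step length or turning angle is ever
constructed across a burst boundary.  A regularity report (fractions of
gaps within 2 h and 3 h, per individual and pooled) diagnoses systematic
fix loss.

Coordinates are planar metres throughout.  Longitude/latitude input is
projected once through a spherical transverse Mercator centred on the data
centroid (or a user-supplied centre); all distances and areas downstream
are Euclidean.  At the sub-degree extents typical of a national tracking
program the spherical approximation errs well below the GPS error budget.

## Movement HMM

Each step (displacement between consecutive within-burst fixes) carries a
length and, from the second step of a burst, a signed turning angle.  The
two-state model assigns each step to *encamped* (short steps, weak
directional persistence: resting/foraging) or *exploratory* (long,
directionally persistent steps: transit).  Emissions are

* step length ~ Gamma(mu_s, sigma_s), parametrised by mean and SD and
  converted to shape/scale internally; an optional discrete mass pi0_s
  absorbs exactly-zero steps, where the gamma density is undefined (the
  mass is estimated only when zeros occur in the data);
* turning angle ~ von Mises(m_s, kappa_s), with kappa = 0 handled exactly
  as the circular uniform; missing angles contribute likelihood factor 1.

The transition matrix is free; the initial distribution is fixed at its
stationary law (one fewer parameter, standard practice).  Bursts are
independent realisations, so the likelihood is a product over bursts.

One model is fitted to the pooled steps of all individuals — the states of
every animal are then defined on a single common scale — via numerical
maximisation of the exact forward log-likelihood over unconstrained
transforms (log for mu, sigma, kappa; logit for transition rows and zero
masses; the angle mean through an atan2 wrap of an unconstrained
parameter).  Ten L-BFGS restarts from multiplicatively perturbed
moment-based starts guard against local optima, and the state labels are
resolved after fitting by the rule "exploratory = larger mean step", which
makes the output invariant to permutations of the start values.  Decoding
uses the exact Viterbi recursion per burst, ties resolved toward encamped.
Both recursions are verified against brute-force enumeration over all 2^n
paths for short series, and the fit recovers well-separated generating
parameters (means 100 vs 1000 m, SDs 80 vs 600 m, concentrations 0.5 vs 2,
transition diagonal 0.9) to within 5% from 20,000 steps with at least 95%
decoding accuracy.

## Five behaviors

For each individual and time step (calendar month or calendar year):

* **movement distance** — sum of within-burst consecutive-fix Euclidean
  displacements, in km.  Steps are assigned to windows by their start
  time, so monthly distances sum exactly to the annual distance on
  gap-free data.
* **home range** — area of the 95% isopleth of a bivariate-normal kernel
  density estimate, in km².  The density is evaluated on a 250-m lattice
  aligned to absolute coordinate multiples and padded 3h beyond the point
  bounding box; the isopleth region is the smallest set of
  highest-density cells reaching 95% of the mass.  The bandwidth h is
  *fixed per temporal scale* as the mean of the per-window reference
  bandwidths h_ref = sqrt((var_x + var_y)/2) * n^(-1/6), and can be
  overridden by configuration (e.g. to externally fixed values such as 1220 m
  annual / 920 m monthly) so that ranges are comparable across windows.
  The 250-m cell keeps discretisation error far below 10% at
  kilometre-scale bandwidths; both cell size and padding are
  configurable.
* **site fidelity** — area of the intersection of the current and
  preceding 95% regions divided by the preceding region's area (an
  intersection-over-union option exists).  Because all ranges of an
  individual live on the same absolute lattice, the overlap is an exact
  cell-set intersection.  Fidelity is undefined at a window with no
  immediately preceding retained window.
* **diurnality** — per local-clock day, (daytime distance − nighttime
  distance) / total distance with daytime = [06:00, 18:00), averaged over
  days with nonzero movement; +1 is exclusively diurnal and −1
  exclusively nocturnal.  Steps are assigned day/night by their start
  fix; at hourly sampling at most the single boundary step of a
  transition can be misassigned (a midpoint rule is available).
* **exploratory behavior** — the fraction of Viterbi-decoded steps in the
  exploratory state.

Inclusion rules: a monthly record requires at least 50% of the month's
hours to hold a fix (no completeness rule is standard; the threshold is
configurable and every exclusion is logged with its reason); an annual
record requires every month of the calendar year to meet that bar.

## Covariates

Rasters share the planar frame of the tracks: a static human footprint
index (HFI) and temperature seasonality (per-cell population SD of the 12
monthly mean temperatures), plus monthly rainfall and monthly NDVI.
Missing NDVI cells (cloud) inherit the previous month's filled value;
leading gaps stay missing; the annual NDVI is the per-cell mean of the
filled months.  Each behavior record is paired with the mean raster value
over cells whose centres fall inside that window's 95% home range —
monthly records with their month's rainfall/NDVI layer, annual records
with the annual layers.  Before modelling, responses and continuous
predictors are z-scored (centre and scale); a scale-only "SD units" mode
exists because centring conventions differ between references.  Home-range
area is log-transformed before scaling — the natural choice for a strictly
positive, right-skewed area (the transformation is configurable).

## Univariate models

Each behavior at each scale is modelled as a Gaussian mixed model with
fixed effects {sex, NDVI, HFI, temperature seasonality, rainfall} and
random intercepts for individual and region, plus month at the monthly
scale.  Inference is a conjugate Gibbs sampler written for this package:
normal updates for coefficients and intercepts, inverse-gamma updates for
variances (residual prior V = 1, nu = 0.002), and parameter expansion on
every random-effect variance — the effect vector is scaled by a working
multiplier alpha ~ N(0, 625), keeping the chain mobile when a variance
sits near zero.  The default run length is 850,000 iterations, 50,000
burn-in, thinning 400 (2,000 retained draws); tests and demos use a short
preset of 8,500/500/4 (also 2,000 draws), and the methods-level checks
below were all run at the short preset.  With the variance components
pinned, the sampler's coefficient draws match the closed-form GLS
posterior of the conjugate submodel — the primary correctness check — and
at the reference simulation conditions (96 individuals × 18 months,
V_I = 0.3, V_month = 0.1, V_resid = 0.6, beta_sex = 0.5) all posterior
means land within ±0.1 of truth.

Derived per draw: adjusted repeatability R = V_individual / (sum of all
variance components); marginal and conditional R² from the variance of the
fixed-effect predictor; 95% equal-tailed intervals everywhere, with an
effect flagged when its interval excludes zero; low-to-high percent
changes of the back-transformed response across an observed covariate
range.  Effective sample sizes use the initial-positive-sequence
autocorrelation estimator, and a warning (recorded in the draw metadata)
fires when any variance chain falls under ESS 100 — site-fidelity models
are particularly prone to this.  Point estimates are reported as posterior
means; a kernel-density mode is also computed.

## Multivariate model and syndrome axes

The four monthly behaviors with non-negligible among-individual variance —
distance, home range, diurnality, exploratory proportion; site fidelity is
excluded — are modelled jointly with a full coefficient block per trait
and unstructured covariance matrices at the individual, region, month and
residual levels.  Updates are matrix-normal for coefficients and group
intercepts and inverse-Wishart for the residual covariance.

The random levels use *parameter-expanded* updates by default: the level's
intercepts are diag(alpha) times working intercepts with a working
inverse-Wishart covariance (scale I, df = traits + 1) and trait-wise
multipliers alpha ~ N(0, 625).  This choice is load-bearing.  A plain
inverse-Wishart prior (scale 0.01·I, df = traits + 1) behaves badly
exactly where this analysis is delicate — levels whose true variance is
near zero: the prior drags the variance diagonal toward its mode while
the covariance stays at its likelihood value, so the derived correlation
r_I = COV_I/sqrt(V_I V_I') piles up against ±1, its credible interval can
exclude the identified value, and the chain mixes slowly.  With parameter
expansion the test suite verifies, on a scenario with near-zero
among-individual variance and a strong residual correlation, that the
residual correlation is recovered sharply while the among-individual
interval honestly covers both zero and the realized latent correlation.
The plain-IW prior remains available (`MultiSpec(px=False)`) for
sensitivity analysis, and conclusions should be checked under both.

From the posterior draws of the among-individual matrix: correlations
r_I(x, y) = COV_I(x, y)/sqrt(V_I(x) V_I(y)) are computed per draw and
summarised with 95% intervals (a significant suite of r_I values is the
operational definition of a behavioral syndrome); the eigen decomposition
of the posterior-mean matrix gives point syndrome axes, each draw's
eigenvectors are sign-aligned to the point axes (positive dot product —
without alignment, eigenvector sign ambiguity makes loading intervals
meaningless), and quantiles over draws give intervals on loadings and
eigenvalue shares.  The point-axis sign convention makes the
largest-magnitude loading positive.  A warning fires when the top two
eigenvalue-share intervals overlap, i.e. when the leading axis is not
cleanly separated.

## Synthetic data

Two generators with stored ground truth:

* `simulate_behavior_table` draws directly from the hierarchical Gaussian
  model (fixed effects, individual/region/month intercepts, residual;
  univariate or multi-trait) — the route for validating the samplers and
  for planting syndrome axes, since only here is a "true axis" defined in
  trait space.
* `simulate_population` builds hourly trajectories from a biased
  correlated random walk switching between the two emission regimes.
  Each individual carries four latent modifiers drawn from a configurable
  among-individual covariance: a log step-length scale, a
  toward-exploratory transition-logit offset, a diurnal amplitude, and a
  home-attraction offset (logit scale).  Transition logits add covariate
  terms (standardized raster values at the current position, default
  weights: HFI −0.3, NDVI +0.2, rainfall +0.3, temperature seasonality
  −0.2) and a noon-centred cosine harmonic scaled by the individual's
  diurnal amplitude (default 0.4, so daytime movement dominates, giving a
  mildly positive diurnality index as observed in forest elephants).
  Headings are von Mises around a rho-weighted compromise between the
  previous heading and the bearing to the individual's home centre; the
  default rho = 0.4 was chosen so that monthly 95% ranges stabilise at a
  few tens of km², the magnitude reported for forest elephants.
  Covariate rasters are sums of Gaussian bumps scaled to plausible ranges
  (HFI 0–50, seasonality 0.4–1.6 °C, annual rainfall 1400–2650 mm) with a
  seasonal sinusoid and a configurable missing-cell fraction in NDVI.
  Positions leaving the raster are clamped at the edge (counted and
  logged).  Default population structure: 96 individuals, 7 regions,
  18 months at 1-h fixes.

What the generator does *not* emulate — and hence what green tests do not
establish about field data: GPS observation error, collar duty-cycle gaps,
social interaction between animals, musth/age structure, memory-based
revisitation beyond a single attraction centre, and habitat-driven
movement barriers.  Recovery results show the estimators are correct under
the assumed model, not that the model captures every feature of real
elephant movement.

## Numerical choices and problem sizes

Scaled-down problem sizes are used throughout testing: the HMM recovery
uses 20,000 steps; sampler recoveries use 96 × 18 tables at the 8,500/
500/4 preset; the end-to-end demo runs 12 individuals for 6 months.  KDE
evaluation exploits the separability of the Gaussian kernel (one matrix
product per range).  Forward/Viterbi recursions are numba-compiled,
operate in log space, and never emit silent NaNs — invalid parameters
raise.  Near-singular posterior covariance matrices in the multivariate
sampler are jittered (from 1e-10 upward, logged) and persistent failure
raises.  Degenerate inputs are contracts, not crashes: empty windows give
missing values with a logged reason; zero-variance columns raise naming
the column; a constant MCMC chain reports ESS 0 with a warning.

## Known limitations

Annual-scale repeatability from few repeated individuals is weakly
identified (the variance components separate poorly), mirroring the
caution appropriate to any such dataset.  The fitted HMM omits covariates
on transition probabilities by design — covariate effects enter only the
downstream behavior models.  The KDE home range is a fixed-bandwidth
estimator; autocorrelated-kernel and local-convex-hull estimators are out
of scope.  Site-fidelity models converge slowly and carry a convergence
caveat in their output metadata.
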