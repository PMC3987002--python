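# Methods

This note documents the models the package implements, the default
parameters and why they are set as they are, what the synthetic-data
generator does and does not emulate, and the numerical and design choices
made where the design was genuinely open.

## Exposure model

Monitoring sites and residences are misaligned, so exposure is a
distance-modified functional of the site measurements. For participant *i*,
chemical *c* measured at sites *j* with concentrations `c_jc`:

    x_ic = Σ_j c_jc / d_ij^p ,   p ∈ {1, 2}

with `d_ij` the great-circle distance in km by the spherical law of cosines
on a sphere of radius 6371.0 km (the conventional mean radius, fixed
explicitly for reproducibility). The arccos argument is clipped to [−1, 1]
to absorb round-off for near-identical points; distances below 0.1 km are
clamped to 0.1 km so a residence on top of a site cannot produce an infinite
exposure.

The unnormalized sum is the default because it preserves the per-site
functional form `c/d` and `c/d²` literally; since one can also argue for a
weighted *average* (total weight varies across participants with network
geometry), the renormalised inverse-distance-weighted mean is available via
`normalize=True`. Columns are labelled by chemical and medium ("mercuryS",
"arsenicW"); strip metals keep their bare element names.

Three address classes — first (birth), longest-held, last (current) — proxy
early, cumulative, and recent exposure windows. No temporal exposure
modeling is attempted beyond this.

## Correlation-matrix PCA

Chemicals live on incomparable scales, so components are extracted from the
sample correlation matrix (equivalently, PCA of column-standardized
exposures). Retention keeps the smallest number of components whose
cumulative variance fraction reaches the threshold (default 0.80; a fraction
exactly at the threshold counts). Eigenvector signs are arbitrary, so each
column is flipped to make its largest-magnitude element negative; this
pins loading reports to a reproducible convention (and makes dominant
components read as uniformly negative). The loading report omits chemicals
with |loading| below a display cutoff, default 0.30, configurable. Raw
eigenvector loadings are reported (not correlations with scores), and no
rotation is applied. Missing exposure entries are rejected rather than
imputed — upstream must decide how to handle them.

## Spike-and-slab logistic mixed model

Outcomes are Bernoulli with

    logit(p_i) = x_i' β + γ_i .

Selectable coefficients get the NMIG (Normal-mixture-of-inverse-Gammas)
prior: `β_j | η_j, τ²_j ~ N(0, τ²_j η_j)` with `τ²_j ~ IG(a_τ, b_τ)` and a
two-point indicator `η_j = 1` (slab) with probability `w`, `η_j = v0`
(spike) otherwise, `w ~ Beta(a_w, b_w)`. Defaults `v0 = 0.00025`,
`a_τ = 5`, `b_τ = 25`, `a_w = b_w = 1` follow common spike-and-slab GAMM
practice; all are configurable. The posterior frequency of `η_j = 1` is the
inclusion probability; a term is *reported* at ≥ 0.25 and *included* at
≥ 0.5 (a tie at exactly 0.5 counts as included, since 0.5 is a minimum).
Included single-coefficient terms additionally get a posterior mean and
equal-tailed 95% credible interval, starred "well estimated" when the
interval excludes zero.

Non-selectable coefficients (always including the fixed intercept) have
zero-mean Gaussian priors whose precisions carry Ga(1, 5e−05) hyperpriors,
independently per coefficient; the random-intercept precision has the same
hyperprior. A term can instead fix its prior variance (no hyperprior), which
gives an effectively flat reference fit for checking against maximum
likelihood.

**Computation.** The Bernoulli-logit likelihood is linearised exactly by
Pólya-Gamma augmentation: `ω_i ~ PG(1, ψ_i)` makes every full conditional
standard (Gaussian for β, γ and the latent measurement errors;
inverse-Gamma for τ²; Bernoulli for η; Beta for w; Gamma for the
precisions). PG(1, z) is drawn with Devroye's exact alternating-series
rejection sampler, implemented in `spatsel._polyagamma` and validated
against the closed-form PG mean and variance. The sampler therefore targets
the exact posterior; no Metropolis step or likelihood approximation is
involved.

**Blocks.** Smooth terms use a first-order random-walk basis: step functions
at interior quantile knots (default 8), centered, whose coefficients are the
RW1 increments — iid under the prior, selected as a block through a single
shared η (the conditional slab probability multiplies the per-coefficient
density ratios). The random intercept is one block of size n; by default it
is itself selectable, and with large n its indicator is nearly absorbing in
both states — inclusion probabilities near 0, 1, or (across chains) multiples
of 1/chains are expected behaviour of block NMIG, not a sampler defect.

**Chains and convergence.** Defaults are 3 chains × 10,000 iterations,
5,000 burn-in, thinning 5, with chain streams spawned from one master seed;
recorded draws per chain are (iterations − burn-in)/thin. Split-R̂ over the
coefficients is computed when ≥ 2 chains run (`max_rhat_`; < 1.1 is the
usual bar). Tests and the acceptance script use shorter single chains
(typically 1,500–3,000 iterations) — at those problem sizes the sampler
mixes well and R̂ on multi-chain runs stays ≈ 1.01 — so suite and script
run in minutes; these sizes are the package's own choices for its checks.

All candidate columns are z-scored before selection (NMIG is
scale-sensitive); coefficients are reported on the standardized scale.

## Bayesian Kriging and the two-stage model

Strip log-concentrations follow a Gaussian process with constant mean and
exponential covariance `sill · exp(−d/range) + nugget · 1{d = 0}` — the
minimal standard family with a nugget. The log scale handles skewed
nonnegative concentrations; the health model consumes log-scale exposures.
Hyperparameters are sampled by Metropolis-within-Gibbs: a joint random-walk
on (log sill, log range, log nugget) with Robbins–Monro step adaptation
toward 30% acceptance during burn-in only, plus a conjugate Gibbs update of
the mean. Priors are normal on the log parameters, empirically centred
(data variance for the sill, median pairwise distance for the range, 10% of
variance for the nugget) with wide spreads (1.5 on the log scale) —
weakly-informative in the usual applied-GP sense; explicit locations
override the centring. Predictions marginalise over (up to 100) posterior
draws: means are mixture means, variances are mixture variances. With fixed
hyperparameters and zero nugget the predictor interpolates exactly (a
1e−12·sill diagonal jitter keeps factorizations stable; duplicated sites
with conflicting values and a forced zero nugget are rejected).

Eligibility for the validation analysis: residence inside the convex hull
of the strip sites or within a buffer (default 1 km) of it, measured in a
local equirectangular km projection (adequate at the tens-of-km scale of a
strip). The convex hull stands in for the unpublished true strip polygon.

The two-stage health model is sequential with no feedback: stage 1 kriges
each chemical; stage 2 refits the spike-and-slab logistic model where each
interpolated exposure enters as `mean_ij + ω_ij` with a latent
`ω_ij ~ N(0, sd²_ij)`, `sd_ij` the stage-1 predictive standard deviation
(plug-in propagation; cross-chemical error correlation is ignored). The ω
are Gibbs-updated — their full conditionals are Gaussian under the PG
augmentation — and a zero stage-1 sd pins ω to zero exactly, collapsing the
model to the plain fit. Chemicals enter linearly by default (matching
single-coefficient reporting); the RW1 smooth option exists for terms
without measurement error. As measurement error grows, credible intervals
for the affected coefficients widen; at extreme error the spike absorbs the
coefficient and intervals re-tighten around zero, which is why the
widening checks use moderate error levels.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with defaults
fixed as the study conditions:

- ~80 participants, target outcome prevalence 0.475; prevalence is
  calibrated by root-finding the intercept on the realized linear predictor.
- A ~25 × 28 km coastal-scale region; sparse irregular regional networks
  (30 soil, 20 groundwater sites, uniform over the region) and a dense
  strip of 110 sites in a ~1 km × 22 km band — so most address-to-site
  distances fall within 15 km.
- Chemical surfaces: per medium, a separable Gaussian process on
  log-concentrations with exponential spatial correlation (range 10 km,
  sill 1.0, nugget 0.1) and compound-symmetric cross-chemical correlation
  (0.6 within a medium; media are independent). Exponentiation gives
  log-normal, hence nonnegative, concentrations. The exponential family and
  log-normal marginals are modeling choices for validity and positivity,
  not claims about real fields.
- Personal covariates are questionnaire-style marginals (counts Poisson,
  binaries Bernoulli, age ≈ N(54, 12²) clipped to adulthood, 15% male);
  these are pragmatic choices — no distributional information about the
  real covariates is available.
- Addresses: base residence uniform over the region; the longest and last
  addresses jitter the base by ~1 km and ~3 km (moves are local). This is a
  convenience model for "addresses vary over time".
- Outcomes: `logit(p_i) = α + Σ_k β_k z_k + γ_i` over standardized
  covariates/exposures named in `true_beta` (sparse; default empty),
  `γ_i ~ N(0, 1)` by default.

All randomness flows from the config seed through per-stage
`SeedSequence` splits: a config regenerates its study bit-identically.

What passing tests on these data do *not* show: robustness to real-world
geography (shorelines, clustered settlement), non-stationary or non-log-normal
concentration fields, informative missingness, residential mobility beyond
local jitter, or confounding structures absent from the generator.

## Numerical choices and degenerate inputs

- PG sampler: stable log-normal-cdf tail expansion and an overflow guard for
  extreme linear predictors.
- Spike-slab Gibbs: the β update factorizes the full conditional precision
  by Cholesky; tiny spike variances (τ²·v0) enter as large but finite prior
  precisions.
- PSD square roots (duplicate site coordinates at zero nugget) use an
  eigendecomposition with eigenvalues clipped at zero, so duplicated sites
  receive identical field values.
- Constant exposure columns, constant Kriging fields (in the inference
  path), empty site sets, non-binary outcomes, out-of-range coordinates,
  mismatched effect names, and missing stage-2 predictions all raise
  errors naming the offending column/parameter rather than propagating NaNs.
- A constant column is detected with tolerance 1e−12 relative to its mean
  (identical values accumulate ~1e−16 float noise in a variance).

## Known limitations

- The random-intercept indicator is nearly absorbing for large cohorts
  (see above); its inclusion probability should be read qualitatively.
- The Kriging range parameter is weakly identified from a single narrow
  strip; calibration checks use spatially spread site layouts.
- Exposure columns built from a shared site network are strongly collinear
  by construction (shared 1/d geometry); that is exactly why the PCA stage
  exists, but it limits per-chemical attribution in the selection stage.
- No co-Kriging across chemicals, no spatially structured random effects,
  and no marginal-likelihood model comparison — selection is by inclusion
  probabilities only.
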