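# spatsel

Spatial environmental-exposure modeling of binary autoimmunity outcomes.

`spatsel` implements, as a tested and reusable pipeline, a statistical
workflow for studying whether residential proximity to chemical contamination
relates to antinuclear-antibody (ANA) positivity in a small, genetically
at-risk cohort. The setting is spatially *misaligned*: chemical
concentrations are measured at monitoring sites (sparse regional soil and
groundwater networks, plus one dense ~110-site soil-metal "strip"), while
participants are observed at residential addresses — first (birth), longest
held, and last (current) — that do not coincide with any site.

The pipeline has four stages, each usable on its own:

1. **Distance-modified exposures** (`spatsel.exposure`). For participant *i*
   and chemical *c*, exposure is the inverse-distance functional
   `x_ic = Σ_j c_jc / d_ij^p` with `p ∈ {1, 2}`, where `d_ij` is the
   great-circle distance (spherical law of cosines, R = 6371 km) from the
   address to site *j*. A normalized inverse-distance-weighted mean is
   available as an option.
2. **Correlation-matrix PCA** (`spatsel.pca`). Components of the exposure
   correlation matrix are retained until they explain ≥ 80% of the variance;
   signed loadings above a display cutoff summarise each component.
3. **NMIG spike-and-slab selection** (`spatsel.selection`). A Bayesian
   logistic mixed model `logit(p_i) = x_i'β + γ_i` with a
   Normal-mixture-of-inverse-Gammas prior on selectable coefficients:
   `β_j | η_j, τ²_j ~ N(0, τ²_j η_j)`, `τ²_j ~ IG(a_τ, b_τ)`, `η_j ∈ {v0, 1}`
   with `P(η_j = 1) = w`, `w ~ Beta(a_w, b_w)`. The posterior frequency of
   `η_j = 1` is the term's inclusion probability (report ≥ 0.25,
   include ≥ 0.5). The logistic likelihood is handled exactly by
   Pólya-Gamma augmentation (Devroye's sampler, implemented in-package), so
   the whole model is a Gibbs sampler. Random intercepts and first-order
   random-walk smooth terms are supported, both optionally selectable.
4. **Kriging validation** (`spatsel.kriging`). Along the dense strip, an
   exponential-covariance Gaussian process with sampled hyperparameters
   (Bayesian Kriging) interpolates log-concentrations to the addresses of
   participants living within 1 km of the strip's convex hull. The two-stage
   health model then repeats the spike-and-slab fit with an additive latent
   measurement error `ω_ij ~ N(0, sd²_ij)` per participant-chemical, where
   `sd_ij` is the Kriging predictive standard deviation — so stage-1
   interpolation uncertainty propagates into stage-2 credible intervals.

A synthetic-data generator (`spatsel.simulate`) reproduces the structure the
analysis assumes — ~80 participants at 47.5% prevalence, spatially correlated
log-normal chemical surfaces, three address classes, outcomes from a sparse
logistic truth — so every stage is testable end to end with known truth and
no confidential inputs.

The core model classes follow scikit-learn conventions
(`fit`/`transform`/`predict`, `get_params`, fitted attributes with a trailing
underscore): `InverseDistanceExposure`, `CorrelationPCA`,
`SpikeSlabLogisticRegression`, `BayesianKriging`.

## Worked example

```python
import numpy as np
from spatsel import (SimulationConfig, simulate_study,
                     SpikeSlabLogisticRegression, correlation_pca,
                     retain_components, loading_report)

cfg = SimulationConfig(seed=100, n_participants=500,
                       true_beta={"Smoke": 2.0, "education": -2.0},
                       random_intercept_sd=1.0)
study = simulate_study(cfg, include_strip=False)

# which chemicals dominate the exposure correlation structure?
pca = correlation_pca(study.exposures)
k, scores = retain_components(pca, 0.80)
print(f"{k} component(s) explain 80% of exposure variance")
print(loading_report(pca, k).to_text())

candidates = ["tTermites", "tInsects", "tWalls", "tPaint", "education",
              "CurAge", "Smoke", "Work", "Saltfin", "well_water"]
est = SpikeSlabLogisticRegression(n_iter=1500, burn_in=500, thin=2,
                                  n_chains=1, random_state=0)
est.fit(study.participants[candidates], study.participants["ana"].to_numpy())
print(est.summary_.to_text())
```

Output:

```
3 component(s) explain 80% of exposure variance
1: DDTW(-), arsenicW(-), atrazineW(-), leadW(-), mercuryW(-)
2: DDTS(-), arsenicS(-), atrazineS(-), leadS(-), mercuryS(-)
3: arsenicS(-), atrazineS(+), leadS(+)
term                  incl. mean (sd)       estimate (95% CI)
education             1.0000 (0.0000)    -1.777 (-2.146, -1.446) *
Smoke                 1.0000 (0.0000)    1.816 (1.483, 2.171) *
random_intercept      1.0000 (0.0000)    ---
```

The two planted effects (log-odds ±2 per standardized unit; the fitted means
are attenuated slightly by the random intercepts) are the only covariates
whose inclusion probability reaches the 0.5 criterion; their 95% credible
intervals exclude zero, so they are starred "well estimated". The first two
components split cleanly by medium with uniformly negative loadings — the
generator simulates soil and groundwater as independent processes, with
strong cross-chemical correlation only within a medium.

The same pipeline runs from the shell:

```bash
spatsel run --config config.yaml --out results/
```

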