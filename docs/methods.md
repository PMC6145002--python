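# Methods

`enmstack` implements a stacked species-distribution-modelling workflow for
asking how projected climate change reshapes the alpha and beta diversity of
a regional species pool, together with a virtual-species test bed in which
every stage of the workflow can be validated against known truth. This note
documents the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic experiments do and do not demonstrate.

## Workflow overview

1. **Covariate screening.** Environmental layers are filtered by iterative
   variance-inflation-factor (VIF) removal until every retained layer has
   VIF < 10 (strictly below; a VIF exactly at the cutoff is removed). VIF_j =
   1/(1−R²_j) from an OLS regression (with intercept) of layer j on the
   others, evaluated over raster cells of the calibration region (all cells,
   or a seeded subsample of 10⁵ when grids are larger; the report records
   which). Ties on the largest VIF are broken by input order. Perfect
   collinearity (1−R² < 1e−10) is reported as +∞, not an error.
2. **Per-species models.** Presence records are collapsed to unique raster
   cells; species with fewer than 5 informative cells are dropped. Background
   points (default max(1000, n_presences)) are uniform random non-presence
   cells. Data are split 80/20 (single stratified random split, no
   cross-validation). Four algorithm families are fitted with fixed,
   documented hyperparameters — no per-species tuning, so large species sets
   receive a uniform treatment:
   * **GLM** — binomial logistic regression on standardized linear +
     quadratic terms. The quadratic expansion is essential: climatic niches
     are unimodal, which a linear logit cannot express.
   * **BRT** — gradient-boosted shallow trees (300 trees, learning rate
     0.05, depth 3).
   * **RF** — random forest (500 trees, min leaf 2, probability output).
   * **SVM** — RBF-kernel classifier with Platt-scaled probabilities (C=1,
     median-heuristic gamma).
3. **Evaluation and exclusion.** On the held-out 20%: rank-based AUC (ties
   count ½) and TSS = sensitivity + specificity − 1, evaluated at the
   sensitivity–specificity equality threshold. The threshold search scans the
   sorted unique scores plus midpoints; ties on |sens − spec| break by larger
   TSS, then by the smaller threshold. Models with AUC < 0.75 **or**
   TSS < 0.3 are excluded from the ensemble; a species with no passing model
   is flagged unmodelable and excluded downstream (logged). The equality
   threshold is computed on evaluation-set scores — the same data the other
   evaluation metrics use.
4. **Ensemble, binarization, dispersal filter.** Per species, the baseline
   suitability surface is the unweighted cell-wise mean over passing
   algorithms; future surfaces average algorithms × GCMs × RCPs of the slice.
   All surfaces are binarized at the mean of the passing algorithms' equality
   thresholds (futures reuse the baseline threshold: evaluation data exist
   only for the baseline). Future ranges are then filtered: a connected patch
   (8-connectivity — diagonal neighbours count as continuous area) survives
   if it overlaps ≥ 1 baseline cell, or lies within 400 km of the main
   (largest) predicted patch, or within 400 km of any occurrence record;
   strictly more distant isolated patches are deleted as suitable-but-
   unreachable. Distances are minimum cell-center distances (edge-to-edge at
   cell resolution), Euclidean on planar synthetic grids. The filter is
   idempotent and never applied to baseline ranges. "Main area" is defined as
   the largest patch (ties → lowest label), the only reading that makes the
   distance rule well defined. The filter is fully rule-based; a per-patch
   log (area, distances, decision) supports manual review.
5. **Diversity.** Binary ranges are aggregated onto a coarse grid (default
   50 km; a coarse cell is occupied if ≥ 1 constituent fine cell is). Alpha
   diversity: per-site richness, future−current change classed gain/loss/
   stable, and classical paired t tests on per-site differences. Beta
   diversity from the Jaccard dissimilarity matrix D: A = −D∘D/2 is
   double-centered to G, SStotal = tr(G) (equal to (1/n)Σ_{i<j}d²_ij by the
   Gower identity — both code paths are compared in tests), BDtotal =
   SStotal/(n−1), LCBD_i = G_ii/SStotal. Site-wise LCBD significance uses a
   permutation null in which each species column is shuffled independently
   across sites; p_i = (1 + #{LCBD*_i ≥ LCBD_i})/(1 + n_valid) (add-one
   Monte-Carlo estimator, so p is never exactly 0); permutations with
   SStotal = 0 are skipped and counted. Raw p < 0.05 is mapped by default (a
   Holm option exists but defaults off). Each pair's dissimilarity is
   decomposed (Baselga family, presence–absence): Repl = 2·min(b,c)/(a +
   2·min(b,c)), Nes = D − Repl, S = 1 − D; triplets sum to 1 and are drawn in
   a ternary plot with vertices Repl=(0,0), Nes=(1,0), S=(½,√3/2).

**Empty sites.** Sites with zero predicted species are excluded from
beta-diversity matrices (the Jaccard coefficient is 0/0 between two empty
sites) but keep their 0 in richness maps; exclusions are recorded per slice.
Inside the permutation null, where shuffling can empty a site, an
empty–empty pair contributes dissimilarity 0.

## The synthetic world

Real inputs (gridded bioclimate plus curated occurrence records) are
replaced by a generator with known truth:

* **Climate.** Layers are Gaussian random fields: white noise smoothed with
  a Gaussian kernel of standard deviation `autocorr_length_km` and
  standardized to mean 0, sd 1. Default 25 km on a 40×40 grid of 10-km
  cells: long enough for coherent regional gradients, short enough that the
  400-km domain contains many independent climate features. (At 50–60 km the
  domain holds only a handful of independent blobs and nominally independent
  layers acquire incidental correlations of |r| ≈ 0.5, which destabilizes
  both the collinearity filter and niche identifiability.) Two derived
  layers — standardized linear combinations of base layers plus 5% noise —
  emulate the redundant variables that motivate VIF screening; the filter
  removes them in practice.
* **Species.** A niche is a multiplicative Gaussian: suitability =
  ∏_layers exp(−(v−opt)²/2β²). The default roster draws optima uniformly in
  [−1.5, 1.5] sd and breadths in [0.4, 0.9] sd. These moderately selective
  niches put the fitted models in the high-skill regime these workflows
  report in practice (mean AUC ≈ 0.94, mean TSS ≈ 0.74 in the reference
  run); with very broad niches (β ≥ 1.2) presence and background samples
  barely differ and most models fail the skill gate, which is a property of
  diffuse niches, not of the pipeline.
* **True occupancy.** A cell belongs to the true range when it lies within
  `occupancy_z` breadths (default 1.25) of the optimum along **every** axis,
  i.e. product suitability ≥ exp(−n_layers·z²/2). Parameterizing the cutoff
  per axis, rather than as a fixed product value, keeps range sizes sensible
  as the number of niche axes changes (a fixed product cutoff of 0.2 with
  four axes would confine species to ±0.9β on all axes simultaneously —
  vanishingly small ranges unlike the widespread species of real regional
  pools). With the defaults, species occupy ~17% of the landscape on
  average.
* **Occurrences.** Presence cells are drawn without replacement with
  probability ∝ true suitability (duplicate records are therefore
  impossible, mirroring duplicate-record cleaning); an optional bias field
  multiplies the weights for survey-effort sensitivity studies and is off by
  default, since the effect of database bias on such models is an open
  question.
* **Futures.** future layer = base + rcp_scale·trend + smooth GCM
  perturbation (sd 0.15, correlation length 5 cells). The perturbation is a
  function of (GCM, slice, layer) but not of the RCP — circulation models
  differ structurally, independent of the emission pathway driving them.
  Default trend: strong warming (+2.5 sd on the temperature layer per unit
  scale, smaller shifts elsewhere), with slice × pathway scales 2050: 0.8 /
  1.0 and 2070: 0.9 / 1.8 (the pathways diverge as the horizon lengthens).
  Derived layers inherit the weighted trend of their parents.
* **Designed extinction.** Species `s000` is a cold specialist (optimum
  −2.0 sd, breadth 0.4 on temperature, broad elsewhere). Under the default
  trend the coldest future cell is several breadths warmer than its optimum
  in every member, so it loses all suitable area by 2050 — the analogue of
  species predicted to retain no climatically suitable area.

## Scenario experiments

Two controlled experiments probe the beta-diversity mechanisms without
confounding from range shifts:

* **Extinction-dominated contraction** — the narrowest-ranged 25% of species
  lose all area; the rest keep their baseline ranges. Every species' range is
  a subset of baseline (pure contraction). Narrow endemics are the species
  unique to few sites; their loss removes site-unique occurrences (the b and
  c of the pair counts), converting turnover into richness-difference
  nestedness, so the centroid's Nes share rises.
* **Uniform expansion** — every species is re-binarized at threshold − 0.12.
  Compositions converge on the shared widespread pool and BDtotal falls
  (homogenization).

A caution established while testing: "any pure contraction raises the mean
nestedness share" is **not** a theorem. Uniform thinning of shared species
lowers the shared count a and pushes pairs toward replacement; random
contractions on random matrices *decrease* the mean Nes share more often
than not. The nestedness response is a property of extinction-dominated,
spatially structured loss — which is the mechanism the package's contraction
experiment implements — and the test suite asserts it in that form.

## Numerical conventions and degenerate inputs

* Thresholding is inclusive (mask = values ≥ threshold); the dispersal rule
  deletes only strictly-beyond-cutoff patches (a patch at exactly 400 km is
  retained).
* Equality-threshold candidates include midpoints so a zero sens–spec gap is
  attainable between score clusters; constant scores return that constant
  with a warning.
* AUC with all-tied scores returns 0.5.
* `paired_t` rejects all-equal differences (t undefined); the pipeline
  records NaN for that comparison rather than aborting (it arises in the
  zero-trend null experiment).
* LCBD rejects matrices in which every retained site has the same
  composition (SStotal = 0).
* An empty future mask passes through the dispersal filter unchanged.
* Seeds: a master seed fans out via SHA-256 of a tag path (`_seeds.child_seed`)
  to every stochastic component; all child seeds are < 2³¹. Reruns of a
  configuration are bit-identical.

## Problem sizes

The reference experiment — also what `scripts/acceptance.py` runs — uses 20
species on a 40×40 grid (10-km cells, 8×8 coarse sites), 200 presences per
species, 4 algorithms, 2 GCMs × 2 RCPs × 2 slices, and 999 LCBD
permutations; it completes in about a minute on one CPU. The permutation-null
calibration inside the acceptance script uses 60 null matrices × 499
permutations, a size at which the nominal 5% rate is estimated to about ±1
percentage point. Unit tests use 20×20 worlds with 4–6 species.

## What the synthetic tests do and do not show

Passing tests show the machinery is correct and the inference chain can
recover known truth under a smooth, stationary, low-dimensional climate with
unimodal independent-axis niches, unbiased sampling, and equilibrium
occupancy. They do not show robustness to the things real data add: spatially
biased survey effort, niche shapes with interactions or skew, dispersal
limitation and biotic exclusion within the realized range, non-analogue
future climates, or the coastline/topography structure of real rasters. The
dispersal rule in particular is a distance cutoff, not a mechanistic
dispersal model, and is only as plausible as its 400-km default.

## Real-data mode

`pipeline_cli` accepts user-supplied rasters (plain-text ASCII grids) and an
occurrence CSV and runs the identical chain from variable screening onward.
It performs no data acquisition, no taxonomy resolution, and no cartography;
distances on geographic rasters should be interpreted with the cell size the
user supplies.
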