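# Methods

This note records the models, the defaults and why, the numerical choices,
and what the synthetic data do and do not establish.

## Trait construction

**Day grid and intake.** The test period is 42 days; feeder events are
assigned to days by their entry-time date (unambiguous and
order-preserving for events spanning midnight), daily intake is the sum of
event grams, and mean intake is the mean of the 42 daily values with
zero-intake days included. Energy intake is the product
(kg as-fed × dry-matter fraction) × ME (MJ/kg DM). The product reading was
chosen because it is the only interpretation consistent with study-scale
numbers: ~2.5 kg/day of 93%-DM, 10.9 MJ/kg-DM pellets gives ~25.3 MJ/day,
matching the reported mean of 25.6. Per-year pellet compositions
(DM 93/94/90%, ME 10.9/11.4/10.8 MJ/kg DM) are the defaults.

Intake pre-adjustment by a day-level repeated-measures model is not
implemented beyond the 42-day mean: the original description of that step
is too thin to pin down a unique specification, and with complete daily
records the least-squares day adjustment reduces to the plain mean.

**Growth.** Daily weights come from piecewise-linear interpolation between
consecutive weighings (day 0 = first test-period weighing); outside the
observed span the nearest segment's slope is extrapolated, with a log
message. ADG = (day-42 − day-0 weight)/42 and MMWT = day-21 weight^0.75.
An OLS regression through (day, weight) is provided as the alternative
method; both are always computed so their agreement can be monitored
(correlation > 0.95 under realistic weighing noise).

**Feeding behavior.** Events/day, mean event duration, mean intake/event,
and feeding rate. The rate is the mean of per-event g/s — "rate during
each event" — not pooled grams over pooled seconds; zero-duration events
are excluded from the rate but still counted.

**RFI.** OLS with pen nested in cohort (a combined cohort:pen factor).
Aliased design columns are removed by pivoted-QR rank detection and
logged, so redundant nestings degrade gracefully. Residuals are exactly
zero-sum and orthogonal to every design column; R² is reported overall and
within cohort.

**Gas conversion.** g/day = slope(ppm/min) × 10⁻⁶ ×
P·V_free/(R·T) × M × 1440, with V_free = 827 L minus an allometric animal
volume (1 L per kg liveweight by default; both configurable). The slope is
OLS over the three timed readings rather than an endpoint difference — it
uses the recorded exact times and damps single-reading noise. A negative
fitted slope is retained but flagged. Lot scaling is applied per trait
within round across lots, with the grand mean taken over all animal-rounds
of the dataset (the only self-consistent grand-mean choice when both
rounds are scaled); after scaling, every lot mean equals the grand mean
exactly. O2 is parsed and stored but no O2 trait is derived.

**CT.** The printed HU bands (40–255) are treated as an offset display
scale; bands are configuration, never hard-coded. Volumes use the
rectangular rule (area × spacing), matching the source procedure;
trapezoidal integration is available as an alternative function. The
HU→density map is linear with coefficients fitted through nominal
(display-HU, density) anchors for fat/lean/bone — the externally cited
relationship is not printed anywhere, so the map is explicit
configuration. Mass conversion defaults to per-depot area-weighted mean
HU; a single density per tissue type is available. Compartment labels
(carcass/viscera, subcutaneous/intermuscular, rumen-content exclusion) are
per-slice inputs, mirroring the manual segmentation of the original
protocol. Fat:lean is total fat / carcass lean (consistent with the
reference mean of 0.67); dressing-out percent is carcass weight / CT
weight — the composition-section definition — noting that the source
table's footnote instead says ratio to live weight; the two differ
materially (ours centres near 66% on synthetic cohorts, the printed value
48.8 reflects the live-weight denominator).

## REML engine

All fitted models have linear covariance structure
V(θ) = Σ_k θ_k C_k (additive A-block, maternal dam block, i.i.d.
permanent environment, residual identity). The dense engine maximises the
restricted likelihood by average-information steps with a small Levenberg
ridge, accepting a step only if the log-likelihood does not decrease
(halving otherwise, with a backtracked scaled-gradient fallback), so the
accepted likelihood sequence is monotone by construction — the role an EM
fallback usually plays, but valid unchanged for covariance parameters in
bivariate models. Variance parameters are floored at 1e-8 × the
phenotypic variance. Convergence: |Δ logL| < 1e-6 and maximum relative
parameter change < 1e-4.

For the common special case — a single A-structured effect, one record per
animal — the likelihood is maximised in the eigenbasis of A, where V is
diagonal and the profile over the variance ratio is a 1-D bounded search
(xatol 1e-12). This is an exact reparametrisation of the same likelihood,
not an approximation, and it is what makes the 20-replicate recovery
suites cheap. Fully overlapping bivariate designs use the same rotation
(2×2 blocks d_k G + R per eigenvalue), optimised over Cholesky factors of
G and R by Nelder–Mead with a polishing restart — the Cholesky
parametrisation keeps both matrices PSD without penalties. Partially
overlapping or maternal/PE models fall back to the dense engine.

Standard errors of h², maternal h², repeatability and correlations come
from the delta method on the inverse average-information matrix at the
optimum. The phenotypic variance in every ratio denominator is the sum of
all fitted components. Genetic correlations with |r| at the boundary are
projected onto ±1 and flagged; two traits that are (anti)identical after
fixed effects are detected up front and returned as a flagged boundary
estimate, because the restricted likelihood diverges as the residual
covariance matrix becomes singular.

**Maternal structure.** The dam effect defaults to an A-structured
maternal *genetic* effect; an i.i.d. dam-environment option exists because
the original model statement ("dam fitted as a random effect") does not
distinguish them. The direct–maternal genetic covariance is fixed at zero
(no such covariance is reported). Covariates (age of dam, its square,
birthday deviation, weight adjustments) are mean-centred.

**Pedigree.** A is built by the tabular method; its sparse inverse by
Henderson's rules with the Quaas inbreeding correction, using exact
inbreeding coefficients from ancestor-closure tabular kinship. This is
exact at every size (no approximate large-pedigree mode is needed at
cohort scale); cost grows with pedigree depth, which is shallow here.
Unknown parents are unrelated non-inbred founders; no genetic groups.

## Synthetic cohort generator

The generator is the package's study stand-in, with exact bookkeeping:
every phenotype is stored as mean + fixed effects + direct breeding value
+ dam's maternal value + permanent environment + residual, summing exactly.

- **Pedigree:** three generations (founder grandparents, sires/dams,
  phenotyped lambs); 100 sires × 5 dams × 2 lambs by default
  (1000 phenotyped, cohort-scale); 20% of sires have progeny in two
  cohorts (link sires); every lamb has a known dam, so maternal effects
  are estimable. Flocks (3) and cohorts (5: 1, 2a, 2b, 3a, 3b) follow the
  study layout, with 5 pens per cohort in years 1–2 and 2 pens in year 3.
- **True parameters:** means, SDs, direct and maternal heritabilities and
  repeatabilities are seeded from the packaged reference estimates, with a
  default set of genetic correlations (e.g. RFI × visceral fat −0.52,
  CH4 × carcass lean 0.54); residual correlations are backed out of target
  phenotypic correlations and both matrices are PSD-projected by
  eigenvalue clipping. Recovery tests therefore double as plausibility
  checks at study scale.
- **Breeding values** descend the pedigree by Mendelian sampling with the
  inbreeding-corrected sampling variance, so Cov(a_i, a_j) = a_ij G
  exactly in expectation.
- **Feeder events:** event counts are Poisson around the animal's latent
  events/day (reference mean 13.67), event sizes are normalised gamma
  draws so daily sums equal the day's latent intake exactly, and durations
  follow the animal's latent feeding rate. One visit = one event (no
  merging rule exists to emulate). Day-to-day intake varies with an 8% CV
  whose 42-day mean is constrained to the latent mean.
- **Liveweights:** linear growth on the twice-weekly grid (0, 3, 7, …, 42)
  with Gaussian weighing noise (0.5 kg default; optionally a fraction of
  body weight). The day-21 weight is MMWT^(4/3), tying the weight stream
  to the latent MMWT trait.
- **Energy intake** is generated *from* the RFI model (b0 = 2.62,
  b1 = 0.6 MJ/kg^0.75, b2 = 30 MJ/kg gain — chosen to reproduce the
  reference intake mean at the reference MMWT and ADG), so the RFI
  pipeline's residual recovers the latent RFI trait.
- **PAC:** two rounds (days 21 and 35), lots of 10 within cohort,
  concentrations rising linearly at the rate implied by the latent g/day
  through the same ideal-gas algebra the analysis inverts; a multiplicative
  log-normal lot factor (σ = 0.10) represents shared waiting-time nuisance
  — exactly the structure lot scaling removes; 1% reading noise and small
  timing jitter by default.
- **CT:** 30–32 slices at 30 mm; each depot's area profile is a parabola
  along its compartment sampled at slice midpoints, so the rectangular-rule
  volume error is O(spacing²) and vanishes as spacing shrinks — the basis
  of the convergence check. Rumen-content areas are emitted on middle
  visceral slices and excluded by the pipeline. A raster fidelity mode
  draws per-pixel HU values inside the configured bands (64×64 rasters,
  450-mm field of view) with subcutaneous masks, exercising the actual
  segmentation path.

**What the generator does not emulate:** selection or assortative mating,
the 14-day introductory period, circadian feeding structure, growth
curvature, chamber humidity/absorption corrections, or real scanner
artefacts. Passing recovery tests therefore demonstrates that the
*pipeline* is correct and unbiased under the stated generative model, not
that it is robust to every field pathology of real data.

## Validation problem sizes

Parameter-recovery suites use the study-scale design of 100 sires × 10
progeny with 20 replicates per truth value, sharing one pedigree across
replicates (fresh phenotype draws each time — a standard parametric
bootstrap that also reuses the eigendecomposition). Oracle-equivalence
checks use 50 sires × 10 progeny (balanced ANOVA) and 50-animal inbred
pedigrees (brute-force profile likelihood). The analysis drivers run a
500-lamb cohort. These sizes keep the default test run at desk scale while
matching the study's family structure.

## Known limitations

- The PAC conversion algebra is a documented, configurable choice (the
  source delegates it to an external description); only self-consistency
  with the generator's forward model is asserted, not agreement with any
  particular published constant.
- Bivariate models require fully overlapping records for the fast path and
  do not fit maternal/PE terms; repeated gas traits enter bivariate pairs
  as round means.
- Multi-trait (>2) models, genomic relationships, dominance, and genetic
  groups are out of scope.
- REML SEs are asymptotic (inverse average information); for boundary
  estimates (variance at the floor, |r_g| projected to 1) they are
  indicative only and flagged.
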