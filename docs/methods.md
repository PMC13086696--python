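# Methods

This note documents the models, numerical choices and open design decisions
behind the package, and what the synthetic-data generator does and does not
emulate.

## Dose-response models and likelihood

Apical endpoints (viable cell density, % DNA in tail, % micronuclei) are
strictly positive, so fits use a lognormal likelihood: log responses are
normal around the log of the mean curve with a pooled residual SD σ. The
family is the nested continuous suite

| id    | mean curve                              | free parameters |
|-------|-----------------------------------------|-----------------|
| null  | a                                       | a               |
| exp3  | a·exp(b·xᵈ)                             | a, b, d         |
| exp5  | a·(c − (c−1)·exp(−b·xᵈ)), b > 0         | a, b, c, d      |
| hill3 | a·(1 − xᵈ/(bᵈ + xᵈ))                    | a, b, d         |
| hill5 | a·(1 + (c−1)·xᵈ/(bᵈ + xᵈ)), b > 0       | a, b, c, d      |

With the exposure timepoint as covariate, background *a* and rate *b* are
level-specific while asymptote *c*, shape *d* and σ are shared — one of
several defensible covariate structures; it was chosen for parsimony and is
the main divergence risk against other implementations of the same family.
AIC = 2k − 2·lnL with k counting all free parameters including σ; the
reported log-likelihood includes the lognormal Jacobian term −Σ log y so the
identity is testable externally. Model selection takes the lowest AIC, and
ties within 1e−6 (printed-precision ties are rounding artifacts) go to the
lower BMC at the requested BMR.

Optimization is multi-start nonlinear least squares on log residuals
(≥ 5 starts per model from direction-oriented rate grids over d ∈
{0.7, 1, 2} and ±½-decade rate scalings, plus one seeded jittered start),
with tolerances 1e−12. The shape exponent is clamped to d ∈ [e⁻⁴, e³] to
keep xᵈ finite; non-convergence yields a `fit_failed` record, never an
exception.

BMCs solve |mean(x)/mean(0) − 1| = BMR in closed form per model (the same
algebra as the generator's oracle, which the tests exploit: noise-free fits
must agree with the oracle to 1e−6 relative). A fitted asymptote short of
the BMR yields `unreachable`; a selected null model yields `no_response`.
The adverse direction defaults per endpoint family (viability decreases;
comet, MN and tPOD endpoints increase) and otherwise follows the fitted
curve's own direction.

Concentrations are fitted on the experimental mass axis (µg/mL) and the
resulting BMCs converted to µM of the constituent metal — µg/mL ÷ molar
mass × 1000 × metal atoms per formula unit, hydrate masses for the dissolved
salts — which is an exact transformation because the model family is closed
under rescaling of x.

Quantal-style micronucleus percentages are treated on the same continuous
relative-deviation track as the other endpoints. This is a flagged
interpretation: a quantal treatment of "relative risk" would differ in
detail.

## Williams-type trend test

Group means ordered by concentration are amalgamated by PAVA; the statistic
compares the isotonic estimate at the top dose with the control mean using
the pooled within-group variance, t = (M_k − ȳ₀)/√(s²(1/n_k + 1/n₀)). For
the top dose the isotonic estimate reduces to the extreme suffix-weighted
mean of the treated groups, which is what the vectorised permutation core
computes. p-values come from label permutations (default 1000, seeded per
gene) with the add-one convention (1 + hits)/(1 + N); the increasing and
decreasing one-sided p-values are Bonferroni-doubled and capped at 1.
Permutation rather than critical-value tables gives exact small-sample
behaviour at n = 3 replicates; calibration on null data is verified to sit
inside the binomial 99 % band around the nominal 0.05 at 2000 genes. Genes
additionally need a ≥ 1.5-fold change (2^|mean log2 ratio| at any
concentration, either direction) to proceed to BMC modelling.

## Gene BMC model averaging

Gene models are fitted on the log2-ratio scale with normal residuals. The
family ids mirror the usual continuous suite but use additive saturating
forms appropriate for data centred at zero (a + b·x, a + b·xᵈ,
a + b·xᵈ/(cᵈ+xᵈ), a + b(1−e^(−x/c)), a + b(1−e^(−(x/c)ᵈ))). Averaging uses
AIC weights w ∝ exp(−ΔAIC/2) — a frequentist surrogate for Bayesian model
averaging; the BMC is solved on the weight-averaged mean curve at
|m̄(x) − m̄(0)| = k·σ̄ (σ̄ the weight-averaged residual SD) by bracketed
root-finding on [0, top dose], taking the first crossing when the averaged
curve is non-monotone. Averaging the curve rather than the member BMCs
matches "the best estimate according to the model average" most directly;
the per-member route is available through single-model families.

Pathway tPODs are the median gene BMC among responsive pathway members
(arithmetic midpoint for even counts), requiring ≥ 3 genes under the
default rule or max(3, ⌈0.05·pathway size⌉) under the NTP rule — 10 genes
for a 198-gene pathway.

## Matrices

Cells without an estimable BMC (no response, unreachable, failed fit) are
imputed at the compound's top tested concentration in µM metal (multiplier
configurable, default ×1) — the standard "no observed BMC at or below the
top dose" surrogate. Winsorization is per endpoint column at the (5th,
95th) percentiles using order-statistic replacement (the
`scipy.stats.mstats.winsorize` convention: the ⌊q·n⌋ most extreme values
take the adjacent order statistic). This convention was chosen over
interpolated-quantile clamping because it is idempotent and never
manufactures values absent from the column; at n = 18 compounds the default
(0.05, 0.95) pair replaces no values (⌊0.9⌋ = 0), so winsorization only
bites for wider quantile settings or larger compound sets. log10 is applied
once, centrally, after imputation.

## Ensemble clustering and AU support

Compounds are clustered on endpoint columns under 12 configurations: 4
linkages (complete, average, single, Ward) × 3 distances (euclidean,
manhattan, minkowski). The Minkowski exponent is unstated in the underlying
convention (p = 2 would duplicate euclidean), so the default is p = 3,
configurable and logged. Ward on non-euclidean dissimilarities applies the
Lance–Williams update to the supplied distances, mirroring common
`ward.D2`-on-dissimilarity practice. Columns are not standardised before
distance computation (matrices are already log10; PCA scaling is separate).

Multiscale bootstrap resamples the **features** (endpoint columns) with
replacement at sizes round(r·n) for r = 0.4, 0.5, …, 1.4 and re-clusters
the compounds; with only 7 features the small scales realise coarsely
(e.g. round(0.4·7)/7 = 3/7), which the fit absorbs by regressing on the
realised scales. Scales below 2 features are skipped. Per original internal
node, the per-scale hit counts (exact member-set subtree recovery) are
converted to bootstrap probabilities. Scales with degenerate counts (0 or
nboot) carry no curvature information and are excluded from the fit — a
clamped constant z-profile would leave v − c unidentified and bias AU
toward ½ for clearly supported nodes. On the usable scales, BP is clamped
to [0.5/nboot, 1 − 0.5/nboot] and z_r = Φ⁻¹(1 − BP_r) is regressed on
(√r, 1/√r) by weighted least squares with binomial-variance weights
w_r = nboot·φ(z_r)²/(BP_r(1−BP_r)), giving the signed distance v and
curvature c: AU = 1 − Φ(v − c), BP = 1 − Φ(v + c). Fully degenerate nodes
(all counts 0 or all full) pin AU to 0 or 1; fewer than two usable scales,
or a failed fit, fall back to the raw BP at the scale nearest r = 1 with
`fit_ok = False`.

Supported clusters are nodes with AU > 0.95, excluding the root (otherwise
every pair trivially co-clusters); leaves are not clusters; nested supported
nodes are all reported. The best attempt maximises the supported-cluster
count, ties going to fewest singletons, then to the documented config order.
Across attempts the co-occurrence fraction (share of attempts in which a
pair shares at least one supported cluster) and the pooled-cluster Jaccard
index are both computed — the two readings of "Jaccard similarity" over a
binary cluster-inclusion matrix; reported group percentages use the
co-occurrence reading. A compound never entering a supported cluster keeps
zero rows (and a zero diagonal) by convention and is flagged. Potency groups
are connected components (size ≥ 2) of the co-occurrence graph thresholded
at 0.5 by default; cross-BMR grouping pools the four per-BMR ensembles by
concatenating their attempts (48 in total).

## Ordination and associations

PCA follows the correlation-matrix convention (columns centred, unit
variance, unit-norm eigenvector loadings); each component's sign is fixed by
making its largest-magnitude loading positive. Endpoints with
|loading| > 0.4 on the first two components are reported as significant
loaders. Spearman correlations between endpoint potencies use the combined
cross-BMR matrix (n = 72 rows for the full study) with average-rank ties
and pairwise-complete observations; Kendall τ-b against physicochemical
properties (form code 1/2/3, primary particle size, specific surface area,
% solubility) drops missing property rows pairwise and uses the exact
null distribution for n ≤ 10 without ties. The strength taxonomy
(negligible < 0.3 < weak < 0.5 < moderate < 0.7 < strong < 0.9 < very
strong) leaves gaps at its printed boundaries (0.30–0.31, 0.50–0.51, …);
these close downward, so e.g. |r| = 0.305 is negligible and 0.905 strong.
Endpoint–property tests pool BMRs exactly as the Spearman analysis does; a
per-BMR mode is available.

## Hazard rules

Boundary semantics follow the printed operators exactly: cell death iff
top-dose viability ≤ 0.66 (inclusive; the printed 66 % is used rather than
the 1/1.5 ≈ 66.7 % implied by "1.5-fold"); clastogenicity iff MN ≥ 2-fold
at any concentration with viability ≥ 0.40; DNA strand breaks iff
> 10 % tail DNA (strict); cell stress iff ≥ 3 responsive stress-pathway
genes. "Latest timepoint" means 48 h viability, 4 h comet, 40 h MN and 48 h
stress genes; a strict-24 h mode drops stress calls accordingly. Missing
inputs give an explicit negative call with an insufficient-data flag, never
a missing state; all calls are monotone in their inputs.

## Synthetic data: what it emulates and what it does not

The generator draws apical responses as mean-curve × exp(N(0, σ)) — the
same lognormal form the estimator assumes — and expression log2 ratios as
archetype mean shifts plus additive normal noise on a N(0, σ_null)
background, matching per-concentration log2-ratio matrices with replicates.
The default study mirrors the real design's scale: 18 compounds (4 dissolved
salts, 7 NPs, 7 MPs with their published molar masses, form codes, particle
sizes, surface areas and solubilities), 7 endpoints, 6 concentrations
(0–100 µg/mL), 3 replicates, 2 timepoints. Ground-truth group structure is
planted by assigning compounds to three archetype classes
(soluble/cytotoxic, genotoxic particle, insoluble/inert) whose rate
parameters are jittered per compound (lognormal, 0.15 log-SD) coherently
across endpoints — for Hill curves the ED50 divides by the jitter so
"more potent" means the same thing in every model family.

The generator does **not** emulate probe-level microarray structure, dye or
normalisation effects, correlated gene–gene noise, batch effects, or
non-monotone dose responses. Passing tests therefore demonstrate that the
estimation and grouping machinery recovers truth under its own
distributional assumptions at realistic noise levels — not that the
pipeline is robust to violations a real microarray study would add upstream
of the log2-ratio matrices it consumes.

Replicate counts per endpoint in the emulated studies are not asserted
anywhere; they are configurable defaults (3).

## Problem sizes and seeds

Tests and the acceptance script run reduced-but-real sizes chosen as the
package's own defaults for fast verification: ensembles at nboot = 100 or
below (the analysis default is 1000), 40–60-gene expression panels for
end-to-end runs, 2000 genes for the type-I-error check, and the planted
two-archetype recovery at a 5×-noise effect. All randomness flows from one
master seed through a documented child-seed scheme (a stage/entity-tagged
64-bit mix reduced mod 2³¹−1), so every artifact is reproducible byte for
byte from the run manifest.

## Known limitations

* AIC-weight averaging is not ToxicR's Bayesian averaging; gene BMCs can
  differ in detail from BMDExpress3-based analyses.
* The covariate structure (level-specific a, b) is one point in a larger
  model-selection lattice; no BMDL/BMDU confidence bounds are produced.
* With 7 features the multiscale-bootstrap scale grid realises only 4
  distinct resample sizes (3–10 features), so AU estimates on real-scale
  matrices carry appreciable Monte-Carlo and extrapolation error; nboot
  should stay at 1000 for production use.
* The exact filtering/winsorization recipe behind published matrices is
  generally not recoverable from a methods section; every knob here is
  config-exposed, and externally published matrices should be injected
  directly into the `cluster`/`stats` stages rather than re-derived.
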