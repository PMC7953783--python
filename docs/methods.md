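# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `spectroselect`.  Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The inference problem

Nine beef-quality traits are measured in the laboratory on aged samples
(CIELAB L\*, a\*, b\*, C\*, h\*; pH; purge losses PL, %; cooking losses CL,
%; Warner-Bratzler shear force WBSF, N) and simultaneously *predicted* from
absorbance spectra collected on the intact muscle surface at the abattoir
one day after slaughter, on two instrument grids (Vis-NIR 350–1830 nm at
1 nm, 1481 points; Micro-NIR 905–1649 nm at 6 nm, 125 points; five replicate
spectra per animal).  The package estimates (i) how well the spectra predict
each trait out of slaughter batch, and (ii) the genetic architecture of the
predictions relative to the measurements.

## Stage 1 — spectral QC and Bayes B calibration

**Editing.**  The fixed pipeline order is: flag outliers → average
replicates → standardize.  Outliers are screened by Mahalanobis distance in
a principal-component subspace retaining 99% of variance, capped at 20
components (the raw covariance of >1,000 wavelengths is singular at these
sample sizes).  The standardized distance GH = D²/k is compared with a
conventional chemometric cutoff of 3 (configurable); under multivariate
normality GH ≈ χ²ₖ/k, which the tests verify distributionally.  Surviving
replicates are averaged to one spectrum per animal — the genetic analysis
needs one prediction per animal, and averaging before prediction is the
variance-optimal choice for a linear model.  Centering/standardization
parameters are always learned on the training portion only and applied to
held-out spectra, so no leakage enters external validation.

**Bayes B.**  For trait y and standardized covariates X (one per
wavelength), each effect β_j is zero with prior probability π (default
0.95) and otherwise N(0, σ²_j) with σ²_j ~ scaled-inv-χ²(df_b, S_b) —
marginally a scaled-t, so single wavelengths can carry large effects.  The
Gibbs sampler draws the inclusion indicator with β_j integrated out, then
β_j, then every σ²_j (from its prior when the effect is null), the
intercept, and σ²_e ~ scaled-inv-χ².  Scales follow the expected-R² rule
with R² = 0.5: the prior mode of (1−π)·Σ_j var(x_j)·σ²_β equals R²·var(y),
and the residual prior mode is (1−R²)·var(y); df_b = df_e = 5.  Defaults:
12,000 iterations, 2,000 burn-in, thinning 5, one chain, fixed seed
(identical seed ⇒ identical chain; the kernel is numba-compiled).  The
degenerate-model limit π→0 reproduces a BayesA-style sampler, which the
tests check against an independent plain-numpy implementation.

**Leave-one-batch-out validation.**  The slaughter batch (day) is the
dominant environmental grouping, so external validation holds out one
entire batch at a time, refits standardization and the sampler on the rest,
and accumulates held-out predictions over all batches; R²_EXT is the squared
Pearson correlation of accumulated predictions with measurements (pooled,
not averaged per batch).  Both instrument grids run through the same code
path with no wavelength pre-selection.

## Stage 2 — bivariate animal-model REML

For a (measured, predicted) pair,
y = Xβ + W₁c + W₂q + Zu + e with c ~ N(0, C⊗I) (herd), q ~ N(0, Q⊗I)
(batch), u ~ N(0, G⊗A), e ~ N(0, R⊗I); all blocks 2×2.  Fixed effects:
dam-parity classes (4) for pH, slaughter-age classes (5) for L\*, intercept
otherwise; a predicted trait inherits the rule of its base trait.  Herd and
batch levels with fewer than 3 records are dropped (iterated until stable;
counts logged).  A is built from the pedigree by the tabular method; its
sparse inverse by Henderson's rules with inbreeding from the kinship
recursion; log|A| = Σ log d_i comes free from the T D T′ decomposition and
enters the restricted likelihood.

**Estimation.**  The restricted log-likelihood is evaluated through sparse
mixed-model equations (one symbolic structure precomputed; per-evaluation
cost is one sparse LU with symmetric minimum-degree ordering).  The
maximizer is a Newton iteration using the average-information (AI) matrix,
with

* a finite-difference score (central by default, forward optionally),
* Levenberg damping adapted to line-search success, backtracking
  step-halving so the accepted likelihood trace is monotone non-decreasing,
* a **Cholesky parameterization** of every covariance block (Σ = LL′).
  This keeps blocks PSD without ad-hoc bending and, crucially, turns
  boundary optima — correlations of ±1, which are routine for herd/batch
  blocks of a measured trait and its own prediction — into smooth
  stationary points instead of bending-induced crawl.

Convergence: |ΔlogL| < 1e-8 and maximum relative parameter change < 1e-6,
with two safeguards: a flat-trace stop (three consecutive gains < 1e-7) and
acceptance of the iterate when neither the damped Newton nor the gradient
direction can improve the likelihood at numerical resolution.  Missing
single traits are handled by restricting each animal's residual block to
its observed traits (missing at random).  The asymptotic covariance of the
estimates is the inverse AI matrix at convergence; the tests verify it
against the numerical Hessian of an explicit dense restricted likelihood.
Internally each trait is scaled by its phenotypic SD; estimates, the
likelihood and the covariance are reported back on the natural scale.

**Derived parameters.**  Intra-herd heritability h² = σ²ₐ/(σ²ₐ+σ²ₑ)
(herd and batch variance excluded from the denominator — the formula is
applied literally); correlations r = cov/√(var₁ var₂) from the G and R
blocks, clipped to [−1, 1] with a flag; SEs by first-order delta method.
Variance ratios are reported as fractions of the phenotypic variance and
sum to 1 by construction; pH variances are flagged for ×100 display in
output tables, matching the convention of the published summaries.

## The synthetic-data generator

The generator defines the study conditions under which the machinery is
validated; its defaults mirror the motivating design: 204 sires × 1,286
dams → 1,327 progeny, 98 herds, 106 slaughter batches (≥3 animals per
retained level, enforced by rejection sampling with a deterministic repair
fallback), five replicate spectra per animal on both instrument grids, and
the published laboratory variance partitions for all nine traits (printed
ratios are rounded to two decimals and renormalized to sum to one).

* **Breeding values** follow the pedigree exactly: founders N(0, G),
  descendants parent-average plus Mendelian sampling with variance
  d_i G, d_i = ½ − ¼(F_s + F_d) using exact inbreeding coefficients.
* **Latent surface trait.**  Each measured trait is paired with the day-1
  muscle state the spectra can see.  The pair shares herd and batch
  effects and has configurable genetic and residual correlations; both
  default to 1.0, making latent ≡ measured, so that `spectral_info` alone
  controls attainable prediction accuracy.  The abattoir/lab discrepancy is
  therefore modeled statistically (set the correlations below 1), not
  mechanistically — no aging-chemistry model is attempted.
* **Spectra** are a smooth fixed baseline plus one unit-norm Gaussian
  loading bump per trait (fixed centers spread over the 950–1600 nm region
  common to both grids, width 30 nm), a batch-level flat drift
  (SD 0.02 absorbance), and white noise (SD 0.02).  The per-trait signal
  amplitude is calibrated in closed form so the best linear predictor of
  the standardized latent trait from replicate-averaged spectra attains the
  configured `spectral_info`, accounting exactly for cross-talk between
  overlapping bumps and for the drift direction (Woodbury).  Default
  `spectral_info` values follow the published Vis-NIR R²_EXT ladder (0.84
  for L\* down to 0.16 for WBSF).  A configurable fraction of replicate
  spectra (0.5% by default) is corrupted into gross spike or offset
  outliers for QC testing.

**What passing tests do and do not show.**  The generator's spectra are
far simpler than real NIR data (no scatter effects, no wavelength-dependent
noise, no trait cross-correlations); passing the ladder and recovery tests
shows the *inference machinery* is correct and calibrated under the stated
model, not that real spectra carry the assumed information.  Realized
R²_EXT falls below `spectral_info` in finite samples — estimating ~10²
coefficients from ~10² ·10 records costs accuracy, most visibly for
low-information traits — mirroring the attenuation any real calibration
shows, and the deficit shrinks with n and with the number of batches.

## Problem sizes used in the shipped checks

Chosen as the smallest sizes at which the statistical assertions are
stable: parameter recovery uses 20 replicates of n = 2,000 progeny
(100 sires, 100 herds, 100 batches) with h² = 0.30/0.15, r_a = 0.9, herd
and batch fractions 0.06/0.20, nuisance correlations 0.8 (herd/batch) and
0.5 (residual) to keep the optimum interior; the information ladder uses
n = 800 with 40 batches at five `spectral_info` levels; the permutation
null uses n = 500; gene-dropping uses 200,000 allele-drop replicates on a
50-animal pedigree.  Gibbs chains in the checks are shortened
(1,200–2,000 iterations) relative to the 12,000-iteration default — the
posterior means involved are stable well before that.

## Known limitations

* Unknown parents are unrelated non-inbred founders; no genetic groups.
* No scatter-correction pretreatments (SNV, MSC, derivatives) — the
  workflow this mirrors used none.
* The REML score is finite-difference based; likelihood evaluations are
  exact (verified against a dense oracle), but gradient noise near the
  optimum is absorbed by the damping/flat-stop logic rather than eliminated.
* Bivariate models only (one measured trait and one prediction at a time);
  no maternal effects; no genomic relationship matrices.
* The printed-table verifier checks aggregates against rounded published
  per-trait values; its tolerance (±0.015 on correlations/R², ±1.5
  percentage points on percentage aggregates) reflects that rounding.
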