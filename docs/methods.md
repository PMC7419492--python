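# Methods

## Population and data model

The package targets multi-parent populations formed as collections of
biparental crosses sharing a central parent (NAM designs), with doubled
haploid (DH) progeny. DH lines are fully homozygous: marker dosages are
0 or 2 copies of the minor allele, and residual heterozygous calls in
input data are treated as missing. Phenotypes are plot-level records
from augmented p-rep trials: per environment, entries laid out in
incomplete blocks nested in replicates, a fraction of entries
replicated, and repeated check genotypes partitioned out of the entry
term.

## Allele codings

At every map position the QTL regressor `x_ia` is the expected number of
copies of allele `a` carried by individual `i`:

* **Parental.** One allele per founder. For a DH line from cross
  (central × peripheral), parental origin along a chromosome follows a
  two-state Markov chain; the transition probability between adjacent
  markers `d` cM apart is Haldane's recombination fraction
  `r = (1 − e^(−2d/100))/2`. Markers where the two parents share a
  score (or any call is missing) are uninformative; elsewhere the
  progeny dosage identifies the transmitting parent, with genotyping
  error treated as zero (calls matching neither parent become missing).
  Forward–backward posteriors give `x = 2·P(origin)`, so each line's
  dosages over the two cross parents sum exactly to 2.
* **Ancestral.** Parents that are locally identical by state are merged
  into one ancestral allele. At each marker, pairwise parent similarity
  is the fraction of matching scores over markers within ±2 cM
  (falling back to the focal marker for empty windows), followed by
  single-linkage clustering at a similarity threshold (default 0.9,
  exposed as a parameter). The ancestral design equals the parental
  design post-multiplied by the class-membership matrix. This windowed
  IBS clustering is a deliberately simple local-haplotype model, not a
  kernel-smoothed one; the threshold default gives a NAM-scale
  simulation a handful of classes per position rather than one per
  parent.
* **Bi-allelic.** The SNP minor-allele dosage itself; missing calls are
  imputed by sampling from the within-cross allele frequency (population
  frequency if a marker is entirely missing within a cross), seeded.

Effects are deviations from a reference allele — the central parent's
allele, the ancestral class containing it, or the SNP major allele — so
the reference column is dropped from the fixed design. Allele columns
absent from the data (locally monomorphic crosses) are dropped with a
warning to keep designs non-singular; columns still collinear with the
structural effects are removed greedily left-to-right, which always
sacrifices the QTL column rather than the structure, and the Wald df
shrink accordingly.

## Marker quality control

Markers with folded minor-allele frequency below 0.05 or more than 10%
missing calls are removed (both thresholds are parameters). Among
markers mapped to the same (chromosome, position), the most polymorphic
is kept; equal frequencies keep the first in map order. QC is idempotent
and preserves marker order.

## Stage one: genotype BLUEs

The plot model is
`y_icep = μ + E_e + rep_l(e) + block_m(le) + G_ic + GE_ice + ε_icep`
with environment and genotype fixed, replicate and block random with one
variance each across environments, a homogeneous genotype-by-environment
variance, and iid plot error. (Cross-specific G×E variances are not
attempted: with partial replication between environments they are
frequently inestimable.) Fitting jointly across environments yields
across-environment BLUEs; dropping `E_e` and `GE_ice` and fitting one
environment yields within-environment BLUEs. A BLUE is reported as
intercept + mean environment effect + genotype effect, so adding a
constant to all plots shifts every BLUE by that constant, and under
balance with zero-variance random effects BLUEs reduce to cell means.
Reported BLUE standard errors are those of the genotype-effect deviation
(zero for the reference level). Stage-one BLUEs are carried to stage two
unweighted; no weighting scheme is implemented.

## Covariance structures and REML

All models share the marginal form
`V(θ) = Σ_k σ²_k Z_k Z_kᵀ + Σ_s φ_s I_s`: random-term contributions
(replicate, block, and the compound-symmetry genotype main effect that
links the same genotype across environments) plus stratum-wise residual
variances. The strata implement cross-specific errors (M1/M2) and
environment-cross-specific errors (ECSE; M3/M4, one variance per
(cross, environment) cell, checks in their own per-environment
stratum). Observations from different crosses are independent; the
genotype term supplies the `σ²_g` covariance between environments.

Variance parameters are estimated by REML on the log-variance scale
with an analytic gradient (bounded L-BFGS-B, lower bound 1e−8 × the OLS
residual variance; components ending at the bound are reported as 0).
Two starting points are used — an equal split of the OLS residual
variance and a residual-dominant split — except inside genome scans,
where each position warm-starts from the previous optimum with a single
start. Convergence is declared on optimizer success or an essentially
zero gradient (the line search can fail exactly at a warm-started
optimum); non-converged positions enter scan profiles as missing rather
than aborting the scan. Saturated designs (n = p) return the exact
solution with no variance estimates. Fixed effects follow by GLS at the
optimum.

Wald tests are marginal: each term is tested given all other terms in
the model, `W = β̂ᵀ V(β̂)⁻¹ β̂` against a chi-square with df equal to
the number of coefficients tested (`n_a − 1` for main-effect QTL terms,
`N_e (n_a − 1)` for environment-specific ones; a singular sub-covariance
falls back to a generalized inverse with df equal to its rank).
Sequential conditional testing, whose outcome depends on term order, is
deliberately not implemented. `−log10 p` uses the chi-square log
survival function, switching to the asymptotic expansion of the upper
incomplete gamma function where the survival function underflows
(p below ~1e−308), so scan profiles stay finite.

## Detection procedure

Simple interval mapping (SIM) fits the method's model with a single QTL
term at every marker position (marker positions only; no pseudo-marker
grid). Cofactors are chosen greedily from the SIM profile: repeatedly
take the highest −log10 p ≥ 4, excluding positions within 50 cM on the
same chromosome; ties prefer the smaller chromosome, then the smaller
position. Composite interval mapping (CIM) repeats the scan conditioning
on all cofactor QTL terms except those within an exclusion window
(default 50 cM, matching the cofactor spacing) of the tested position on
its chromosome. Candidate QTLs are selected from the CIM profile with
the same greedy rule at 20 cM, then pruned by backward elimination:
refit the joint multi-QTL model, drop the least significant QTL while it
is below threshold. QTL positions from different methods are declared
the same QTL when separated by less than 10 cM (single linkage per
chromosome, so chains merge — a documented consequence of the rule).
Permutation thresholds are intentionally absent; a Bonferroni threshold
(−log10(α/n_tests)) is available instead.

## Environmental sensitivity

For a QTL with environment-specific effects in M3/M4 data, the block
`x_ia β_ae` is re-parameterized as
`x_ia (β_a + Z_e γ_a + δ_ae)`: a main effect at the covariate reference
level, a linear sensitivity per covariate unit, and a random residual
QTL×E term. The covariate is centered by subtracting the reference
environment's raw value (a configuration choice, e.g. the driest site).
With two environments the decomposition is a exact reparameterization
and δ is dropped (inestimable); with three or more, δ gets one variance.
Low-carrier alleles are retained but flagged (default minimum 10
carriers) since their estimates and SEs inflate. The homozygous
contrast of the reference allele versus allele `a` at covariate level Z
is `−2(β_a + Z γ_a)` — positive when the reference allele is favourable
— with a delta-method SE from the coefficient covariance; it is affine
in Z with slope `−2γ_a` exactly.

## Simulator

The generator emulates the study design end to end: founder genomes
(central parent as reference; peripheral parents carrying the
alternative allele at a configurable fraction of markers, default 0.3),
DH meiosis as a Poisson crossover process without interference
(consistent with the Haldane function used in IBD), and phenotypes from
the one-stage generative model — environment shifts, random replicate
and block effects, fixed cross-by-environment effects, planted QTL
effects per parental allele and environment (optionally linear in a
covariate), a shared genotype main effect (σ²_g = 35) and
environment-cross-specific plot error (mean 65, ±30% spread across
cells). Those defaults give a single-plot between-environment genotypic
correlation of 0.35 and a line-mean heritability near 0.5, the regime
the methods are meant for; layout defaults (one third of entries
replicated, blocks of eight with one check plot each) mirror a dense
NAM field trial, as does the default map (10 chromosomes × 158 cM at
3.8 markers/cM ≈ 5950 markers). The simulator does not model founder
linkage disequilibrium, crossover interference, genotyping error, or
spatial field trends — so passing tests validate the estimators under
the stated model, not robustness to those features of real data.

Tests and examples run scaled-down configurations (2–4 crosses of 30–60
lines, 1–2 chromosomes, 10–20 markers each); the planted-QTL recovery
suite uses 50 replicates of 3 crosses × 40 DH × 2 environments with a
7 dt/ha environment-specific QTL, sized so the whole suite completes on
one CPU in minutes.

## Numerical and design notes

* One- versus two-stage: M4 profiles track M3 closely but not exactly
  even in the degenerate balanced case with zero design variances,
  because the plot-level fit also uses within-cell replicate contrasts
  to estimate its residual variance; the agreement tested is
  correlation > 0.995 and |Δ(−log10 p)| < 0.5 on a toy.
* With one environment, M3's CS+ECSE family is over-parameterized along
  a ridge (σ²_g trades off against every cell variance), but every
  ridge point implies the same total covariance, so profiles coincide
  with M2's.
* All randomness flows from explicit integer seeds (imputation,
  simulation); repeated runs are bit-identical.
* File formats are plain CSV with documented schemas plus a JSON run
  manifest (config, seed, package version) for exact reruns; the CLI is
  a thin layer over the library.

## Limitations

Unstructured or cross-specific genotypic covariances, multi-trait and
longitudinal extensions, EMMA-style approximations, spatial field
models, confidence intervals for QTL location, and permutation-based
thresholds are out of scope. The ancestral clustering is a local-IBS
approximation to haplotype-based ancestry; physical (bp) coordinates
are not handled. The dense REML solver is comfortable to a few thousand
observations; genome scans on much larger one-stage datasets would need
sparse or approximate methods.
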