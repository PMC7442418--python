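# Methods

## The model

`mrscreen` implements two-sample Mendelian randomization (MR) for
summary-level GWAS data. For SNP *j*, let γ_j be its per-allele effect on a
continuous exposure (in SD units of the trait) and Γ_j its per-allele effect
on a binary outcome (log-odds). Under the instrumental-variable assumptions
(the SNP is associated with the exposure, independent of confounders, and
affects the outcome only through the exposure), all instruments share

    Γ_j = θ · γ_j,

where θ is the causal log-odds of the outcome per SD of the exposure,
reported as OR_SD = exp(θ) with a normal-theory 95% CI. Only summary
statistics (β̂, SE pairs from two non-overlapping studies) are consumed;
no individual-level data.

## Estimators

* **Wald ratio** (single SNP): θ̂_j = β̂_yj / β̂_xj. Default SE is the
  first-order delta-method expression se_yj / |β̂_xj| — the dominant
  two-sample convention, in which exposure-side uncertainty is ignored
  because instruments are genome-wide significant; the second-order form
  √(se_y²/β_x² + β_y²·se_x²/β_x⁴) is available by flag.
* **IVW-FE**: inverse-variance-weighted fixed-effects mean of the per-SNP
  Wald ratios, w_j = 1/se(θ̂_j)², θ̂ = Σw_jθ̂_j/Σw_j, SE = (Σw_j)^(−1/2),
  with no overdispersion rescaling. With first-order ratio SEs this is
  exactly weighted least squares of β̂_y on β̂_x through the origin with
  weights 1/se_y² (an oracle equivalence the tests verify to 1e-10).
* **Profile maximum likelihood**: observed (β̂_xj, β̂_yj) are modelled as
  independent normals around (γ_j, θγ_j) with known SEs and zero
  cross-trait correlation (non-overlapping samples). The per-SNP nuisance
  means profile out analytically, leaving the concentrated log-likelihood
  ℓ(θ) = −½ Σ (β̂_yj − θβ̂_xj)² / (se_yj² + θ²se_xj²), maximized by a damped
  Newton iteration on the score (tolerance 1e-8, max 200 iterations,
  iteration trace carried on failure); the SE comes from the observed
  information of the profile likelihood, evaluated by central differences.
* **Weighted median**: order the ratios ascending with normalized
  inverse-variance weights; the standardized cumulative weight at the j-th
  order statistic is p_j = (S_j − w_j/2)/S_total and θ̂ interpolates
  linearly to p = 0.5. Consistent when valid instruments carry ≥ 50% of
  the weight. SE by seeded parametric bootstrap (default 1000 resamples of
  β̂_x, β̂_y from their sampling normals, weights recomputed per resample).
* **Weighted mode**: θ̂ maximizes a weighted Gaussian-kernel density over
  the ratios. Bandwidth is φ × 0.9·min(sd, 1.4826·MAD)·k^(−1/5) with φ = 1
  by default; the maximizer is located on a 2048-point grid and refined by
  bounded scalar minimization, so the point estimate is deterministic.
  Degenerate spread (all ratios identical) returns that common value.
  Consistent when the largest homogeneous cluster of instruments is valid.
  SE by the same parametric bootstrap (coarser 512-point grid per resample).
* **MR-Egger**: orient every SNP to a positive exposure effect (negating
  both betas where needed — done on a copy, never mutating caller data),
  then weighted regression of β̂_y on β̂_x *with* an intercept, weights
  1/se_y². The slope is the pleiotropy-adjusted effect; the intercept
  estimates the average directional (unbalanced horizontal) pleiotropy,
  tested with a two-sided normal p.

All p-values are two-sided normal rather than t — the summary-data MR
convention; with very few instruments this is mildly anti-conservative, a
known trade-off documented here rather than hidden.

### Egger standard errors: a deliberate convention choice

Some MR toolkits inflate Egger SEs multiplicatively by the residual SD
(max(1, σ̂)). This package uses plain fixed-effect SEs, √diag((XᵀWX)⁻¹),
matching the fixed-effects convention of the rest of the suite (the IVW
estimator is explicitly fixed-effects). The multiplicative convention has a
structural pathology in exactly the setting the intercept test exists for:
under a mixture of valid and directionally pleiotropic instruments, the
between-group separation inflates σ̂ proportionally to the pleiotropy
magnitude, so the intercept z-statistic *saturates* (at ≈ 1.2 for 30
homogeneous-strength instruments with 40% invalid) and the test can never
attain majority power regardless of how strong the pleiotropy is. The cost
of the fixed-effect choice is anti-conservative intercept tests under
balanced heterogeneity; users comparing against σ-inflating implementations
should expect smaller SEs here.

## Instrument selection

Instruments are admitted at genome-wide significance (P ≤ 5×10⁻⁸,
boundary inclusive), then greedily clumped on a caller-supplied r² matrix:
rank by |β| descending (ties: smaller p, then snp_id — a total order, so
clumping is invariant to input order), accept the top SNP, discard
everything with r² ≥ 0.01 against it, repeat. A SNP absent from the LD
matrix is a hard error, never assumed independent. Per-SNP instrument
strength is F = (β/se)², summarised by the mean with the conventional
weak-instrument flag at mean F ≤ 10 (both per-SNP and mean values are
exposed, since screening conventions differ).

## Harmonization

Outcome alleles are reconciled to the exposure's effect allele by identity,
swap (outcome effect negated, frequency complemented), strand complement,
or complemented swap, in that order; anything else is recorded as
`dropped_incompatible`. Palindromic SNPs (A/T, C/G) are dropped by default —
the conservative two-sample choice, since allele labels carry no strand
information. The permissive policy keeps them only when both studies report
an allele frequency outside 0.5 ± 0.08 on the same side of 0.5; a missing
frequency drops the SNP. Every shared SNP leaves the step with a recorded
orientation action, so counts always reconcile.

## Decision rules

* **Multiplicity**: a screen of *n* exposures uses the Bonferroni-corrected
  threshold α/n (0.05/37 = 1.35×10⁻³ for the default 37-trait screen).
  Classification is strict: p < α/n is significant, α/n ≤ p < α is
  suggestive, otherwise null; `n_tests` is a config value decoupled from the
  number of exposures in a particular run so partial runs keep the screen's
  correction.
* **Leave-one-out**: re-estimate (IVW-FE by default; bootstrap methods
  opt-in, with per-exclusion seeds derived deterministically from the run
  seed) with each SNP removed. A SNP is a *driver* iff the full estimate is
  significant at α and the estimate without it is not — an operational
  version of "the association was reliant on a single SNP". Drivers whose
  excluded-p lies within [α, α+0.01] are additionally flagged near-drivers
  (the borderline pattern where removal weakens rather than collapses an
  association). Note this rule inherits an irreducible ≈ α false-retention
  rate: when the remaining instruments are truly null their excluded-set
  p-value is uniform, so ~5% of genuine driver scenarios will not flip.
  Validation therefore measures detection as a frequency over seeds.
* **Concordance**: an association is *consistent* iff IVW-FE, MLE, weighted
  median and weighted mode agree in the sign of θ and all have p < α.
* **Power**: for a binary outcome the test statistic has approximate mean
  ncp = |θ|·√(n·R²·cf·(1−cf)) where R² is the exposure variance explained
  by the instruments and cf the case fraction. Power sums both rejection
  tails, Φ(−z_{1−α/2}+ncp) + Φ(−z_{1−α/2}−ncp), so it reduces to α exactly
  at θ = 0 (a one-tail version would give α/2 and violate the null limit).
  The detectable OR_SD at a target power inverts this by Brent root-finding
  on θ > 0. Outputs are approximate and labelled as such in the manifest.

## The synthetic-data generator

Summary statistics are simulated directly — the quantities two-sample MR
consumes — rather than via individual-level genotypes, keeping the whole
validation suite in seconds. Per SNP: maf ~ U(0.1, 0.5);
γ_j ~ N(0.04, 0.01) SD/allele; a direct (pleiotropic) outcome effect α_j,
zero for valid instruments; true outcome effect θγ_j + α_j; observed betas
drawn with the large-sample SEs se_x = 1/√(2·maf(1−maf)·n_x) and
se_y = 1/√(2·maf(1−maf)·n_y·cf(1−cf)). Defaults are chosen to emulate the
screening design the package targets:

| parameter | default | rationale |
|---|---|---|
| n_exposure | 100 000 | large continuous-trait GWAS |
| n_outcome | 30 657, cf = 0.407 | a glioma-scale case-control meta-analysis (12 488 cases / 18 169 controls) |
| γ distribution | N(0.04, 0.01) | per-SNP F ≈ 60–70 at these sample sizes — strong instruments, comfortably past the F > 10 screen, with most SNPs at genome-wide significance |
| invalid fraction | 0 (presets: 0.4) | pleiotropy scenarios mirror the ≥ 50%-valid-weight regime the weighted median targets |
| pleiotropy magnitude m | 0.08 log-odds | directional α_j ~ N(m, m/2) puts the invalid instruments' Wald-ratio shift (m/γ̄ = 2) at ≈ 4× the per-SNP ratio noise (se_y/γ̄ ≈ 0.45) — material, detectable pleiotropy, the regime the robust estimators are designed for; balanced α_j ~ N(0, m) |
| driver outlier | +0.4 log-odds (≈ 20 outcome SEs) on one SNP | dominates the full-set IVW decisively (z ≳ 3 even when the outlier's own instrument strength is two SDs below its mean), so the leave-one-out flag isolates exactly one SNP |

The α_j are drawn independently of γ_j, so the InSIDE condition holds by
construction; exposure and outcome noise are independent (non-overlapping
samples). What the generator does **not** emulate: LD between instruments
(the clumping step is exercised with explicit synthetic r² matrices
instead), winner's-curse bias in discovery-significant effect sizes,
sample overlap between studies, population stratification, and non-collapsibility
of the odds ratio (the "true" θ is defined on the linear log-odds scale).
Passing validation therefore demonstrates correctness of the estimators and
decision rules under the stated sampling model, not robustness to these
real-data complications.

## Validation experiments and problem sizes

The acceptance script and the statistical test suite run, per seed:
parameter recovery and CI coverage (500 all-valid replicates, 30
instruments, θ = 0.2); type-I error (2000 null replicates); robustness
separation (200 directional-pleiotropy replicates, comparing weighted-median
and IVW absolute bias and the Egger intercept detection rate); driver-SNP
detection (50 replicates of the driver scenario, scored as the frequency of
exact single-SNP identification); and a 37-exposure null screen repeated
100 times (mean counts of suggestive-or-better and Bonferroni-significant
calls). These sizes keep every experiment to seconds while leaving
Monte-Carlo error well inside the asserted tolerances (3 Monte-Carlo or
binomial SEs throughout). The cross-method concordance check uses θ = 0.3
with a 200 000-sample, 50%-case outcome study: the mode-based estimator is
markedly less efficient than IVW, and only at that scale does joint
significance of all four methods become the ≥ 95% norm.

## Numerical choices and degenerate inputs

* Ties in clumping rank break by p-value then snp_id (total order →
  deterministic, order-invariant output).
* β_exposure = 0 makes a Wald ratio undefined → explicit error, never ∞.
* An empty instrument set after selection or harmonization is an error at
  the estimator layer; the study runner records the exposure as skipped
  (with a reason) and continues.
* Egger with no leverage (all oriented exposure effects equal) raises a
  singular-design error.
* All bootstrap and simulation randomness flows through
  `numpy.random.default_rng` seeds; run-level seeds fan out to per-method
  and per-exclusion child seeds via integer draws below 2³¹, so results are
  bit-reproducible for a given configuration.
* Study outputs (TSV tables, JSON manifest) are byte-identical across
  repeated runs of the same configuration; the manifest carries a SHA-256
  hash of the canonical config, the seeds, and library versions.

## Known limitations

Random-effects IVW, MR-PRESSO-style outlier correction, multivariable MR
and correlated-instrument (generalized) IVW are out of scope. Binary
exposures are not supported (two-sample MR with binary exposure and binary
outcome yields poorly interpretable causal estimates). Proxy-SNP lookup,
genome-build liftover and reference-panel LD queries are deliberately
excluded: the clumping step takes an explicit LD matrix so the pipeline is
fully deterministic and offline. The per-trait exposure R² needed for
exact power calculations must be supplied by the user; the power module is
an approximation and labelled as such.
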