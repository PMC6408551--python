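# Methods

This note documents the statistical models, the synthetic-cohort generator,
and the numerical and design choices behind `chromx`.

## Genotype representation and PLINK I/O

Calls count copies of the minor (A1) allele. Females take 0/1/2; males are
hemizygous and take 0/1 internally. Only the PLINK-1 variant-major binary
dialect is supported (mode byte 0x01; sample-major files are rejected), since
that is how X-linked candidate-gene filesets are deposited. On disk, male X
genotypes follow the usual "0/2" storage convention (a hemizygous A1 call is
stored as the homozygous-A1 bed code); the reader inverts this, and parks the
biologically impossible male heterozygote bed code at a marker value that only
`validate_x_males` may clear — it sets such calls missing (rather than
dropping the sample or coercing the call) and reports the count. Setting
missing is the conservative choice: the sample's other markers carry no
evidence of error. fam sex code 0 (unknown) excludes the sample with a
warning; an unparseable phenotype code leaves the obesity group unset rather
than failing the read.

Minor-allele frequencies are X-aware throughout: a female contributes two
allele observations, a male one.

## QC battery

Five per-variant rules with inclusive pass boundaries, following standard
X-chromosome recommendations:

| rule | statistic | pass condition (default) |
|---|---|---|
| sex frequency | Fisher exact on allele counts × sex | P ≥ 0.05 |
| female missingness | missing-call rate in females | ≤ 0.02 |
| differential missingness | Fisher exact on (missing, called) × sex | P ≥ 1e-7 |
| per-sex MAF | X-aware MAF per sex | ≥ 0.01 in each sex |
| HWE | exact test, control females only | P ≥ 1e-4 |

Hardy–Weinberg equilibrium is tested in control (normal-BMI) females only:
males carry one X and cannot deviate, and using controls avoids confounding a
true association with apparent disequilibrium. The exact HWE test enumerates
all heterozygote counts compatible with the observed allele counts under
P(n_het) ∝ n!·2^n_het / (n_AA! n_Aa! n_aa!) and sums configurations no more
probable than the observed one; an exact test is required because the pass
thresholds are tiny tail probabilities where chi-square approximations fail.
Two-sided Fisher P values use probability-mass ordering (the convention of the
standard genetics tool chain); the implementation delegates to
`scipy.stats.fisher_exact` and the test suite checks it against full
enumeration for all table totals up to 60.

Missingness and sex-frequency failures are report-only by default while MAF
and HWE failures exclude the variant. Candidate-gene panels routinely retain
a marker that trips a missingness recommendation (the emulated study's own
tag SNP does); `exclude_on` makes every rule's consequence configurable.

## Haplotypes and LD

`em_haplotype_freqs` runs EM over the 2^k haplotypes of k SNPs (refused above
k = 12). Males are fully phased single-chromosome observations; a female
genotype contributes a sum over compatible ordered haplotype pairs, with
missing sites summed over. The E-step weights pair (h1, h2) by f(h1)·f(h2);
the M-step re-estimates frequencies from expected counts over the
2·n_female + n_male chromosomes. Initialisation is at linkage-equilibrium
product frequencies, which makes the fit deterministic; iteration stops when
the largest frequency change falls below 1e-8 (default) or at 1000
iterations. The log-likelihood is non-decreasing by construction and the test
suite verifies it, along with agreement with a direct likelihood maximiser on
2-SNP problems.

Pairwise LD comes from the 2-SNP EM fit: D = p_AB − p_A·p_B, D′ = |D|/D_max,
r² = D²/(p_A q_A p_B q_B). Haploblocks use the solid-spine rule: a block
[i..j] is valid when D′(i, j) ≥ 0.8 and both endpoints are in strong LD with
every intermediate SNP; a greedy left-to-right scan takes the maximal valid
extension at each start. This is the concrete reading of "solid spine of LD"
implemented by the standard haplotype-visualisation tool. The multiallelic D′
between two adjacent blocks treats each block haplotype as one allele and
averages the biallelic |D|/D_max over haplotype pairs weighted by p_i·q_j.

Tag SNPs are selected by greedy pairwise capture: repeatedly take the SNP
whose r² ≥ 0.8 neighbourhood covers the most uncaptured SNPs, ties to the
lower map position. LD is computed per sex stratum (X LD can differ by sex)
and pooled; tagging uses the pooled estimates.

Haplotype association regresses the phenotype on posterior expected haplotype
dosages (reference = most frequent haplotype; haplotypes below 1% pooled as
"rare"). Haplotypes whose EM frequency corresponds to less than half a
chromosome of expected count are treated as absent rather than pooled — the
EM leaves numerical dust on phase-ambiguous configurations, and pooling dust
would create a near-degenerate design column that distorts the omnibus test's
numerator degrees of freedom. The omnibus statistic is a restricted-vs-full F
test whose numerator df is the rank the haplotype columns actually add
(likelihood-ratio chi-square in the logistic case).

## Association models

Sex-stratified OLS under the escape coding is the primary analysis; the
random-XCI coding is available as a parallel model. Inference is a Wald t
test with 95% CI = beta ± t_{0.975,df}·SE (normal-based for logistic).
Missing data are handled by listwise deletion, matching the per-cell sample
sizes a published table reports. Logistic fits flag |beta| > 15 or failed
convergence as (quasi-)separation; the Newton step falling over triggers a
BFGS retry that diverges gracefully instead.

The pooled-sex score test (see README for the formulas) stratifies by sex,
uses the random-XCI dose, and is asymptotically chi-square(1); with a single
stratum it reduces algebraically to the classic trend score test, which the
suite checks numerically. Its calibration target (empirical type-I error
within [0.04, 0.06] at alpha = 0.05, n = 915) is validated by simulation
rather than by value-matching an external implementation.

The conditional joint model enters all block SNPs into one OLS fit and
reports per-SNP conditional Wald P plus variance-inflation factors; an
exactly collinear pair keeps the earlier SNP in map order. Power for small
effects uses the noncentral-F formulation with ncp = f²·n for the f²
effect-size scale.

## Multiple testing

`adjust` wraps `statsmodels.stats.multitest.multipletests` for Bonferroni,
Holm, Hommel, BH and BY, with results clipped to [raw, 1]. The default family
groups all sex-stratified tests of one phenotype and model (7 SNPs × 2 sexes).
That family definition was fixed by exact reverse-verification: BH over the
14 published raw P values reproduces every printed FDR value to 4 decimals,
and no other grouping does. Families for secondary tables are configurable
because their published groupings are not uniquely recoverable. Hommel is
validated against brute-force closed testing (all 2^m − 1 Simes intersection
tests) for m ≤ 6.

## Synthetic-cohort generator

The generator emulates the structure of the childhood-obesity cohort the
pipeline was built for; defaults are frozen and are not tuning knobs.

* **Cohort**: 915 children, 438 boys / 477 girls; obesity case/control label
  drawn from a logistic liability on the BMI z-score (intercept −0.8, slope
  1.4, giving ≈ 72% cases as in the emulated study, where cases pool the
  obese and overweight groups).
* **Markers**: 7 X-linked SNPs in two blocks (3 + 4) at Xq22-like positions,
  drawn as haplotypes — two per girl, one per boy. Block-1 pool: minor-allele
  frequencies 0.27/0.29/0.31 with D′ = 1 inside the block. Block-2 pool:
  MAFs 0.40–0.47, pairwise D′ 0.88–1.0, with the third marker (rs4828038) the
  block's single tag at population r² ≈ 0.83–0.84 to the others while
  non-tag pairs sit at r² ≈ 0.63–0.69. The pool was designed analytically
  from these population-LD targets (the qualitative layout of the emulated
  study's LD figure), not fitted to data.
* **Between-block LD**: blocks are coupled by an inverse-CDF draw on a shared
  uniform and broken with recombination fraction 0.5, yielding multiallelic
  D′ ≈ 0.5 — partial inter-block LD.
* **Phenotypes**: Gaussian (or log-normal for insulin, triglycerides and
  IL-6) around study-like means and SDs, with age (and height) covariate
  terms. The BMI z-score carries the planted genetic effect: +0.65 per minor
  allele in boys and +0.11 in girls on rs2073162 under the escape coding,
  with residual SD 1.0 (the natural unit of a z-score). HOMA-IR
  (glucose·insulin/405) and QUICKI (1/(log10 insulin + log10 glucose)) are
  derived from fasting glucose (mg/dl) and insulin (mU/l) — the standard
  constants, which the emulated study cites without printing. Insulin is
  generated and labelled in mU/l.
* **Missingness**: missing-completely-at-random within sex, per SNP. The
  first marker emulates the panel's one low-call-rate assay (~7%) and the
  block-2 tag carries excess male missingness, so the QC battery has
  realistic work to do. Phenotype columns have independent MCAR missingness;
  derived indices inherit their parents'.

What the generator does **not** emulate: genotyping-intensity cluster
structure, population stratification, a real recombination map,
non-Gaussian phenotype tails beyond the log-normal traits, informative
(non-MCAR) missingness, and the real cohort's residual BMI z-score variance
(back-solving the published SE suggests a residual SD near 2.3; the generator
uses 1.0, so simulated test statistics for the planted effect are larger than
the published ones). Passing tests therefore demonstrate correctness of the
statistical machinery under a faithful structural model, not reproduction of
the original cohort's effect estimates — which would require the
access-controlled genotypes.

## Numerical choices and degenerate inputs

* Fisher two-sided P: probability-mass ordering with relative tie tolerance
  1e-7 (enumeration oracle side).
* EM: tolerance 1e-8 on frequencies, 1000 iterations, deterministic
  initialisation; k > 12 refused.
* Monomorphic pairs yield NaN LD flagged as undefined; a degenerate block
  (single haplotype) yields NaN multiallelic D′.
* Constant dosage, a single outcome class, rank-deficient covariates, and
  empty strata raise informative errors rather than returning numbers.
* Reported tables round beta to 2 d.p. and P to 4 d.p.; internal precision is
  full, and adjusted P values are computed before rounding.

## Problem sizes used in validation

Calibration experiments use 5000 null replicates at the study's sex split;
recovery experiments use 200 simulated cohorts of n = 915; structural checks
use 10 independent cohorts. These sizes put Monte-Carlo error comfortably
inside the validation bands (binomial SE ≈ 0.003 at 5000 replicates for a
0.05 rate).

## Known limitations

* The solid-spine and tagging heuristics are greedy; they match the reference
  tool's behaviour but are not globally optimal (the suite bounds the tag set
  at exhaustive-minimum + 1).
* The pooled-sex score test is the quantitative-trait form; the 2-df variant
  and covariate-adjusted score tests are not implemented.
* Sample-level QC (relatedness, heterozygosity outliers) is out of scope.
* With the frozen block-2 LD targets, the planted SNP's strongest proxy sits
  at population r² ≈ 0.83, which caps the probability that the causal SNP
  out-ranks its proxies in a single cohort at roughly 0.90 — a structural
  property of candidate regions in strong LD, visible in the acceptance
  summary's top-rank rate.
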