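# Methods

## Data model

All analyses operate on a `Cohort`: a panel of biallelic markers, each
oriented to its **risk allele** (A1), and per subject a case/control
phenotype, a risk-allele dosage d ∈ {0, 1, 2} per marker (NaN when
missing) and three covariates (age in years, sex, BMI in kg/m²). Dosage is
deliberately stored with respect to the risk allele, not the minor allele:
minor-allele frequency is always recomputed from pooled counts and folded
to ≤ 0.5 at reporting time, with the unfolded risk-allele frequency
reported alongside so the orientation is never ambiguous. For the ABO
insertion/deletion (rs8176719) the deletion allele is the literal token
`DEL` in cohort tables; in VCF input it is matched as the shorter of the
REF/ALT alleles at the site, since VCF encodes indels with an anchor base.

Missing-data policy: association tables are complete-case per marker;
risk-score and ROC analyses drop subjects with **any** missing dosage. No
imputation, phasing or liftover is attempted.

## Marker QC

Expected heterozygosity is 2p(1−p) at the sample allele frequency. HWE is
tested on the pooled sample by default (one QC column per marker) with two
methods:

* **chi2** (default): 1-df goodness-of-fit of the three genotype counts
  against p², 2pq, q² at the estimated allele frequency, no continuity
  correction;
* **exact**: the conditional exact test — the probability, given allele
  counts, of all heterozygote counts no more probable than the observed
  one.

The two tests agree closely in the rejection region but can differ
noticeably (up to ~0.2) in the middle of the p scale for low-MAF markers,
where the exact conditional distribution is coarse and the test
conservative; both are exposed for that reason. A monomorphic marker
yields χ² = 0, p = 1 rather than an error. Multiple testing uses the
Bonferroni threshold α/m (0.05/5 = 0.01 for the default panel).

## Association models

Five contrasts per marker, all oriented to the risk allele:
multiplicative (Pearson 1-df χ² on the 2×2 allele table; OR =
cross-product ratio), additive (Cochran–Armitage trend with scores 0/1/2;
the attached OR is the per-allele OR, so only the χ² differs from the
multiplicative row), dominant, recessive (collapsed subject-level 2×2) and
genotypic (2-df Pearson on the 2×3 table with het-vs-reference and
hom-vs-reference ORs). Confidence intervals are Woolf intervals at a fixed
95% level (z = 1.959964); p-values come from the χ² distribution.

A zero cell makes a contrast *not applicable*: statistics are reported as
NA rather than silently continuity-corrected, matching the convention of
candidate-SNP reports for rare variants (e.g. a recessive test with no
risk homozygotes among controls). A `haldane=True` flag adds the +0.5
Haldane–Anscombe adjustment for users who want an estimate anyway; the
applicability flag stays false so the correction is never invisible.

## Risk scores and logistic models

unGRS = Σ dᵢ′ and wGRS = Σ wᵢ dᵢ′, where dᵢ′ = 2 − dᵢ for markers whose
named allele is protective (so every term points in the risk-increasing
direction) and wᵢ defaults to the natural log of the marker's allelic OR
estimated **from the analysed cohort itself** — external weights can be
supplied where a published meta-analysis is preferred. Natural log is the
GRS convention; since AUC is invariant to any common positive rescaling of
the weights, the base of the logarithm is immaterial to discrimination.

Logistic fits use maximum likelihood (statsmodels) with Wald standard
errors and intervals; with a single binary predictor the fitted OR equals
the 2×2 cross-product ratio to numerical precision, which is used as a
self-check. Rank-deficient designs raise an error naming the collinear
columns; complete or quasi-complete separation is flagged
(`converged=False`, NaN estimates) instead of returning silently diverged
coefficients. Explained variation is Nagelkerke's pseudo-R² (Cox–Snell
rescaled by its maximum), with Cox–Snell also exposed. The non-genetic
risk model uses age in 5-year units, sex, and BMI categories (<25
reference, 25–30, ≥30 kg/m²); the combined model adds the wGRS, and the
subject-level combined risk score is the fit's linear predictor.
Group-distribution comparisons (age, BMI, GRS) use the two-sided
Mann–Whitney U with normal approximation and tie correction; U/(n₁n₂)
equals the empirical AUC, asserted to 10⁻¹⁰ in the tests.

## Discrimination

The empirical AUC is tie-adjusted (half credit), computed via midranks;
standard errors and CIs use DeLong's structural-components estimator, and
the paired DeLong test compares two correlated AUCs measured on the same
subjects. Under HWE and inter-locus independence the AUC of any weighted
dosage score has a closed form: the per-group score distribution is built
by convolving the per-marker genotype distributions (3^k joint states,
merged at a 10⁻⁹ score tolerance) and AUC = Σ P(case > control) + ½P(tie).
Enumeration is refused beyond 12 markers (use Monte-Carlo simulation
instead). The incremental procedure adds markers in descending allelic-OR
order with **fixed** log-OR weights — no refitting — which treats the
trajectory as a property of the score; a logistic-refit variant is
available behind a flag.

## Synthetic cohorts

The generator's defaults are the published study conditions: 298 cases /
400 controls; per-group risk-allele frequencies (cases 0.203, 0.2836,
0.6191, 0.5956, 0.0302; controls 0.0675, 0.2312, 0.5412, 0.5262, 0.02 for
rs6025, rs2066865, rs2036914, rs8176719, rs1799963); age 63.4 ± 16.4 vs
43.8 ± 12.6 years; BMI 28.2 ± 8.2 vs 27.2 ± 5.5 kg/m²; 51% vs 44% male.

* **marginal mode** (default): each group's dosages are Binomial(2, p) at
  its own frequency — HWE within group, independent loci. This is the
  structure implied by group-level frequency tables and underlies all
  reproduction checks.
* **logistic mode**: a source population is drawn at control-like
  frequencies and case status assigned by a logistic model with known
  per-allele log-ORs and a rare-disease intercept (default −4), sampling
  to quota. Because cases inherit HWE with a shifted allele odds and
  controls stay near the population frequency, the allele-level OR equals
  the model OR in expectation — the mode exists for estimator-recovery
  experiments.

Covariates are truncated normals (age 18–100 y, BMI 15–60 kg/m²) with sex
Bernoulli per group; truncation is a plausibility choice that shifts the
realised means slightly from the nominal moments (≲1 y for age). A single
seed feeds separate genotype and covariate substreams, so changing the
marker panel leaves covariate draws untouched; identical configuration
gives a byte-identical cohort.

What the generator does **not** emulate: linkage disequilibrium between
loci, age–genotype or sex–genotype correlation, and the right-skewed age
distribution of real VT cases (the study population's case ages skew
old). Consequently tests based on simulated cohorts validate the
*estimators* under the stated model, not the study's exact covariate-driven
quantities: the combined-model and non-genetic-model AUCs depend on the
full covariate distributions and are checked as an ordering (combined >
non-genetic > wGRS > unGRS ≥ best single SNP) rather than as point
targets. That ordering is asserted on a large simulated cohort
(5,000/5,000, fixed seed) because it is a population-level property and at
the 298/400 study size sampling noise is comparable to the ~0.03 AUC gaps
involved.

## Count reconstruction

Integer count tables are rebuilt from printed summaries by
nearest-integer rounding: risk-allele count = round(freq × 2n), and
genotype counts from (MAF, observed heterozygosity, n) via
het = round(O(HET)·n), minor-hom = round((minor alleles − het)/2).
Inconsistent inputs (negative implied count) raise. These reconstructed
tables reproduce the published allelic ORs and χ² statistics exactly at
the printed precision; the exact HWE test on the reconstructed rs6025
counts (538/145/15) reproduces the printed p-value 0.1665 to 4 d.p.
(the chi-square test gives 0.164).

One analytic note: the closed-form AUC of the unweighted 5-SNP score at
the published frequencies is 0.6446, which prints as 0.64 while the study
reports 0.65 for its empirical cohort estimate — the 0.005 gap is within
that estimate's sampling error (the published CI is 0.60–0.69). The
weighted-score enumeration (0.6775) and single-SNP enumeration (0.6190)
print as the published 0.68 and 0.62.

## Numerical choices

* 95% level fixed with z = 1.959964 everywhere Wald/Woolf intervals occur.
* Ties: half-credit (mid-rank) convention throughout, consistent with the
  Mann–Whitney identity.
* Enumeration merges scores within 10⁻⁹; weights and dosages are exact
  floats so this only guards against representation noise.
* Report tables round only at serialization (ORs 2 d.p., frequencies
  4 d.p.); all internal computation is full precision, and reruns with the
  same input and seed are byte-identical.
* Reconstruction uses round-half-up (floor(x + 0.5)) so printed
  frequencies map deterministically to counts.

## Known limitations

* Biallelic markers only; no haplotype, gene–gene interaction or
  imputation support.
* Adjusted (multi-covariate) odds ratios on real data depend on the joint
  covariate distribution; on synthetic cohorts they reflect the
  generator's independence assumptions, not any real cohort's covariance.
* The exact HWE test is conservative by construction; its type-I error
  sits below nominal α (the chi-square version is calibrated and is the
  default).
* The pipeline's sex-stratified analyses are not implemented: stratified
  AUCs require the sex-by-genotype joint distribution, which group-level
  summaries do not determine.
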