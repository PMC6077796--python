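# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices and the known limitations of `poemeth`.  Everything
quantitative stated here is computed by the test-suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## 1. Transmission resolution and the orthogonal POE coding

A duo design observes the mother's and the child's genotypes but not the
father's.  For a biallelic SNP (minor-allele counts g ∈ {0, 1, 2}) the
parental origin of a heterozygous child's minor allele is certain exactly
when the mother is homozygous: mother 2 ⇒ the maternal allele is minor
(P = +1), mother 0 ⇒ it is major, so the minor allele is paternal
(P = −1).  Mother-het/child-het duos are unresolvable without LD-based
haplotype phasing, which this package deliberately does not implement:
entries are set missing per SNP–duo.  Missingness reduces the effective
sample (at MAF q, the resolvable fraction of heterozygotes is roughly
q² + (1 − q)² of them) and therefore power, but cannot bias the POE test.
Mendelian impossibilities (child 0 / mother 2, child 2 / mother 0) are
flagged and excluded per SNP–duo, mirroring array-error handling.

The ordered genotypes map to design rows [1, A, D, P]:
major/major → [1,0,0,0]; major|minor (minor maternal) → [1,1,1,+1];
minor|major → [1,1,1,−1]; minor/minor → [1,2,0,0].  When the two
heterozygote orderings are equally frequent — the expectation under random
mating — P is exactly orthogonal to the centered A and D columns, so the
estimated βP does not move when A and D enter or leave the model.  This is
verified exactly on constructed balanced samples and statistically
(|corr| < 3/√n) on simulated cohorts.

The minor allele is defined within the analysis sample (children), ties at
frequency 0.5 broken to the alt allele.  SNPs with child MAF < 5% are
dropped on input: with a handful of minor-allele heterozygotes, a single
aberrant methylation value can masquerade as a parent-of-origin difference.

## 2. The regression and its robust Wald test

Each CpG is regressed by OLS on [1, A, D, P, covariates] per time point.
Covariates follow the array-cohort convention: sex, age, three genotype
ancestry PCs, ten control-probe PCs (batch).  The POE Wald statistic uses a
heteroscedasticity-consistent sandwich covariance,
(XᵀX)⁻¹ Xᵀ diag(wᵢeᵢ²) X (XᵀX)⁻¹, with wᵢ = 1 (HC0), n/(n−k) (HC1) or
(1−hᵢ)⁻² (HC3).  HC3 is the default — it is the small-sample
leverage-corrected variant and the common default of sandwich-estimator
implementations; observations with leverage 1 are excluded from the meat
(they carry zero residual).  The reference distribution is standard normal
(two-sided); a t(n−k) reference is available by flag and is slightly more
conservative.  Fits require both heterozygote orderings to have at least
`min_het = 3` members — below that the POE contrast is driven by single
observations — and a full-rank design; failing pairs are recorded as
degenerate rather than aborting a scan.

Calibration (test-suite, 10,000 null tests at n = 740, 15 covariates,
heterozygote noise SD 1.5× the homozygote SD): empirical type-I error at
nominal 0.05 is ≈ 0.049 with HC3 and ≈ 0.16 with classical OLS standard
errors — the motivation for the sandwich.

Effect size is reported as the partial correlation R between methylation
residualized on intercept + covariates only and the raw P coding.  A and D
are deliberately not residualized (flag available): the reported R then
matches the quantity that the scan's own regression tests, up to the
A/D-orthogonality noted above.

## 3. Effective number of tests and the significance threshold

Cis scanning (window 500 kb, inclusive) at array scale produces ~10⁸
correlated tests.  The effective test count is estimated spectrally: in
randomly placed 1 Mb windows the SNP–SNP correlation matrix (additive
coding, pairwise-complete) is eigendecomposed and

* li_ji: Meff = Σ [ 1{λᵢ ≥ 1} + (λᵢ − ⌊λᵢ⌋) ]   (default)
* nyholt: Meff = 1 + (M − 1)(1 − Var(λ)/M)

Both give Meff = M for independent SNPs and 1 for perfect correlation.
li_ji is exactly additive over block-diagonal structure (the spectrum of a
block-diagonal matrix is the union of the block spectra); nyholt is not —
e.g. two independent blocks of 5 perfectly correlated SNPs give block sum
2 but whole-matrix value 6 — one reason li_ji is the default.  Note the
li_ji weight function is discontinuous at integer eigenvalues, so sampling
noise around λ = 2 (duplicated SNPs) inflates window ratios; the estimator
is used as published.

The mean per-window ratio Meff/M (normal-theory 95% CI across windows)
rescales the Bonferroni division: threshold = α/(ratio × n_tests),
truncated — not rounded — to two significant figures.  Truncation is the
only reading consistent with the reference arithmetic this reproduces:
0.05/(0.33 × 4 × 10⁸) = 3.787…× 10⁻¹⁰, reported as 3.7 × 10⁻¹⁰.

## 4. Loci, known regions, and the U/B pattern call

Significant CpGs are clustered per chromosome by single linkage on CpG
position with a 2 Mb rule (join iff the gap to the previous significant
CpG is < 2 Mb), so reported loci are pairwise ≥ 2 Mb apart; the lead pair
is the member with the smallest POE p.  CpG positions (not SNP positions)
are the clustered entities, since CpGs are the mapped phenotype.  Known
vs novel is decided against a user-supplied region list (BED): known iff
the locus span lies within a 2 Mb flank of any region, with the distance
to the nearest region reported.  Cross-time consistency counts the time
points at which the lead pair is at least nominally significant (p < 0.05).

Two methylation architectures are distinguished at significant pairs:

* **U (uniparental)** — each heterozygote ordering sits on one homozygote
  level; consistent with one silenced parental chromosome.
* **B (bipolar dominance)** — the homozygote means coincide and the two
  heterozygote orderings deviate from them in opposite directions.

The verbal description suggests gating on Welch tests (homozygotes equal;
each het ordering significantly above/below both homozygote groups).  That
rule is implemented (`method="welch"`) but is not the default: requiring
significance against the small minor-homozygote group (≈ 46 members at
MAF 0.25, n = 740) leaves it only ~25–50% sensitive to true bipolar
patterns at 4% variance explained.  The default instead fits both
architectures to the four genotype-group means by weighted least squares —
uniparental: two levels with each het ordering assigned to one homozygote
level (better of the two assignments); bipolar: a common homozygote level
c with hets at c ± d — and picks the better-fitting shape, requiring the
het deviations to be opposite-signed for a B call.  Both models have two
parameters, so the comparison is penalty-free.  When the minor-homozygote
group has fewer than `min_group = 5` members it is dropped and hets are
compared against the major homozygote level only (at MAF 5% and n = 740
the minor-homozygote group has ~2 expected members); degenerate outcomes
carry a low-confidence flag and default to U.  Measured on planted
patterns at 4% variance, n = 740: ≈ 99% correct U calls and ≈ 98% correct
B calls.

## 5. Methylation-based transmission inference

At a uniparental CpG the heterozygote orderings coincide with the two
homozygote groups, so a logistic model fitted to homozygotes only —
logit Pr(H = 1) = β0 + β·CpG, H = 1 for major homozygotes — transfers to
heterozygotes.  The predicted probability P₁ of resembling the major
homozygotes yields a hard call (P₁ > 0.5) and the expected dosage
2P₁ − 1 ∈ [−1, 1].  Class imbalance between homozygote groups (severe at
low MAF: p² vs q²) is deliberately left uncorrected; the intercept absorbs
the prior log-odds, and this imbalance is precisely what makes the
downstream power cost MAF-dependent.  Under perfect separation the MLE
diverges and a weakly penalized (ridge, C = 10⁴) fit is substituted and
flagged; the weak penalty keeps the probabilities near the separation
limit rather than shrinking them toward the prior.  Accuracy is summarised
per SNP by the Mann–Whitney AUC (half-credit for ties) over heterozygotes
with known (duo-resolved) transmissions, evaluated in-sample by default.

## 6. The power analysis and its calibration

How much does inferring transmissions cost?  Per scenario (target R²,
MAF, target AUC) and per run: a cohort of n = 10,000 children is drawn
under HWE with balanced heterozygote orderings; an inference CpG is
simulated under the uniparental model with unit within-group noise and its
effect size calibrated by bisection (50 replicates per evaluation,
tolerance ±0.002) so the homozygote-trained logistic attains the target
AUC on heterozygotes; heterozygotes are coded by the expected dosage
P − (1 − P) (homozygotes 0); the phenotype is simulated so the *true*
coding explains the target R²; and the phenotype is regressed on the
inferred coding.  The mean R² over 500 runs is the degraded variance
explained.  Sample sizes come from the two-sided Fisher Z′ formula
n = ⌈((z₁₋α/₂ + z_pow)/atanh√R²)² + 3⌉ (α = 5 × 10⁻⁴, power 0.8), and the
fold-increase is n(degraded R²)/n(target R²).  AUC = 1 is defined as
transmissions known with certainty, i.e. the true ±1 coding (fold exactly
1); AUC = 0.5 leaves only the ~1/n small-sample bias of a squared
correlation.

**Calibration of the dosage scale.**  The procedure being reconstructed
does not pin down the scale on which the "probability" P enters
P − (1 − P).  Taken on the logistic **response scale** (P = expit(β0 +
β·CpG), dosage bounded in [−1, 1]), the homozygote class imbalance at
MAF 0.25 shifts and compresses all heterozygote dosages toward the
majority side, and the simulation yields a degraded R² of ≈ 0.042% for a
1% effect at AUC 0.75 (fold ≈ 24 at MAF 0.25, ≈ 5.6 at MAF 0.45).  Taken
on the **linear-predictor (link) scale** — the default output scale of
common GLM prediction routines — the same simulation yields ≈ 0.078%
degraded variance and folds ≈ 12.8 (MAF 0.25) and ≈ 5.3 (MAF 0.45), a set
of values that is mutually consistent with the worked example this module
reproduces (1% → ~0.09%, ~12×, ~5×).  The link scale is therefore the
default (`dosage_scale="link"`), the response scale remains available, and
the sensitivity between the two is printed by the acceptance suite.  Note
the transmission-inference module of Section 5 always reports the bounded
response-scale dosage; the scale choice applies only to this power
reconstruction.  A fast `binormal` mode (score separation √2·Φ⁻¹(AUC),
balanced-prior posterior) is provided for exploration; it has no MAF
dependence, which is exactly what makes the end-to-end mode with class
imbalance the credible mechanism.

The degradation factor (degraded/target R²) is a squared correlation
between codings and hence invariant to the target R²; the fold-increase is
non-increasing in AUC and, in end-to-end mode, decreases as MAF rises —
both asserted by the tests.

## 7. The synthetic-data generator

* **Genotypes.**  Mother haplotypes and the paternal transmitted haplotype
  are drawn from the population allele frequency (fathers are never
  observed in a duo design, so nothing is gained by simulating them); the
  child receives one maternal allele chosen at random (per LD block) plus
  the paternal allele.  The truth of every transmission is recorded, and
  phased child VCFs (paternal|maternal order) round-trip it through the
  file readers.  LD blocks use a Gaussian copula with equicorrelated
  latents thresholded at Φ⁻¹(MAF): only the correlation matrix matters for
  the spectral Meff stage, so no attempt is made at realistic genome-wide
  LD maps.  All randomness hangs off one integer seed with per-stage
  stream splitting (`numpy` SeedSequence).
* **Methylation.**  β = group mean + Gaussian noise, clipped to [0, 1]
  (raw-β analysis is the target, so simulation is on the raw scale; a
  logit-scale variant was considered and rejected as out of scope).
  Uniparental patterns track a single parental allele (maternal or
  paternal); bipolar patterns put the group mean at baseline ± δ for the
  two heterozygote orderings.  δ is calibrated against realized sample
  moments so the variance explained by the true POE coding equals
  `poe_r2`, with covariate-effect variance included in the budget; the
  defaults (baseline 0.5, noise SD 0.08) keep the clipping rate below 1%.
  A pure uniparental architecture cannot exceed poe_r2 ≈ 0.5 — the same
  allelic shift loads the additive coding equally — and infeasible
  requests raise rather than silently under-deliver.  The optional
  heteroscedastic noise model scales the SD with √(μ(1−μ)) of the group
  mean, the natural mean–variance coupling of a proportion.
* **Covariates.**  Sex ~ Bernoulli(0.5); age constant per time point plus
  jitter; 13 PCs standard normal; 15 columns total, with small seeded
  effects on methylation by default.
* **What it does not emulate.**  Cell-type composition, probe artefacts,
  batch structure beyond linear PC effects, longitudinal autocorrelation
  beyond shared genetics, multimodal within-group methylation, and real LD
  maps.  Passing tests on these cohorts demonstrate the statistical
  machinery under its stated assumptions, not robustness to every artefact
  of real array data.

## 8. Problem sizes, determinism and degenerate inputs

The test-suite runs cohorts of 740 duos (the scale the scan is designed
around) with 100 replicates per grid point for recovery/classification
checks, 10,000 replicates for type-I calibration, and the full 500-run /
n = 10,000 degradation simulations; the whole suite completes in a couple
of minutes on one core.  Scans are deterministic given inputs; pipeline
reruns produce byte-identical summary files.  Degenerate cases are
first-class: missing P rows are dropped per pair, absent heterozygote
orderings or rank-deficient designs yield flagged degenerate results,
zero-variance residuals give missing partial correlations, and BED/VCF
round-trips preserve the 1-based-internal / 0-based-BED conventions.

## 9. Known limitations

* Double-heterozygous duos are never phased; cohorts genotyped without
  mothers cannot be analysed at all.  X-chromosome transmission rules are
  not implemented.
* The genome-wide threshold ignores correlation among CpG probes and is
  therefore conservative.
* The U/B classifier is a two-model comparison on group means; patterns
  outside its families (e.g. asymmetric "polar" architectures) will be
  forced into U or B.
* Transmission-inference AUC is computed in-sample by default
  (cross-validation by flag); at discovery loci it inherits winner's-curse
  optimism.
* A detection-power worked value quoted for a 4%-variance effect at
  n = 740 under the genome-wide threshold is not achievable: the expected
  Wald z is ≈ 5.5 against a 6.26 cutoff (~29% power; ≈ 99% at 9%
  variance).  The corresponding acceptance test documents this honestly
  and fails by design.
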