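# Methods

This note documents the statistical models, the defaults that matter, the
synthetic data the package is validated on, and the numerical choices made
where the design was genuinely open.

## Data model

Genotypes are held as a dense samples × variants matrix of alternate-allele
dosages {0, 1, 2} with a sentinel for missing calls; only biallelic records
are accepted (multi-allelic sites must be decomposed upstream, e.g.
`bcftools norm -m-`), and coordinates are VCF-native 1-based throughout — no
coordinate arithmetic is performed anywhere. Annotations are one record per
variant: gene symbol, one SIFT label, one PolyPhen label and an optional
population alternate-allele frequency, read from the INFO keys
`GENE`/`SIFT`/`POLYPHEN`/`AAF_1KG` (renameable for other dialects; VEP CSQ
parsing is out of scope). Phenotypes are binary severe/mild grades:
overall severity plus the four sub-phenotype axes (non-verbal IQ, memory,
attention, verbal ability), case-folded on input and required to be
complete.

## Allelic association

Each variant contributes a 2×2 allele-count table — two alleles per diploid
genotype; missing genotypes shrink the denominator, no imputation at this
stage. The ranking statistic is the 1-df Pearson χ² on the raw table (the
basic allelic case–control test), with the upper-tail χ² probability as
p-value; a Fisher exact p is available behind an option for very small
tables. The odds ratio ad/bc receives the Haldane–Anscombe +0.5 correction
(all four cells) only when a cell is zero, and only for the OR — never for
the χ². A monomorphic site gets χ² = 0, p = 1; a table with an empty group
margin is an error. Variant ranking is fully deterministic: ascending p,
ties broken by descending |ln OR|, then by (chrom, pos, alt). Covariate
adjustment, stratification correction and multiple-testing control are
deliberately absent: the test is a feature-selection device inside
cross-validation, not an inferential endpoint.

## The risk model

The classifier is logistic regression on the selected variant dosages with
independent Cauchy priors, fitted to its posterior mode. Predictors are
standardized before the prior is applied — every column shifted to mean 0,
non-binary columns scaled to standard deviation 0.5 (sample sd, n−1) — with
prior scale 2.5 on coefficients and 10 on the intercept. These are the
published defaults of the weakly-informative scheme; nothing in this
problem suggested overriding them, and with 32 training samples and up to a
few dozen predictors the regularization is what keeps separable fits
finite.

The fit is the approximate-EM penalized IRLS: writing the Cauchy prior as a
scale mixture of normals (t with 1 df), each outer iteration sets every
coefficient's prior variance to its conditional expectation
σⱼ² ← (βⱼ² + sⱼ²)/2, then takes one penalized weighted-least-squares step
(ridge with per-coefficient penalty 1/σⱼ²). Numerical safeguards:

- IRLS weights are clipped below at 1e-10;
- each step is halved (up to 60 times) until the Cauchy-penalized deviance
  does not increase, so the recorded deviance path is monotone by
  construction (asserted in tests);
- convergence is max |Δβ| < 1e-8 within 100 iterations; the diagnostics
  object records iterations, final change and the deviance path.

Coefficients are reported back on the original dosage scale. Predicted risk
is the inverse-logit of the linear predictor; classification uses threshold
0.5 with ties to severe (the paper-style binary outcome defines no
threshold, so the natural probability midpoint is used). A constant column
keeps coefficient ≈ 0; with a flat intercept prior the intercept then
reproduces the class base rate exactly, while under the default
Cauchy(0, 10) intercept prior it is shrunk by ~1e-4 on the probability
scale — the tests isolate the base-rate property with a flat intercept
prior for that reason.

Missing dosages are mean-imputed per variant from the training fold only,
and the training means are re-applied to the held-out sample, so imputation
cannot leak test information.

## LOOCV and the saturation scan

Feature selection is nested: for each of the n folds, association ranking
and top-k selection are recomputed on the n−1 training samples, the model
is refit, and the held-out sample is scored out-of-fold. Aggregate
confusion counts (severe = positive class), accuracy, sensitivity,
specificity and MCC (0 by convention when its denominator vanishes) are
computed over the n out-of-fold predictions; ROC AUC is the Mann–Whitney
probability on the pooled out-of-fold risks — computing it on a refit
full-data model would be optimistically biased, and the out-of-fold choice
is the documented one. The per-fold selections are pooled as a
de-duplicated union ordered by selection frequency, then best rank.

The saturation scan evaluates k = 6, 8, 10, … and stops after `patience`
(default 3) consecutive evaluations strictly below the running maximum
accuracy; an evaluation that ties the maximum resets the counter. The
chosen k is the smallest maximizer. Step 2 and patience 3 are defaults, not
doctrine — the procedure is "increase until no further improvement" and
both knobs are exposed.

Reclassification between two risk models uses half-open categories
[cᵢ, cᵢ₊₁) with the last interval closed, default cut-points {0, 0.5, 1}
(no category boundaries are canonical for this problem; two categories
mirror the binary decision). NRI is the usual event/non-event net
up-minus-down difference; IDI the between-class difference of mean risk
change.

Molecular subtyping clusters the scalar out-of-fold risks by average
linkage (UPGMA) with Euclidean distance, cuts the tree at two clusters,
labels the higher-mean cluster "high-risk/severe-like", and reports samples
whose molecular side disagrees with the clinical grade, sorted by
descending risk.

## The important-gene rule

A variant qualifies for a sample iff dosage = 2 and SIFT ∈ {deleterious,
deleterious_low_confidence} and PolyPhen ∈ {possibly_damaging,
probably_damaging}; token matching is case-insensitive on exactly this set,
and an absent label disqualifies (no benefit of the doubt for
unannotated variants). Genes without a symbol are dropped. A gene is a
group IG when it appears in ≥ n−2 of the group's n member gene sets — read
literally, no percentage generalization (a custom threshold is exposed for
sensitivity analyses; threshold 1 gives the union, n the intersection, and
the n−2 call is provably sandwiched between them). Groups need n ≥ 3. The
eight groups are {iq, memory, attention, verbal} × {severe, mild}; a
"language" alias maps onto "verbal" in the CLI.

Cross-group structure is an exact membership partition (Venn regions,
capped at 8 sets = 255 regions); the all-groups region is the
severity-independent signature. The multi-set intersection test reports the
observed all-set overlap against the independence expectation
U·Π(|sᵢ|/U) with a seeded Monte-Carlo p (continuity-corrected
(hits+1)/(B+1)); an exact multi-set hypergeometric distribution is not
computed — the Monte-Carlo estimator is validated against exhaustive
enumeration on a toy universe in the tests, and the gene universe defaults
to all genes present in the annotated VCF (the natural choice when no
universe is stated).

External validation is exact symbol matching after upper-casing; no
HGNC alias or synonym resolution, because database exports vary by version
and silent alias mapping would manufacture agreement.

## The synthetic cohort generator

The generator emulates the study design the pipeline targets: 15 severe /
18 mild samples; genotypes Binomial(2, f) per sample and variant under
Hardy–Weinberg; planted risk variants with f raised by `risk_delta`
(default 0.35) over `background_aaf` (default 0.2) in the severe group
only; 2000 variants over 400 genes; a background rate of 0.05 for doubly
damaging annotation; missing calls injected uniformly at random at rate
0.02 (the design it emulates reports nothing about missingness; this is an
explicit choice). Sub-phenotype grades reproduce the target marginal
counts (IQ 15/18, memory 15/18, attention 24/9, verbal 14/19 for the
33-sample default; IQ coincides with overall severity, which is defined
from it) while being maximally concordant with overall severity up to a
configurable discordance fraction (default 0.1, implemented as
marginal-preserving label swaps). Planted important genes receive one
dedicated hom-alt, doubly damaging variant in all but at most one member of
their target group — never fewer than n−2 — and those carrier cells are
shielded from missingness so the planted truth is recoverable by
construction. One seed produces one cohort, bitwise, including the files
written to disk.

An optional `aaf_range` draws each variant's background frequency from a
uniform range instead of the shared constant. Real exome sites span a wide
frequency spectrum, and the option also matters statistically: with one
shared frequency and 33 samples, the χ² p-values live on a coarse lattice
(including an atom at p = 1 from tables with ad = bc), so no continuous
uniformity test can pass regardless of implementation. The null-calibration
check therefore uses a cohort scaled to 255/306 — preserving the 15:18
design ratio — with `aaf_range=(0.05, 0.5)`, under which the
Kolmogorov–Smirnov test against Uniform(0,1) passes comfortably at
α = 0.01 on 6000 variants.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: linkage disequilibrium (variants are independent, so
feature selection never faces correlated proxies), sex chromosomes and
hemizygosity, multi-allelic sites and indels, population stratification,
genotyping error beyond uniform missingness, and transcript-level
annotation ambiguity (one SIFT/PolyPhen label per variant is taken as
given). Recovery results on synthetic cohorts demonstrate the machinery is
correct and leak-free, not that the clinical effect sizes are realistic.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full LOOCV machinery on
the 33-sample / 2000-variant default cohort, the permutation null with 20
(acceptance) or 100 (property test, 20-sample/300-variant cohort) label
shuffles, and the KS calibration on 6000 variants — sizes at which every
check completes in seconds on one CPU while keeping the statistical
comparisons meaningful. Two properties of LOOCV at this scale are worth
knowing: the permutation-null accuracy sits *below* the majority-class rate
(the well-known pessimistic bias of leave-one-out under label permutation —
the shipped check is one-sided accordingly), and with strong planted signal
the saturation scan can settle below the planted variant count because
accuracy reaches its ceiling early.

## Known limitations

- The allelic test assumes Hardy–Weinberg-like allele counting; genotypic,
  dominant and recessive models are not offered.
- With ~20 informative variants among 2000 at delta 0.35 and 33 samples,
  single-variant ranking is near its power boundary: on a typical draw only
  ~12–13 planted variants survive into the top 26, even though the
  aggregated classifier separates the groups almost perfectly. Variant-level
  recovery claims at this design size should be treated as noisy.
- The Cauchy-prior fit returns the posterior mode only; no posterior
  uncertainty is propagated into the risk scores.
- Gene symbols are treated as opaque strings end to end.
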