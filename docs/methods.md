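# Methods

This note documents the statistical model, the numerical choices, and
the design decisions behind `dcmburden`, including what the synthetic
cohorts do and do not emulate.

## Variant qualification

A candidate variant qualifies for a gene when all of the following
hold, applied in this order (the first failing filter is the recorded
exclusion reason):

1. **Site QC** — genotyping call rate ≥ 0.90, QualByDepth ≥ 6, and an
   exact Hardy–Weinberg equilibrium p-value ≥ 1e-6. Comparisons pass at
   equality, mirroring the convention that sites *below* the cut-offs
   are excluded. The HWE test is the Levene–Haldane exact test: the
   conditional distribution of the heterozygote count given the allele
   counts is enumerated and the probabilities of all outcomes no more
   probable than the observed one are summed (no mid-p correction). It
   is computed on the genotyped cohort samples — cases only, since the
   analysed cohort is a case series; for a disease this rare the
   distortion of genotype proportions among cases is negligible at
   these allele frequencies. Whether an ancestry-stratified HWE filter
   would be preferable is an open question; the full-sample test is the
   implemented choice.
2. **Rarity** — allele frequency strictly below 0.01% (1e-4) in *every*
   reference population supplied, i.e. a popmax rule over the
   populations present in the annotation table; a variant absent from
   the reference is rare. Exactly 0.01% fails (strict `<`).
3. **Consequence class** — sequence-ontology terms on the MANE
   transcript are mapped to pLoF (`stop_gained`, `frameshift_variant`,
   `splice_acceptor_variant`, `splice_donor_variant`) or missense
   (`missense_variant`, `inframe_insertion`, `inframe_deletion`), with
   pLoF taking precedence; PAV is the union. Each gene collapses only
   its mechanism-consistent class. For the four genes excluded from the
   cohort analysis by the carrier-count rule (BAG3, TNNC1, TNNT2, PLN)
   the qualifying classes are taken from the disease-mechanism
   literature (BAG3 and PLN protein-altering, TNNC1 and TNNT2
   missense); on the bundled fixtures these genes never reach testing,
   so the choice does not affect any reported number.
4. **Titin exon inclusion** — TTN variants additionally require a
   percent-spliced-in (PSI) of at least 0.90 in cardiac tissue. No
   published PSI threshold accompanies the phrase "constitutively
   expressed cardiac exons"; 0.90 is the conventional cut-off for
   constitutive cardiac titin exons and is configurable. A TTN variant
   with no PSI annotation is conservatively excluded (and logged).

Multi-allelic sites must be split before analysis; the VCF reader does
this and recomputes per-sample allele counts and genotype counts per
split allele. Coordinates are 1-based, as in VCF. Sample-level QC
(heterozygosity, sex checks, relatedness) is **not** performed: the
sample sheet is assumed pre-cleaned upstream.

Missing QC fields raise an error under `strict` (the default); with
`strict=False` they are treated as passing and logged, for annotation
tables produced without QC columns.

## Burden test

Carriers are collapsed per gene — at least one alternate allele at at
least one qualifying variant; a missing genotype counts as non-carrier.
The alternative (shrinking the per-gene denominator) was rejected for
simplicity: post-QC missingness is below 10% by construction and the
analysis reports fixed per-sex denominators.

The 2×2 table puts females in the exposed row, so OR > 1 means
enrichment in women. The test is Fisher's exact test; the two-sided
p-value sums the probabilities of all tables (margins fixed) whose
hypergeometric probability does not exceed the observed table's, with a
relative tie guard of 1e-7. One-sided alternatives are available.

The reported OR is the conditional MLE: the ψ maximising the
non-central hypergeometric likelihood with both margins fixed, found by
bisection on the score equation E_ψ[X] = a in log-ψ (64 iterations on a
bracket that is widened until it straddles the root; boundary counts
give 0 or ∞). The 95% CI is the central exact conditional interval —
each tail solves P(X ≥ a | ψ) = 0.025 or P(X ≤ a | ψ) = 0.025 by Brent
root-finding — with one-sided bounds for boundary counts. These match
the printed cohort values (e.g. DSP 3.04 [1.44–6.63]); the crude sample
OR ad/bc is reported alongside in machine-readable output.

Genes with fewer than five carriers in the combined male and female
data are excluded ("fewer than" is strict: five carriers are tested).
Benjamini–Hochberg step-up adjustment (via statsmodels) runs over the
tested genes only — excluded genes yield no p-value — so the family
size is 8 on the cohort fixture.

**Multiple-testing caveat.** On the fixture's exact contingency tables
the two-sided Fisher p for DSP is 0.00229, giving an adjusted value of
0.0183 over the 8 tested genes. The adjusted-p column printed for this
cohort in the literature (DSP 0.0092, with 0.12/0.75/0.54 elsewhere)
cannot be reconstructed from these carrier counts under any single
convention we tried — two-sided, one-sided, mid-p, unconditional exact
or chi-square p-values, with BH families of 8 or 12 — and is internally
inconsistent with any one BH family (the implied ranks would violate
the p-value ordering). The package therefore reports the standard
two-sided convention and the raw p alongside, and leaves the published
adjusted values as not reproducible from the published counts.

## Penetrance

Cross-sectional estimator, by Bayes' rule:

    penetrance = clamp(prevalence × f_case / f_pop, 0, 1)

with f the aggregated qualifying-variant frequency among diagnosed
cases and in an unselected population of the same stratum. Frequencies
are carrier counts per individual by default; for variants under the
0.01% rarity cut-off the factor of two against allele counts cancels in
the ratio, and an `allele_counts` mode divides by 2n instead.

Uncertainty: `n_draws` (default 100,000) Monte-Carlo draws of both
frequencies from Jeffreys Beta(c + ½, n − c + ½) posteriors; the
clamped product is formed per draw (clamp events are counted and
reported) and the 2.5/97.5 percentiles are the CI, forced to bracket
the point estimate so a zero-numerator point of 0 keeps a one-sided
interval. Draws use `numpy.random.default_rng(seed)` (default seed
20250423) and are bit-reproducible. The prevalence is a required input
treated as fixed — the package ships a 1/250 placeholder that warns
loudly when used — unless a 95% CI is supplied, in which case it is
drawn log-normally. Per-stratum estimates use independent streams
spawned deterministically from the seed.

The published sex-stratified penetrance values for this cohort rest on
external population carrier counts that are not redistributable, so
they are not recomputed here; the estimator is validated by its
algebraic identities (ratio 1 → prevalence; zero numerator → 0;
linearity in prevalence until clamping) and by parameter recovery on
simulated cohorts (below).

## Synthetic cohorts

**Generative model.** Each individual draws a sex (P(female) = 0.5), a
carrier state for at most one gene (multinomial over per-gene carrier
frequencies q_g — single-gene attribution keeps per-gene expectations
analytic), and a disease state: Bernoulli with the gene- and
sex-specific penetrance for carriers, with the background risk (0.003)
otherwise. Hence

    P(carrier of g | case, sex) = q_g·pen_{g,sex} / (Σ_h q_h·pen_{h,sex} + (1 − Σ_h q_h)·bg)

which the fast replicate path samples directly as one multinomial per
sex. Carriers receive concrete rare variants (annotations drawn in the
passing ranges); genes with a positive decoy fraction also emit decoy
variants that must fail qualification for one specific reason each
(common allele, synonymous consequence, low QualByDepth, low call rate,
Hardy–Weinberg violation, non-constitutive TTN exon).

Default parameters are the study conditions: q_g are plausible
population carrier frequencies for the mechanism-matched classes (TTN
0.4%, DSP 0.2%, down to 0.01% for the rarest), and penetrances are
calibrated so the expected case carrier fractions at 274 female / 556
male cases equal the cohort's observed fractions under the joint
denominator above. The default population size (400,000) leaves
comfortable headroom to ascertain such a cohort.

**What is not emulated:** linkage disequilibrium, relatedness, ancestry
structure beyond a categorical label, X/Y genotypes (all twelve genes
are autosomal), multi-gene carriers, and sequencing failure modes
beyond the decoy classes. Passing tests therefore demonstrate correct
statistical behaviour under the stated sampling model, not robustness
to cohort artefacts excluded by upstream QC.

**Fixtures.** A deterministic, seed-free 830-sample cohort encodes
fixed qualifying-carrier counts per gene and sex (with class splits,
e.g. 6 of the 20 female DSP carriers truncating), one designated
double-carrier to exercise collapsing, an ancestry sliver for subset
analyses, and eight decoys covering every failure mode; a 1,304-case
validation cohort (387 female) encodes the fixed DSP carrier counts of
the population validation analysis. Expected counts and decoy reasons
live in a JSON manifest written next to the VCF/TSV files.

**Penetrance recovery scenarios.** Two single-gene scenarios with true
penetrances (DSP 0.11 female / 0.02 male; TTN 0.06 / 0.18) at cohort
sample sizes (274/556 cases; 91,751/75,727 population). Carrier
frequencies are set in the qualifying-variant regime (DSP 2e-3, TTN
4.3e-3) so each stratum expects at least ~5 case carriers: at
pLoF-only frequencies (~6e-4) the rarest stratum expects ~2 carriers
and the *median* point estimate is determined by count discreteness
rather than estimator behaviour — a known small-sample limitation of
any count-ratio estimator, not specific to this one. Recovery runs use
4,000 CI draws per estimate to keep 500 replicates per gene around a
second; the CI quantiles at that depth are accurate to well under the
coverage tolerance.

## Verification strategy

* Fisher p and the conditional MLE are compared with independent
  enumeration on **every** 2×2 table with n ≤ 60: exact integer
  hypergeometric weights for p, and golden-section search directly on
  the conditional log-likelihood (a different route than the score
  equation) for the MLE. Worst observed deviations ~1e-14 (p) and
  ~5e-7 (MLE, limited by likelihood flatness at the optimum).
* The HWE p is compared with exact integer enumeration for **every**
  genotype triple with total ≤ 200 (worst deviation ~1e-13), plus the
  allele-label mirror of each triple.
* The penetrance CI is cross-checked against a second Monte-Carlo
  implementation using a different generator (Philox) and inverse-CDF
  Beta sampling.
* Null calibration: on 500 equal-penetrance cohorts the per-gene
  rejection rate at α = 0.05 is checked against binomial 99% bounds
  around the nominal level. Note that Fisher's exact test is
  conservative at these margins: full enumeration puts the true
  per-gene size at 0.032–0.045, so the nominal-level check has limited
  power against the conservativeness it tolerates and would fail by
  design at much larger replicate counts. Conservative (never
  anti-conservative) behaviour is the accepted property of the exact
  test.
* Reports are reproducible byte-for-byte given identical inputs; the
  run manifest records thresholds, seed, package version and input
  checksums.

## Problem sizes used by the shipped studies

Replicate studies run at 500 replicates each (parameter recovery per
gene, null calibration), the exhaustive oracle comparisons at n ≤ 60
(2×2 tables) and N ≤ 200 (HWE), and simulated populations default to
400,000 individuals. These sizes give stable results on a single CPU
in minutes and are stated here as the package's reference conditions.
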