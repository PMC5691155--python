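# Methods

## The problem and the model

`pathpgs` implements the statistical machinery of a large case/control GWAS
of male-pattern baldness (MPB) and, at its centre, *pathway-partitioned
polygenic risk scores*: the observation that two traits can share genetic
effects inside specific biological pathways even when those effects cancel
in a genome-wide score. Every stage is implemented against a synthetic
cohort with known ground truth, because the underlying biobank data are not
redistributable. The pipeline stages are:

1. **Two-step association.** A vectorised least-squares screen of the binary
   phenotype on every SNP dosage plus covariates (equivalent to the Armitage
   trend test), then a logistic refit (IRLS, max 25 iterations, tolerance
   1e-8) of SNPs passing the extraction threshold p < 1e-5. p-values are
   carried as natural logs internally so that genome-wide signals survive
   floating-point underflow. Replication cohorts are combined by
   fixed-effect inverse-variance meta-analysis (β = Σwᵢβᵢ/Σwᵢ, w = 1/SE²),
   and inflation is summarised by genomic control λ = median(χ²)/0.4549.
2. **Loci and conditionally distinct SNPs.** SNPs with p < 1e-5 are
   single-linkage clustered: consecutive SNPs on a chromosome separated by
   strictly more than 500 kb start a new locus (a 500,000 bp gap keeps one
   locus). Within each locus, stepwise conditional regression on
   individual-level genotypes adds the top SNP as a covariate and refits the
   rest, repeating while any conditional p < 5e-8; candidates with r² > 0.9
   against the selected set are skipped. Loci with no distinct SNP are
   discarded; explicitly listed same-chromosome loci can be merged (the
   AR/EDA2R-style case). Replication requires p < 0.05 (strict) and, by
   default, a concordant effect direction; a flag restores the literal
   p-only rule.
3. **Heritability.** GRMs use the standard standardised-dosage formula
   A_jk = (1/m) Σ (x_j − 2p)(x_k − 2p) / (2p(1−p)). Variance components come
   from AI-REML (average-information updates, Haseman–Elston regression
   start, EM retreat when an AI step would decrease the restricted
   likelihood, variances projected to a small positive floor, convergence at
   |Δ log-lik| < 1e-6; SEs from the inverse AI matrix). Binary phenotypes
   are analysed on the observed 0/1 scale and converted to the liability
   scale with the population-sample multiplier K(1−K)/z², z = φ(Φ⁻¹(1−K)) —
   no ascertainment correction, appropriate because the cohort's own
   prevalence (0.59) is used. The variance explained by a polygenic score is
   the drop in GRM-attributed variance when the score enters the fixed
   effects, with both fractions expressed on the baseline phenotypic
   variance (the with-score model's own total shrinks, which would otherwise
   understate the drop).
4. **Scores.** SNP weights are re-estimated *jointly* — one logistic
   regression over all distinct SNPs plus covariates — so correlated signals
   are not double-counted. A locus score is Σ dosage × joint β over the
   locus's distinct SNPs; the overall score is the sum of locus scores; a
   pathway score is the sum of the locus scores of the loci containing the
   pathway's genes. Pathways with identical locus sets produce identical
   scores and are merged — either only the explicitly named groups (the
   study's behaviour, 28 → 25) or every identical group ("all-identical",
   28 → 24; the SMAD2/3 and TGF-β-receptor rows share a locus set but were
   not merged by the study, so both rules are kept). Score–trait association
   uses linear regression for quantitative traits, logistic for binary, and
   Cox proportional hazards for parental survival; multiplicity is handled
   by Storey q-values (π₀ from a cubic smoother over λ = 0.05…0.95, fixed
   λ = 0.5 below 100 tests).
5. **Regional pleiotropy.** Trait regions are seeded by SNPs with p < 1e-7
   and grown over SNPs with p < 1e-6 until a gap ≥ 1 Mb; regional scores are
   weighted dosage sums after a p < 1e-6 filter; pairs of regional scores
   with r² ≥ 0.5 are flagged as pleiotropic.
6. **Pathway communities.** Genes are joined by edges weighted by the number
   of annotation sets they share (a binary mode is also provided, since
   either reading of "co-membership" is defensible); Louvain modularity
   optimisation (seeded, hence deterministic) partitions them into pathway
   communities.

## The synthetic cohort

Genotypes follow a Gaussian-copula LD model: within each block of
`ld_block_size` SNPs a latent standard-normal AR(1) process with lag-one
correlation `ld_decay` is thresholded at Φ⁻¹(MAF), haplotype by haplotype.
This gives Hardy–Weinberg genotypes with a closed-form adjacent-SNP
correlation target (`allele_indicator_correlation`), which the tests verify
against a brute-force simulation of 10⁶ haplotype pairs. Blocks are
independent and placed > 500 kb apart, so each causal block maps to exactly
one locus under the distance rule. The cohort is all male; X dosages are
{0, 2} (one thresholded haplotype, doubled), and the X GRM scales these by
4p(1−p) so its expected diagonal is 1 and its variance component is on the
same footing as the autosomal one.

The primary trait is a liability threshold model: liability = autosomal
genetic value + X genetic value + noise, dichotomised at Φ⁻¹(1 − 0.59).
Defaults mirror the study conditions: prevalence 0.59, liability-scale h²
0.82 autosomal + 0.12 X-linked, 1–5 conditionally distinct causal SNPs per
locus, one X-linked locus whenever h²ₓ > 0. Genetic values and the noise are
rescaled in-sample so the realised h² equals the configured value exactly;
by default every locus carries the same genetic variance within its
component (`equalise_locus_h2`), which is what makes "equal total weight"
pathway groups cancel exactly rather than only in expectation. Secondary
traits receive genetic input only through configured pathways: trait =
Σ slope × (standardised pathway genetic value) + noise. The cancellation
scenario gives two equal-sized pathway groups slopes ±s; the diffuse
scenario spreads one small slope over many loci.

What the generator does **not** emulate: realistic recombination maps or
long-range LD, population structure (PCs are consumed as covariates but are
simulated independent of genotype), genotyping error, missingness,
imputation uncertainty, mixed-sex X genetics, and case–control
ascertainment. Passing tests therefore show the machinery is correct under
its stated model, not that the original cohort's estimates would be
reproduced on real data.

## Problem sizes and scenario parameters

Chosen once as desk-scale study conditions:

- Heritability recovery: n = 2,000 individuals; single component with
  m = 1,000 causal SNPs and h² = 0.5; two components (0.6 autosomal-like,
  0.2 X-like); 100 seeded replicates, success = truth within 2 reported SE,
  required coverage ≥ 90%.
- Cancellation: 12 loci, two 3-locus pathway groups with slopes
  ±6/√n at n = 2,000 (pathway z ≈ ±6), 50 replicates; the overall score must
  be null (|z| < 1.96) in ≥ 90% of them.
- Diffuse pathway: 16 of 20 loci carry a shared slope 5/√n at n = 2,000, so
  the expected pathway z is ≈ 5 while each locus score's expected z is
  ≈ 5/√16 = 1.25. By construction some locus occasionally exceeds any fixed
  threshold, so the assertions are: pathway |z| > 3.29 in ≥ 90% of 40
  replicates, no locus above 3.29 in ≥ 50% (theoretical ≈ 72%), and the
  pathway z exceeding the best locus z in ≥ 75%.
- Calibration: λ_GC from a null linear screen over 60,000 independent SNPs
  at n = 1,000 (sampling SD of the median-based λ ≈ 0.01, well inside the
  ±0.02 band); score–trait type-I error from 1,000 trait permutations at
  n = 2,000.

## Numerical choices

- AI-REML starts from Haseman–Elston regression estimates (clipped to
  [1% of phenotypic variance, Vp]); a single-GRM fit runs in the GRM
  eigenbasis where every iteration is O(n·p); multi-GRM fits invert V once
  per iteration via Cholesky (LAPACK dpotrf/dpotri). An AI proposal that
  lowers the restricted likelihood triggers an EM step from the previous
  point, so the accepted trajectory is non-decreasing. A near-singular AI
  matrix (e.g. a GRM indistinguishable from the identity) sets
  `degenerate=True` instead of failing silently.
- Stepwise selection tie-breaks: smallest conditional p, then smallest bp,
  then lexicographic SNP id. Candidates collinear with the conditioning set
  (residual variance ratio r² > 0.9) are skipped and logged.
- Allele harmonisation matches (effect, other) pairs, flips β on swaps, and
  passes strand-ambiguous (A/T, C/G) SNPs through with a warning — for those
  a swap cannot be told apart from a strand flip.
- Degenerate inputs: monomorphic SNPs are excluded from screens and GRMs
  with a log entry; a constant score yields a zero variance-explained
  decrease with a warning; an edgeless co-membership graph returns singleton
  communities with Q = 0; an empty discovery table makes the replication
  fraction "not applicable" (None).
- The dosage-compensation scaling of the X GRM (4p(1−p) for male {0,2}
  dosages rather than the autosomal 2p(1−p)) is deliberate: with the
  autosomal scale the X GRM's expected diagonal is 2 and the attributed
  variance fraction is halved, which would bias the recovered h² split.

## Packaged tables

Two TSV fixtures ship with the package: the 71-locus MPB summary (interval,
replication status, distinct/significant SNP counts, selected genes, top p
as printed) and the 28-row pathway composition table (pathway → member loci
→ distinct SNPs). Internal consistency — every pathway's SNP count equals
the sum of its loci's distinct-SNP counts — is asserted in the tests. The
`top_p` column is kept as text: the strongest X-locus value is below the
double-precision floor, and the counts, not the p-values, are what the
worked examples use.

## Known limitations

- The stepwise conditional selection operates on individual-level genotypes
  (the study's X-chromosome procedure); a summary-statistic COJO mode with
  an external LD reference is out of scope.
- Binary-trait heritability uses the observed-scale GREML plus the liability
  multiplier, not a liability-model REML; at high h² and prevalence far from
  0.5 this transformation is known to be approximate.
- The Cox family assumes proportional hazards and uses age as the time
  axis, as in the parental-survival scans.
- λ_GC on LD-correlated panels is a valid null diagnostic but the package
  does not implement LD-score regression (its intercept is out of scope).
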