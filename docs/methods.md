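# Methods

## Scope and data model

The package analyses one cis locus at a time: a samples × SNPs dosage matrix
(expected alternate-allele counts in [0, 2], i.e. imputation posterior
means), expression summaries for the nearby gene at three resolutions (exon
RPKM, junction RPM, transcript abundance, plus the gene total), GWAS summary
statistics (z-scores), and an LD matrix. All interchange formats are TSV
with 0-based half-open coordinates internally (VCF positions convert on the
way in and out).

## Normalization

Responses are rank-based inverse-normal transformed: value → fractional rank
→ Φ⁻¹((r − 0.5)/n), average ranks for ties. The −0.5 offset keeps the
extremes finite and the output symmetric around zero; the exact endpoint
convention is a free choice of the transform and this one (Blom-type) is the
standard symmetric variant. Junction counts become RPM by dividing by
(total mapped reads / 10⁶) before transformation.

## Covariates

* **Genetic ancestry** — principal components of dosages standardized per
  SNP by mean 2p̂ and scale √(p̂(1−p̂)) (the binomial allele-count variance);
  monomorphic SNPs are dropped with a warning. The first three PCs are used
  by default; the variance-explained vector is exposed so a scree plot can
  justify a different cut.
* **Global expression variability** — the first three factors of a truncated
  SVD of column-centered log2(RPKM + 0.25) exon expression. This plays the
  role probabilistic factor models (PEER-style) play as nuisance covariates:
  the leading variance components of expression. The SVD surrogate captures
  those same components without the variational machinery; the covariate
  interface is identical and the count is configurable.
* Factors must be fit on a broad expression matrix. Fitting them on the
  single tested gene's exons would absorb the splicing signal itself — the
  pipeline therefore fits them on a cohort-wide background matrix and the
  synthetic generator provides one (`simulate_background_exons`).

## Association models

All three tests are OLS on the rank-normalized response with dosage g, an
expression covariate, 3 PCs and 3 factors (intercept + 8 slopes; p-values
from the t distribution on n − 9 df, fewer covariates raising the df
accordingly). The exon test's expression covariate is the **leave-one-out**
gene expression: the raw RPKM summed over the other exons, then
rank-normalized. Subtracting the tested exon prevents the covariate from
swallowing the response in short genes; summing raw values and then
rank-normalizing is used because a sum of already-normalized values has no
natural scale. The junction and transcript tests adjust for the (rank
normalized) gene abundance. Transcripts with zero expression in more than
25% of samples are excluded before testing (the rank transform is degenerate
there), and the transcript test only runs for genes with at least two
annotated transcripts, the exon test for genes with at least two exons.

Missing dosages are mean-imputed per SNP (consistent with dosage-as-mean
semantics). Monomorphic SNPs and rank-deficient designs raise errors naming
the problem.

## Multiple testing and reporting filters

Benjamini–Hochberg at FDR < 0.05, applied within each test family (exon,
junction, transcript) separately because discoveries are counted per family;
pooling is a switch. Transcript discoveries additionally require a
nominally significant (p < 0.05) exon or junction record of the same
gene–SNP pair whose direction is consistent with the transcript's
composition: a feature contained in the transcript must share the sign of
β1, a feature excluded from it must have the opposite sign. Records failing
this gain the `transcript_uncorroborated` flag. Genes listed in a
user-supplied paralog/pseudogene table gain `paralog_suspect`. Flags are
reporting decisions; nothing is silently dropped.

## Mapping-bias audit

SNPs in LD with the index SNP at r² > 0.1 (from a supplied table, or squared
Pearson correlation of dosages when none is given) whose position falls
inside the associated feature trigger the audit. For a junction the "site"
is taken as both exonic flanks a junction read spans, since reads cross
both. The feature is recounted using only reads that overlap none of those
SNPs, and re-tested against the index dosage adjusting for gene expression
and ancestry PCs only (the hidden factors were fit on unfiltered data). The
original association is flagged `mapping_bias_suspect` when it was a
discovery (q < 0.05) but the re-test is not even nominally significant
(p ≥ 0.05); the before/after criterion is a documented operational choice.

## Fine-mapping posteriors and overlap

Under a single causal variant per trait per locus, the expected marginal
z-scores when SNP i is causal are μ_j = z_i·r_ij, so
ℓ_i = MVN-density(Z; z_i·Σ[:,i], Σ), computed in log space via one Cholesky
factorization shared across SNPs, and P_i = ℓ_i/Σ_j ℓ_j by log-sum-exp. The
normalizing constant cancels in P_i and can be dropped; it is retained by
default so ℓ_i is a true density. A ridge (default 10⁻⁶, configurable) on
the diagonal keeps perfect-LD pairs invertible. Observed z_i (not a
shrunken effect) is used in the mean. Splicing z-scores derive from the
association p-values by z = sign(β)·Φ⁻¹(1 − p/2); t-derived z-scores are
treated as normal, a negligible approximation at n ≈ 350.

Credible sets sort SNPs by descending posterior (ties broken by genomic
position, then id) and take the smallest prefix with cumulative mass
≥ 0.95. The overlap decision sums the *other* trait's posteriors over that
set: < 0.05 excludes a shared causal variant, anything else leaves sharing
unexcluded. Panels are merged by SNP-id intersection with allele
harmonization (a swapped effect/other allele pair flips that SNP's z in one
trait; unmatched allele pairs are dropped with a warning). Fine-mapping SNP
filters keep MAF > 0.001 and, for imputed SNPs, INFO > 0.5.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions for every test:

* **Genotypes** — two haplotypes per sample from a Gaussian copula with
  block-constant correlation, thresholded at the MAF quantile. Dosages are
  integer {0,1,2}; target LD is approximate (the latent correlation exceeds
  the realized dosage correlation slightly). Positions are evenly spaced
  (1 kb) on one chromosome.
* **Expression** — a two-isoform gene (inclusion vs skipping of the middle
  exon): the affected isoform's share is ψ = logistic(β₀ + β·g); transcript
  abundances are the gene total × shares × log-normal noise (sd 0.2 by
  default, a typical biological CV); exon/junction/gene values are exact
  sums over containing transcripts, so at zero noise exon RPKM equals the
  sum of its transcripts' abundances. Confounders are standard-normal
  sample scores with N(0, strength) loadings applied multiplicatively to
  the gene total, and to background features for the factor analysis.
  Units fix library size 10⁷ and take feature lengths from the gene model.
* **GWAS summary statistics** — Z ~ MVN(λ·Σ[:,c], Σ): the causal SNP's
  expected z is λ and LD propagates it; marginal variances are 1.
* **Read tables** — per-exon Poisson reads; in the SNP-bearing exon each
  read overlaps the SNP with probability 0.5 (read length ≈ half the exon),
  carries the alternate allele with probability dosage/2, and survives
  mapping with the allele's rate. Non-overlapping reads always survive,
  which is exactly the information the recount uses.

Not emulated: raw FASTQ/BAM, sequencing error, transcript-length bias,
somatic copy-number or methylation effects, and the generative process of
real tumors generally — all distributional choices are desk-scale stand-ins.
Passing tests therefore demonstrate the *statistical machinery* (calibration,
power, bias-correction, discrimination) under a correctly specified model,
not performance on real tumor transcriptomes.

## Simulation-study conditions (evaluation module)

Chosen once as realistic desk-scale conditions: fine-mapping loci of 50 SNPs
in five blocks of 10 at r = 0.8 with causal λ = 5 (coverage) or 6
(discrimination); exon-test recovery at n = 358 samples with a planted
standardized slope of 0.4 (planted directly on the log scale with matched
noise, as the logistic-ψ route has no closed-form slope inverse); type-I
error from 2 000 null cohorts; ancestry confounding with two populations of
150, test-SNP frequencies 0.2 vs 0.5, a 0.8-sd expression shift, and a
400-SNP ancestry-informative panel for the PCs (a panel that size estimates
ancestry nearly perfectly, as genome-wide panels do; much smaller panels
leave visible residual confounding); mapping bias with ref/alt rates
1.0/0.8 at n = 300 over 200 cohorts. `scripts/acceptance.py` re-runs all
of these and reports every measured number; nothing in this note states a
result those runs do not compute.

## Numerical choices and edge cases

* Rank transform: (r − 0.5)/n with average ranks; single values map to 0.
* PCA/SVD: exact column re-centering before SVD; components returned as
  scores (left singular vectors × singular values); requesting more
  components than the matrix rank is an error (the pipeline caps with a
  warning on small synthetic cohorts).
* Posterior normalization cleans residual floating-point mass so ΣP_i = 1
  exactly; credible-set thresholds compare with ≥.
* BH q-values come from the standard step-up procedure (statsmodels).
* Determinism: every generator takes a seed or Generator; identical
  (config, seed) reproduce outputs byte-for-byte, including pipeline report
  files (no timestamps in report bodies).

## Known limitations

Single-gene loci per pipeline run; single-causal-variant assumption in the
fine-mapping (no conditional or multi-signal modeling); the overlap method
presumes both traits genuinely harbor a signal at the locus — it asks only
"same variant or different?", not "is there a signal?"; BAM-native input is
out of scope (the read table is the interface; an adapter can feed it);
the SVD factor surrogate does not model count noise the way a full
variational factor model would.
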