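# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-cohort generator's assumptions, the numerical conventions, and
the design choices made where the analysis was genuinely open.

## XIST stratification

Female lines are stratified on `log2(XIST TPM + c)` with pseudocount
`c = 0.01`: strictly below 1.0 → Low, strictly above 2.75 → High,
otherwise Medium. Values exactly on a threshold fall to Medium because
the thresholds are strict inequalities; the pseudocount only matters for
zero TPM, where it maps to log2 ≈ −6.6 (deep Low). Male lines are never
stratified — XCI is a two-X phenomenon.

TMT multiplexing can concentrate High-XIST lines in a few plexes, which
would confound the Low-versus-High comparison with batch structure. Any
plex contributing more than `max_lines_per_plex` (default 4) High lines is
therefore reduced: its lines are clustered hierarchically (average
linkage on 1 − Pearson correlation of log10 copy-number profiles — a
scale-free distance), the tree is cut at k = 4, and each cluster's medoid
(minimum summed within-cluster distance) is retained. Ties, and the
top-up needed when tied merge heights produce fewer than k clusters, are
resolved lexicographically on line id, making the operation deterministic
and idempotent. The linkage, distance and representative-selection rules
are this package's choices; nothing in the source analysis pins them.

## Allele-specific expression

For a heterozygous SNP with allele counts (a, b), the statistic is the
folded secondary-allele fraction `min(a, b)/(a + b)` — the fraction of
reads from the less expressed allele, in [0, 0.5]. SNPs with fewer than
`min_reads_per_snp = 20` overlapping reads are excluded (not zeroed): a
shallow SNP is unmeasurable, and emitting 0 would masquerade as perfect
silencing. Gene-level values are unweighted means of per-SNP fractions;
band- and chromosome-level values pool all passing SNPs in the region by
default (a `gene_mean` alternative is provided, since pooling versus
two-stage averaging is an open choice). Folding is per SNP: no phasing is
attempted, so two SNPs of one gene may fold to different physical
alleles; with erosion fractions below 0.5 this biases the gene mean by at
most the binomial tail mass above depth/2 (≈ 0.003 at fraction 0.4, depth
60). The primary allele of a gene in a line is the allele with the larger
summed count across passing SNPs, ties to allele a.

## Proteomic ruler and batch correction

Protein groups flagged as contaminant, reverse or only-identified-by-site
are removed, then groups with fewer than 3 Razor + unique peptides.
Copy numbers per cell anchor each line's reporter intensities to the DNA
mass of a diploid human cell (default 6.5 pg, configurable):

    copies(i, j) = I(i, j) · m_DNA · N_A / ( MW_i · Σ_histones I(h, j) )

Consequences used as invariants: the summed histone mass per line equals
m_DNA exactly, and copies are invariant to any per-line rescaling of all
intensities (loading and labelling efficiency cancel). Histone anchors
are found via the annotation's histone flag, with an H1*/H2A*/H2B*/H3*/H4*
gene-family fallback. Missing intensities stay missing — they never enter
sums.

The batch correction multiplies all copies of a plex by
`grand median(per-line protein mass) / median(per-line mass of the plex)`.
This preserves within-plex ratios exactly and is idempotent; the exact
correction used in the source analyses is cited but not specified, so
median-mass equalisation was chosen as the simplest transformation with
those two properties. Note its limit: an effect that rescales a whole
line uniformly — histones included — is invisible to the ruler and hence
to this correction; what it corrects is histone-relative (proteome vs
anchor) plex variation, which is also what the synthetic generator
injects.

Protein content is `Σ_i copies(i, j) · MW_i / N_A · 1e12` pg per line;
the 60S/40S ratio divides the summed copies of the annotated large-subunit
set by the small-subunit set per line. Group comparisons report the
percent difference of group medians and Welch's unequal-variance t.

## Differential expression

Expression is compared between Low and High XIST lines per gene on log2
values (TPM with pseudocount 0.01; copies as log2 with non-positives
treated as missing). The fold change is the difference of group means of
logs — identical to the coefficient of a two-group linear model. The
default test moderates the per-gene pooled variance with an
empirical-Bayes prior estimated by moment matching on log variances
(digamma/trigamma identities of the scaled-F distribution of s²; prior
df by trigamma inversion). The moderated t and p agree with R limma to
~1e-15 on shared fixtures (a test runs limma through Rscript as the
independent oracle). With the prior df forced to 0 and equal group sizes
the statistic reduces to the ordinary two-sample t. Welch's t is the
alternative branch. Genes with fewer than 3 observations in either group
are reported with missing statistics and excluded from FDR.

Storey q-values are the default: pi0 is a cubic-polynomial smooth of
pi0(lambda) over lambda ∈ {0.05, …, 0.95} evaluated at 0.95, clipped to
(0, 1]; q is the step-up minimum of `pi0 · m · p_(j) / j`. Below 100
tests the smoother is unstable and pi0 falls back to 1 (BH). Protein DE
uses the capped High set; RNA DE uses all High lines.

## Genome maps and reported percentages

Chromosome summaries are restricted to genes quantified on both layers:
median and SEM (sample SD/√n) of per-gene log2 fold changes per layer,
the Pearson correlation between the layers' fold changes (undefined below
3 genes), and counts/percentages of q ≤ 0.05 genes. Reported percentages
round half-up to one decimal; the unrounded fraction is kept alongside
because rounding conventions can disagree in the last digit (e.g.
2,383/8,593 = 27.73% half-up rounds to 27.7 while 27.8 has also been
printed for the same counts). Three independent half-up roundings of the
up/down/ns shares can deviate from 100 by up to 0.15.

## Enrichment

Given a universe of proteins detected on both layers and a subset (by
default: significantly up at the protein level without an RNA increase),
membership above the 75th percentile of a metric (median copies, or
peptide count) is tested two ways: the exact hypergeometric upper tail
P(X ≥ k), and a resampling null that redraws `n_iterations = 100,000`
uniform subsets of the same size and counts members above the threshold
per draw. The empirical p uses the add-one estimator
`(1 + #{draws ≥ observed}) / (n_iterations + 1)`, which cannot return 0.
The percentile is the linear-interpolation quantile and membership is
`≥ threshold` (a strict mode exists) — both conventions are pinned
because the resulting thresholds are convention-dependent.

## The synthetic cohort generator

The generator emulates the study conditions as its defaults: 74 female
lines (30 Low / 9 Medium / 35 High by construction of the bimodal XIST
draw), 46 male lines, TMT 10-plexes assigned round-robin in line order,
per-SNP binomial allele counts at Poisson(60) depth with per-line
secondary fraction 0.226 (Low) or 0.005 (High and Medium — the medium
population tracks the high one), an X-linked RNA+protein fold of 1.27
with gene-level escape propensities concentrated in hotspot bands (Xp22,
Xq23, Xq26) and normalised to the configured mean log-fold, and a
protein-only autosome fold of 1.13 (the global translation factor).
Male lines are hemizygous (one X allele) and unamplified.

Scale realism: 840 genes stand in for the proteome, so per-gene
abundances are rescaled to give a realistic reference proteome mass
(200 pg/cell) and an X mass share near 5%; histone anchor copies are set
so their summed mass equals the DNA mass exactly, making the ruler exact
on noiseless data. Protein and RNA abundances are coupled on the log
scale with independent noise chosen to give an abundance correlation
near 0.6. Per-protein measurement noise shrinks with peptide count
(sd ∝ 1/√RUP, as peptide-rich proteins average more evidence); this is
what couples detectability to abundance and lets the
high-abundance/high-peptide enrichment of protein-only responders emerge.
Histones draw 30–45 peptides, reflecting their saturated coverage in real
TMT data — and keeping the ruler anchor precise. Plex effects are
multiplicative log-normal factors applied to non-histone intensities:
a uniform per-line factor would cancel in the ruler exactly, so the
recoverable (and correctable) batch effect is by nature histone-relative.

What the generator does **not** emulate: missing reporter intensities,
linkage/haplotype structure or mapping bias in allele counts, per-gene
biological variance heterogeneity, plex-line confounding (round-robin
assignment mixes strata evenly, so the default cohort never triggers the
High-set cap — that operation is exercised on constructed fixtures), or
transcriptome-wide amplification artefacts. Passing tests therefore show
correctness of the estimators under the stated generative model, not
robustness to those real-data complications.

## Problem sizes and calibration experiments

The recovery and calibration experiments use sizes chosen to make
Monte-Carlo error small relative to the tolerance being checked:
secondary-fraction recovery uses 200 X genes × 30 eroded lines × 3 SNPs
(median over ~18,000 gene-line fractions; binomial error ≪ 0.02);
content recovery reports the median over three cohort replicates (the
per-cohort estimate has ≈1.3 pp spread, driven by the plex-median noise
of the batch correction); type-I calibration pools ~6,500 gene tests
across 20 effect-free cohorts. The resampling-versus-hypergeometric
agreement check runs 10,000 iterations, as the 3-standard-error bound is
evaluated at that count.

## Known limitations

* The batch correction slightly attenuates true group differences when
  line-mass noise lets inflated lines cross the plex median; with the
  default noise this bias is below 0.5 pp of content difference.
* Storey's pi0 smoother needs a few hundred p-values; small panels fall
  back to BH.
* Multi-accession protein groups are mapped to chromosomes via their
  first (majority) accession; groups whose accessions disagree on
  chromosome are the annotation preparer's responsibility.
* The capped High-set size depends on the copy-number profiles, so the
  retained count is cohort-specific, not a fixed number.
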