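# Methods

## Scope and model

`spliceqtl` implements a splicing-QTL analysis that starts from split-read
junction counts and ends at the characterisation of disease-colocalised
splice junctions. The quantitative trait is the **intron usage ratio** of
intron *k* within its intron-excision cluster,

    R_k = X_k / Σ_{i ∈ cluster} X_i ,

where X_i are split-read counts. Clusters are connected components of the
graph joining junctions (same chromosome and strand; unknown-strand
junctions form their own stratum) that share a donor or acceptor
coordinate. The clustering refinement iteratively removes introns carrying
less than `min_intron_frac` (default 0.001) of their component's reads and
recomputes components until stable; clusters need ≥ 2 introns and ≥ 50
reads across samples. Junctions must be 50–500,000 bp long (inclusive) with
an anchor of ≥ 8 aligned bases on both sides; the `.junc` reader converts
the BED12 record span to intron coordinates (chromStart + first block size,
chromEnd − last block size, 0-based half-open) and drops records flagged as
variant-ambiguous in an optional 13th column.

## Normalisation

Raw ratios pass four steps: (1) drop introns with a zero ratio in strictly
more than 40% of samples or an across-sample SD below 5 × 10⁻³ (an optional
cluster-level missingness filter exists behind `cluster_missing_frac`;
default is the intron-level rule); (2) impute cluster-total-zero gaps with
the intron's observed mean; (3) quantile-normalise samples onto the mean
order-statistic vector, averaging target quantiles across ties; (4)
rank-based inverse normal transform per intron with the Blom offset
c = 3/8. Because quantile normalisation draws every column from one value
pool, within-intron ties are common and average ranks would leave a small
(~10⁻³) residual row mean; each row is therefore recentred to exact zero
mean, a no-op for tie-free rows. Usage PCs come from SVD of the centred
sample × intron matrix with a deterministic sign convention (largest
loading positive).

## cis-sQTL mapping

Within a ±1 Mb window around the TSS (half-width interpretation,
configurable), every intron of a gene is tested against every variant by
OLS of normalised usage on dosage plus covariates. The gene-level statistic
is the minimum nominal p over intron × variant pairs. Permutations shuffle
the genotype sample labels — one shuffle per round shared by all introns of
the gene — so the intron–intron correlation inside a cluster is preserved;
`empirical_p = (1 + #{perm_min ≤ obs_min}) / (n_perm + 1)`. A Beta ML fit
to the permutation minima gives an optional smoothed tail p, but the
empirical p is what enters the FDR. Per-gene permutation streams are keyed
by (master seed, CRC-32 of the gene id), so results do not depend on gene
order and genes can run in parallel. Ties for the best pair break on
nominal p, then variant position, then intron id.

Gene-level FDR uses Storey q-values: π₀ is estimated from
π₀(λ) = mean(p > λ)/(1 − λ) on λ = 0.05…0.95 with a cubic least-squares
smoother evaluated at λ = 0.95, clamped to [1/n, 1]; with fewer than 20
p-values π₀ falls back to 1 (pure Benjamini–Hochberg). Genotype QC removes
variants with INFO < 0.4, HWE chi-square p < 10⁻⁶, MAF < 0.05 or
missingness > 0.001. The PC sweep reruns the permutation pass over a grid
of usage-PC counts and keeps the k with the most sGenes at FDR ≤ 0.05
(ties to smallest k).

## Differential splicing (simplified)

The two-group cluster test is a multinomial-logit likelihood-ratio test on
aggregated per-group intron proportions, df = #introns − 1, with a
Williams-type moderation: the LRT is divided by the Pearson overdispersion
factor when it exceeds 1. This is a deliberate simplification of the
Dirichlet-multinomial likelihood used by dedicated differential-splicing
tools — the plain multinomial LRT is anti-conservative under biological
overdispersion, and the moderation restores approximate calibration
without the full DM fit. Reported effects are per-intron log-odds changes
(Haldane 0.5 continuity for empty cells) and ΔPSI (difference of group
mean raw ratios); the per-intron "log effect" is therefore analogous to,
but not numerically identical with, the reference tool's effect scale.
Cluster filters follow the reference defaults: ≥ 50 samples per intron,
≥ 50 covered samples per group, coverage = cluster total ≥ 30. Genes are
flagged when any cluster has BH-adjusted p < 0.05 and |log effect| > 0.5,
reporting the intron with the largest absolute effect.

## Multi-condition shrinkage and response sQTLs

Condition-wise effect estimates are compared on **baseline-contrast
coordinates**: each stimulated condition c with matched control b becomes
β_c − β_b with se = √(se_c² + se_b²) (disjoint scans treated as
independent). This replaces the reference tool's internal common-baseline
transform with explicit contrasts — the same inferential target, simpler
algebra. On z-scores, effects follow a mixture of zero-mean multivariate
normals over covariance patterns: null, identity, per-condition
singletons, an all-ones shared matrix, and up to three data-driven rank-1
components from the top PCs of the strong-subset z-scores (a stand-in for
extreme-deconvolution learning), each over the scale grid
{0.25, 0.5, 1, 2, 4} × median strong-subset z². Mixture weights are fitted
by EM on the random subset (log-likelihood is monotone; non-convergence
after 300 iterations returns the best iterate flagged). Posteriors are
conjugate mixtures; the **LFSR** of a contrast is
min{P(b ≥ 0), P(b ≤ 0)}, with point-mass-at-zero components counting
toward both signs. A test is a response sQTL in condition c when the
contrast LFSR is strictly below 0.05.

## Colocalisation

Per variant, the Wakefield log-ABF is ½[ln(1 − r) + r z²] with
r = W/(V + W), V = se², and prior effect SD √W = 0.15 (quantitative) or
0.2 (case-control), the delegated tool's documented defaults. Five
hypothesis sums are accumulated with log-sum-exp (no overflow up to
|z| = 300); the H3 term (ΣBF₁)(ΣBF₂) − ΣBF₁BF₂ is computed in signed log
space and clamped to −∞ when it cancels (single shared variant). Priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. Variants are matched across traits by
position only, so effect directions across traits are unverified by
alleles; pairs sharing fewer than 20 variants are skipped. GWAS loci are
defined greedily: significant variants (p < 5 × 10⁻⁸) visited in
ascending p order each seed a 1 Mbp centred window unless already covered.
A locus is attributed "both" when both the max sQTL PP4 and max eQTL PP4
reach 0.75, "sQTL-only" when S ≥ 0.75 and S > E, symmetrically
"eQTL-only", else "neither".

## Junction characterisation

The **high-genotype IUR** is the mean raw usage ratio among samples
homozygous for the usage-increasing allele (dosage coding flipped when the
association slope is negative); with no homozygote the most extreme
available genotype group is used and flagged "extrapolated". Low usage
means high-genotype IUR < 0.1 (strict). Raw ratios are used for
classification; normalised values are for plotting only. Annotation
against GTF-derived reference introns yields DA (exact intron), NDA (both
sites known, pair unseen), A (known acceptor/novel donor), D (known
donor/novel acceptor) or N; the canonical flag checks GT..AG intronic
dinucleotides on the junction's strand (CT..AC on the plus strand for
minus-strand introns). Enrichment of low usage in colocalised vs tested
introns uses Fisher's exact test with the conditional-MLE odds ratio, over
a cutoff grid 0.01–0.1 on request. Long-read replication is exact
coordinate matching against isoform intron chains, optionally within a
cell group, with a guard that raises when > 50% of annotated junctions
fail but a systematic ±1 shift would rescue them (coordinate-convention
mismatch).

## Synthetic data

The generator plants known effects so every stage can be scored against a
truth table. Genotypes are HWE at MAFs drawn within `maf_range`, with
local LD from a latent AR(1) Gaussian copula (coefficient `ld_rho`)
thresholded to genotype classes. Junction counts per sample and cluster
are negative binomial totals (mean 100, size 10 by default) allocated by a
Dirichlet-multinomial (concentration 30) around per-gene baseline
proportions; sQTL genes shift the target intron's logit proportion by
`effect_size` (default 0.75) × dosage, scaled per condition by a response
factor (0 = absent, 1 = shared, > 1 = amplified; response genes default to
induced-only effects). GWAS summary statistics come from per-variant OLS
of a simulated quantitative trait on an independent panel (n = 10,000)
sharing the variant set and LD, so LD leakage into flanking variants is
realistic; the causal variant explains 1% of trait variance under H4
(shared with the sQTL) or H3 (the least-correlated variant in the window),
and the default scenario mix is ⅓ each none/H3/H4. All streams derive from
one seed; identical config + seed reproduces outputs byte-identically.

The direct effect-panel generator used for the shrinkage stage draws
effect magnitudes Uniform(0.5, 1.0) with random sign: it emulates **lead
SNPs of genes that passed FDR ≤ 0.05**, whose effects at n ≈ 200 and
se ≈ 0.1 necessarily satisfy |z| ≳ 5 — a zero-centred effect distribution
would describe pre-selection effects, not a strong subset.

What the generator does *not* emulate: read-level artefacts, alignment
bias, population structure, multi-causal architectures within a window,
allele-frequency–dependent effect sizes, and sharing of samples across
conditions (condition scans are independent draws). Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed generative model, not robustness to real-data artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen to keep Monte
Carlo error small relative to the asserted margins: calibration at 500
null genes (n = 150, 1000 permutations), power/FDR at 300 genes × 3 seeds
(10% planted sQTLs), colocalisation discrimination at 200 loci per
scenario, response recovery at 300 strong tests with a 3000-test random
panel, and the end-to-end planted low-usage scenario at 50 genes
(n = 200, 1000 permutations). The permutation pass is vectorised (one
matrix product per permutation chunk), which is what makes these sizes
cheap. Degenerate inputs are handled explicitly: constant or
covariate-collinear dosages are skipped with a reason, empty clusters and
all-missing introns raise, and the EM jitters component covariances by
1e-8 × mean diagonal before Cholesky.

## Known limitations

- The differential-splicing p-values are approximate under strong
  overdispersion; the moderation targets calibration, not efficiency.
- Position-only variant matching cannot detect allele flips between
  traits; cross-trait effect signs are reported unverified.
- The mash-style fit uses a fixed canonical + PCA covariance library; it
  will under-fit sharing structures far outside that library.
- Storey's π₀ is noisy below ~100 genes; the pipeline is intended to run
  with hundreds of genes per condition (the small-n fallback is plain BH).
- The no-homozygote fallback for the high-genotype IUR extrapolates from
  the most extreme observed genotype group and is flagged, not dropped.
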