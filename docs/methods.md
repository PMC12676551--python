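# Methods

## Model and procedure

The package analyzes how a set of disease-associated variants perturbs
the plasma proteome. Its statistical core is three nested models:

**PRS and pQTS.** The polygenic score for individual *i* is
r_ci = Σⱼ βⱼ G_ji, with G the effect-allele dosage and βⱼ external GWAS
weights taken as given from a scoring file. A protein quantitative trait
score (pQTS) association is the simple linear regression
p_k = α₀ + α₁ r_c + ε of the adjusted protein level on the score, with a
two-sided t-test of α₁ = 0. The default significance threshold 1e-5 is a
Bonferroni-style correction for a panel of several thousand analytes and
is configurable since the analyte count varies between platforms. The
trans-restricted scan rebuilds the score per analyte from only its trans
SNPs, so a significant trans-pQTS cannot be an artifact of a single cis
effect. A SNP is cis to a protein iff it lies on the same chromosome
within 2.5 Mb of the gene's transcription start site; the boundary is
inclusive (a "within ±2.5 Mb" window reads as a closed interval), and the
TSS is the protein's only genomic anchor. Strong single-variant
trans-pQTLs are flagged at per-SNP p < 1e-6.

**Sparse CCA on summary statistics.** From standardized dosages X and
adjusted proteins Y we form Σ_G = corr(X), Σ_P = corr(Y) and
Σ_GP = XᵀY/n with cis pairs zeroed (masking, rather than dropping,
proteins that are cis to some variants; a `drop_cis_proteins` switch
removes them entirely). The whitened cross matrix
W = Σ_G^{-1/2} Σ_GP Σ_P^{-1/2} uses symmetric inverse square roots with
an eigenvalue floor (default 1e-3) because LD and protein-correlation
matrices are routinely near-singular; the floor is recorded in the
output. Components solve
argmax_{u,v} uᵀWv − λ₁‖u‖₁ − λ₂‖v‖₁ over the unit L2 balls by penalized
alternating power iteration (PMD-style): u ← normalize(S(Wv, λ₁)),
v ← normalize(S(Wᵀu, λ₂)) with S the soft-threshold operator,
initialized at the leading singular pair (deterministic). Each half-step
maximizes the penalized objective over its ball, so that objective is
non-decreasing along the iteration trace; at λ = 0 it coincides with
uᵀWv and the algorithm reduces to power iteration on the SVD.

The component strength is the cc-value q² = (uᵀWv)²/(uᵀu·vᵀv), the
squared cosine-normalized bilinear form, which equals the squared
leading singular value at the unpenalized optimum. An alternative
normalization q² = (uᵀWv)²/((uᵀWWᵀu)(vᵀWᵀWv)) is retained behind
`variant="as_printed"`; it is not the default because it *decreases* in
the association strength (1/σ₁² at the leading singular pair), which
makes it unusable as a test statistic. Successive components come from
rank-one deflation W ← W − √q²·uvᵀ.

**Sparsity selection.** The only selection criterion is support
disjointness: one penalty level is applied to the entire component
sequence, chosen as the smallest grid value whose nonempty components
select pairwise-disjoint SNP sets and pairwise-disjoint protein sets
(ties broken by larger total cc-value). A per-component penalty search
cannot satisfy this criterion when the grid contains 0 — the first
component would always be dense — whereas a single shared level also
matches how the null runs must mirror "the same sparsity levels". If no
grid level achieves disjointness (e.g. a single-point grid at 0), the
closest run is returned in full with a warning, so an unpenalized call
still yields the top-K singular triplets. Supports use an absolute
1e-9 magnitude cutoff, separating exact zeros produced by thresholding
from floating-point dust in singular vectors.

**Competitive test.** GWAS-significant variants are generically enriched
for trans-pQTLs, so component significance is judged against that
background rather than against pure noise: M times (default 1000), s
variants and p proteins are drawn without replacement from a background
pool, the whitened matrix is rebuilt with the same cis masking and
eigenvalue floor, and components are re-extracted at the penalties the
observed analysis selected. Pool-wide correlation matrices are computed
once and sliced per draw. Null components of rank k form the reference
for observed component k (rank matching — the conservative alignment
when the null run can return fewer components; an empty null rank scores
q² = 0). P-values use the add-one estimator
p = (1 + #{null ≥ observed})/(M + 1), which is strictly positive, at
most 1, and finite-sample valid under exchangeability. The pool excludes
nothing by default; a variant filter reproduces designs where the pool
is restricted to GWAS-significant variants.

**Annotation.** Driver enrichment is a one-sided (greater) Fisher exact
test of the 2×2 table of target/non-target × driver/non-driver over an
explicit gene universe — the universe is a required input because
enrichment is meaningless without a stated background; the sensible
default is the set of genes measured on the platform. The essentiality
test compares the targets' mean CERES dependency score (lower = more
essential, conventional cutoff −0.5, inclusive) against same-size
uniform random gene sets, again with the add-one estimator; an
exhaustive mode enumerates every subset for small matrices. Pleiotropy
tabulates per-cancer target sets (union of pQTS-significant and
component-selected proteins) into a protein × cancer incidence matrix
with shared-protein counts.

## Synthetic data generator

`simgen` emulates exactly the structure the analyses assume, so every
stage is testable with known truth:

- **Genotypes**: diallelic dosages as sums of two Gaussian-copula
  haplotypes; within each LD block the latent Gaussians follow an AR(1)
  process with coefficient `ld_rho` ∈ [0, 1), thresholded at each SNP's
  minor-allele-frequency quantile (MAF ~ Uniform over `maf_range`).
  Pairwise LD grows monotonically with `ld_rho`. The synthetic genome
  has two chromosomes, blocks spaced 100 kb with 10 kb SNP spacing, and
  protein TSSs from 200 Mb onward — every SNP is trans to every protein
  unless a cis effect explicitly relocates it next to its target's TSS,
  so cis/trans structure is realizable by construction.
- **Proteins**: on the log scale, protein k = Σ cis effects + Σ trans
  network effects (slopes per SD of dosage, so `effect_size` is an
  interpretable standardized effect) + Λ·confounders + N(0, noise_sd²);
  abundances are exponentiated (log-normal measurement scale), so the
  QC log-transform exactly recovers the linear model. Hidden-confounder
  loadings decay geometrically (factor 0.7) across factors, mirroring
  the decreasing variance shares of latent factors in omics data and
  making them identifiable by principal components. Every nonzero effect
  is recorded exactly once in a truth object.
- **PRS weights** are not part of the generative model (scores are
  externally trained in practice); random N(0, 0.1²) weights or explicit
  designed weights can be attached to any SNP subset.

What the generator does **not** emulate: population structure and
admixture, genotype uncertainty/imputation error, assay batch and plate
effects, non-Gaussian protein noise, LD between blocks, and binary
disease phenotypes. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not
robustness to these real-data complications.

## Defaults and numerical choices

| Parameter | Default | Why |
|---|---|---|
| pQTS threshold | 1e-5 | Bonferroni-style for a few thousand analytes; configurable |
| strong trans-pQTL | 1e-6 | conventional strong single-SNP evidence level |
| cis window | 2.5 Mb, inclusive, TSS-anchored | standard distal definition for trans-proteomics |
| CERES cutoff | −0.5, inclusive | recommended essentiality convention |
| eigenvalue floor | 1e-3 | regularizes near-singular correlation matrices |
| INT variant | Blom offset 3/8, ties = mean of spanned normal scores | deterministic, exactly testable |
| log base | natural | cancels after rank-INT anyway |
| resamples M / B | 1000 | resolution ~1e-3 for add-one p-values |
| components K | 5 | enough for the few separable networks per trait |
| penalty grid | 16 points, 0 → 0.9·max\|W\| | spans empty-to-dense supports |

Categorical covariates are one-hot encoded dropping one level
(identifiability); constant columns are dropped; rank-deficient designs
are an error naming the collinear columns. Allele harmonization matches
scoring-file SNPs to the panel on (chromosome, position), flips dosage
to 2−G when effect alleles disagree, reports match/flip/missing counts,
and flags strand-ambiguous (A/T, C/G) pairs. A master seed derives all
stage seeds via a seed sequence, making full runs bit-reproducible.

## Problem sizes used in the checks

The bundled demonstration plants two disjoint networks (8 SNPs → 12
proteins and 5 SNPs → 8 proteins, per-SD effects 0.15, one cis effect of
0.5) among 60 SNPs × 100 proteins at n = 1000 samples, M = 99 null
resamples. The statistical acceptance checks use n = 2000 with 100
replicates for the pQTS power properties, 20 replicates for network
recovery, and 200 repetitions at M = 199 for the validity of the
competitive test under an effect-free generator; fixtures isolating
power properties use unlinked SNPs (`ld_rho = 0`) so the planted truth
is the exact support. In the many-weak-effects fixture (ten trans SNPs
of per-SD effect 0.06) the residual SD is set to 1.15, placed by a
noncentral-t power calculation so the score-level test is well powered
while single-SNP tests stay clearly below the strong-pQTL threshold —
the regime the aggregated test exists to detect. The cis-only fixture
weights the cis variant at 1.0 against four background variants at 0.1,
so the full score carries the cis signal while the restricted score is
null.

## Limitations

- The hidden-factor stand-in is plain PCA; dedicated latent-factor
  models differ when factor and genetic effects are correlated.
- Penalty selection optimizes support disjointness only; it does not
  cross-validate predictive correlation, and confidence intervals on
  loadings are out of scope.
- The competitive test's rank matching assumes observed and null
  component orderings are comparable; with highly heterogeneous
  component strengths a max-over-ranks null would be more conservative.
- Sample alignment between panels is by identifier order, not by fuzzy
  matching; relatedness/mixed-model corrections are not implemented.
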