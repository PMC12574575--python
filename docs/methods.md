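# Methods

## Scope and model

`alcyte` analyses a cohort with matched bulk whole-blood DNA methylation
(CpG × sample beta values in [0,1]) and gene expression (gene × sample,
non-negative), a biomarker panel for allostatic-load (AL) scoring, a probe
annotation (chromosome, probe-type stratum, linked gene, blacklist flag), a
gene × cell-type signature matrix, and optionally GMT gene-set collections.
The core statistical object is the mixture identity for bulk tissue:

    x_ij = Σ_h w_ih · z_hij + ε_ij

with w the sample's cell-type fractions and z the latent cell-type-level
signal. All inference about AL acts on estimates of z, per cell type.

## Allostatic-load scoring

Two variants. The **index** score sums dichotomized biomarkers: marker b of
sample i contributes 1 iff its value lies strictly on the configured risk
side of its clinical cutoff (sex-stratified cutoffs supported; for HDL
cholesterol the risky side is *below* the cutoff). A value exactly at the
cutoff scores 0 by default (risk requires a strict inequality; configurable
via `dichotomize_at_cutoff`). Samples with any missing configured marker get
a missing score and are excluded from grouping rather than imputed. Groups:
low iff score ≤ 2 (configurable `al_index_cutoff`). With 14 markers the
implemented score range is 0–14; source descriptions of comparable indices
sometimes quote a smaller maximum produced by within-dimension aggregation,
which is not reconstructible from a plain sum and is therefore left to
configuration. The **z-score** variant sums absolute z-scores of the
configured biomarkers, standardised against the full supplied cohort
(sample SD, ddof=1); the group cutoff is the cohort's third quartile
(linear-interpolation quantile), echoed to the output so alternative
quantile conventions are auditable.

## Methylation and expression QC

Probes on chrX/chrY or blacklist-flagged are removed (a probe failing both
filters is removed once, counted under both reasons). Sex is inferred from
beta values directly: X inactivation leaves female chrX probes at
intermediate methylation, so a sample is called female when its median chrX
beta lies in [0.35, 0.65] (configurable window), male otherwise; samples
whose call contradicts the reported sex are dropped from all matrices.
Intensity-based sex checks are out of reach from beta matrices, which is why
the median-window rule is used.

Quantile normalization is stratified by the annotation's `stratum` column
(intended for Infinium probe type × color channel; any stratification the
user encodes works). Within a stratum the target distribution is the
element-wise mean of the sorted values of the designated reference samples
(all samples when none are designated); each sample is mapped rank-for-rank
onto the target with tie-aware interpolation. Strata never influence one
another; within-sample rank order is preserved; strata with fewer than two
probes pass through unchanged. A per-probe "methylation status" axis of
stratification is not implemented: it is not well defined for a single
per-probe sub-distribution split.

Expression rows are mapped source-ID → gene symbol; unmapped rows are
dropped, duplicate symbols collapsed by summing (configurable: `first`,
`max-mean`), and genes with no observed value in any sample removed.

## In-silico cell sorting

**Cell fractions.** Per sample, the bulk expression vector over the
signature genes (intersection with the bulk matrix; at least 10 genes
required) is regressed on the signature columns by non-negative least
squares; coefficients are renormalised to sum to one. NNLS replaces the
ν-SVR used by the popular online tool: it is deterministic and
dependency-light, and on low-noise mixtures the two agree; downstream stages
rely only on the non-negative, row-normalised contract.

**Expression purification.** Per gene, shared cell-type profiles g_h are
fitted by NNLS of the gene's bulk values on the proportion matrix; each
sample's residual is then redistributed across cell types proportionally to
w_ih·g_hj (proportionally to w_ih when all profiles are zero), which reduces
to a multiplicative per-sample rescaling of the profiles. Results are
clamped at zero. Zero-weight samples carry no residual (their slice equals
the shared profile). The exact high-resolution algorithm of the reference
tool is unpublished in implementable detail; the preserved contract is a
per-sample per-cell-type signal whose proportion-weighted mixture
reconstitutes the bulk.

**ReFACTor-style components.** Sites are standardised, technical covariates
regressed out, each site scored by the distance to its rank-k
principal-subspace reconstruction; the t lowest-error sites are selected and
the first k principal components of the selected submatrix are returned as
per-sample composition surrogates. Defaults k=6 (matching the six cell
types), t=500.

**Tensor composition analysis.** Per CpG j,

    x_ij ~ N( Σ_h w_ih (μ_hj + c1_i·γ_hj) + c2_i·δ_j ,
              Σ_h w_ih² σ_hj² + τ_j² )

is fitted by alternating weighted least squares on the mean parameters
(μ, γ, δ) and bounded L-BFGS likelihood maximisation on the variances
(σ²_hj, τ²_j ≥ 0), iterated until the relative log-likelihood change falls
below 1e-6 (at most 100 alternations); both steps cannot decrease the
likelihood. Means are clipped to [0,1]. Cell fractions come from the
expression-based estimate and are not refitted. The per-sample cell-type
methylome ("tensor") is the conditional expectation

    ẑ_hij = μ′_hij + w_ih σ²_hj / (Σ_l w²_il σ²_lj + τ²_j) · (x_ij − m_ij)

where μ′ folds in cell-level covariates and m is the full model mean;
entries are clipped to [0,1]. In the assembled pipeline c1 = sex, age
(standardised), smoking and c2 = recruitment centre; the AL label is *not* a
covariate — the tensor is generated unconditionally and the group contrast
happens downstream, so state calling cannot be circular. Family identifiers
are arbitrary labels and are not used as a numeric covariate.

## Methylation states and functional pairs

For each CpG of a cell type, mixtures of 1–3 beta densities are fitted to
the **high-AL group's** tensor values by EM (quantile-anchored starts, three
per component count; component parameters updated by a few warm-started
Newton steps toward the weighted beta MLE — a generalized EM, so the
likelihood is non-decreasing); the component count is grown while the
Bayesian information criterion improves. A component is **hyper**methylated
when its mean exceeds the low-AL mean by more than `dm_threshold` (default
0.10 beta units) *and* its member samples' betas are significantly higher
than the low-AL betas by one-sided rank-sum test (p < 0.05); **hypo**
symmetrically; other members are **normal**. Prevalences are fractions of
high-AL samples. A computational screen skips the mixture fit for CpGs where
fewer than two high-AL samples deviate from the low-AL mean by more than
`dm_threshold`: such CpGs cannot produce an abnormal component whose members
pass the rank-sum gate, so they are all-normal by construction.

Each abnormal subset is then tested for coordinated expression change in the
linked gene (links from the annotation's `gene` column; multi-gene probes
expand to one link per gene): one-sided rank-sum of the subset's purified
expression against the normal-state high-AL samples pooled with all low-AL
samples. Negative mode expects hypermethylated subsets to be *lower* and
hypomethylated subsets *higher* in expression; positive mode reverses both.
Rank-sum is preferred to a t-test because purified expression is
non-Gaussian by construction; ties use the normal approximation with tie
correction. Subsets smaller than `min_subset` (default max(5, 5% of the
high-AL group)) are not tested. P-values are Benjamini–Hochberg adjusted
jointly across all subset tests of one cell type × mode (the adjustment
scope is this package's documented choice); records with adjusted p below
`alpha` (default 0.05) are **functional CpG-gene pairs**, with state *dual*
when both a hypo and a hyper subset pass. Negative- and positive-mode tables
are concatenated with the mode retained.

## Direction of regulation

Per CpG: hypo+negative or hyper+positive → **up**; hyper+negative or
hypo+positive → **down**. Dual CpGs first resolve to the state with the
strictly higher prevalence; equal prevalences have no dominant state and the
CpG is excluded from direction calling (logged) — a conservative,
configurable choice since the highest-prevalence rule is undefined at
equality. A gene's CpG calls are pooled across modes within a cell type; the
gene is up/down only under unanimity, otherwise **inconsistent** and
excluded from downstream proportions and enrichment. The summary reports
per-cell-type and global pair/DMG counts, state and direction proportions
(full precision in data, one decimal in the rendered report), and genes
shared between cell types (occurrence and unique tallies both reported).

## Over-representation

For each non-empty (cell type × direction) stratum and each GMT namespace,
the overlap k between the stratum's genes (n of them) and each set (K of its
genes inside the universe, universe size N) gets the upper-tail
hypergeometric probability P[overlap ≥ k]; Benjamini–Hochberg runs per
namespace per stratum. The default universe is the genes present in the
expression matrix after preprocessing — the actually tested space — and is
configurable. The reported `gene_ratio` is k/n (overlap over query size);
k, n, K, N are all stored so k/K is derivable. No set-size filter is applied
by default (configurable).

## Synthetic cohorts

The generator emulates the assumed study design: 429 samples of which 126
high-AL; six blood cell types (CD8 T, CD4 T, B, NK, neutrophils, monocytes)
mixed per sample with Dirichlet(10, 8, 3, 2, 14, 5) — neutrophils dominant,
as in whole blood; cell-type methylomes drawn from low Beta(2,10) /
mid Beta(5,5) / high Beta(10,2) regimes with 20% of CpGs made
cell-type-discriminative (spread > 0.3); log-normal expression with 300
signature genes given a distinct marker cell type; bulk = mixture + additive
Gaussian methylation noise (sd 0.03, truncated to [0,1]) and multiplicative
log-normal expression noise (sd 0.1). Each planted pair anchors its CpG at
beta 0.5, shifts a fraction (default 0.3) of high-AL samples by ±0.3 in the
chosen cell type, and shifts those samples' cell-level expression of the
linked gene by 2 cell-level SDs with the sign that makes the pair detectable
in the intended mode; dual pairs plant two disjoint subsets with the hyper
subset larger so the prevalence rule has a winner. Biomarkers: 14 Gaussian
markers with cutoffs at mean+SD (HDL-style marker: mean−SD, risk below);
high-AL samples get 3–6 markers pushed strictly past threshold, low-AL 0–2,
reproducing the skewed integer score distribution of dichotomized indices.
chrX probes carry the female-intermediate/male-extreme regimes used by sex
inference; reported sex is flipped for a configured number of samples.
Feature space defaults to 2,000 CpGs × 1,500 genes so the full pipeline runs
in minutes — these generator defaults are the package's standard study
conditions for all recovery tests.

What the generator does **not** emulate: genomic coordinates and probe
chemistry, linkage between CpGs, distance-decaying or non-monotone
methylation–expression relationships, realistic biomarker covariance, and
batch structure. Passing recovery tests therefore demonstrates correctness
of the estimators under the mixture model's own assumptions, not performance
on real arrays.

## Numerical choices and degenerate inputs

Beta values are clamped to [1e-4, 1−1e-4] before mixture likelihoods; a
constant CpG collapses to a single component directly. Mixture EM runs at
most 50 iterations to relative tolerance 1e-5; TCA alternations at most 100
to 1e-6. NNLS coefficient vectors summing to zero renormalise to the uniform
fraction vector. Proportion rows must sum to 1 within 1e-8. An empty gene
universe, empty query, or empty stratum yields an empty result with a
warning rather than an error. Full-pipeline determinism under a fixed seed
is exact: no stage uses randomness outside the generator (mixture starts are
quantile-anchored, hence deterministic).

## Known limitations

End-to-end power at the default study conditions is modest by construction:
the tensor is a shrinkage estimator, so a 0.3 beta shift confined to a
30% subset of one cell type is attenuated roughly by the cell's fraction
before re-amplification, and purified expression smears sample-specific
shifts across cell types in proportion to w·g. Detected planted pairs
carry the correct direction almost always, but detection concentrates in
abundant cell types (neutrophils, CD8 T) — mirroring the known behaviour of
tensor-composition estimates for rare cell types. The association stage's
sensitivity is therefore assessed on cell-resolved matrices (where it is
high), and the end-to-end criterion scores direction fidelity among
detected genes.
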