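# Methods

## The analysis in one paragraph

A species recolonized its native range from two glacial refugia, leaving an
eastern and a western genetic cluster joined by a longitudinal admixture
cline; it was later introduced, via small founder groups, to environments
scattered far outside that range. The pipeline asks three questions.
First, is genetic diversity across native, introduced and farmed
populations governed by refugial ancestry or by recent introduction
history? Second, which loci in the native range track climate once
neutral structure is controlled for? Third, how far is each introduced
population's climate from the climate its Fst-nearest native source is
associated with — the genomic offset?

## Genotype substrate and filters

Genotypes are biallelic SNP dosages (ALT-allele counts 0/1/2, NaN missing)
read from VCF. Filters are applied in a fixed order: (1) site minor-allele
count, counted on non-missing allele copies; (2) site missingness; (3)
individual missingness, computed after the site filters (mirroring
sequential VCFtools runs); (4) first SNP per assembled locus, with the
locus tag parsed from STACKS-style `locus_column` IDs. Depth-based
filters act upstream of the genotype matrix and are out of scope.
Filtering is idempotent and never mutates its input.

## Diversity and its predictors

Ho, He and π are per-variant-site quantities averaged over variant sites
only (the reduced-representation convention), so values are comparable
between runs of this pipeline, not to genome-wide π. π uses the
sample-size-corrected estimator `2p(1−p)·n/(n−1)` with `n` non-missing
allele copies. A private allele is an allele seen in exactly one
population of the sampled set. The models
`metric ~ status + q_W + q_W²` use OLS with nested-model F-tests for
Ho/He/π and a Poisson log-link GLM with deviance likelihood-ratio χ² for
private-allele counts; the quadratic ancestry term captures the
diversity peak expected at intermediate admixture. Per-status fitted
means are reported at the sample-mean ancestry with Wald 95% intervals
(on the link scale for the Poisson model). With a zero-variance response
the R² is defined as 0.

## Ancestry and cluster number

The admixture model treats dosage `d_il ~ Binomial(2, π_il)` with
`π_il = Σ_k Q_ik F_kl`. We maximize this likelihood by EM block
coordinate ascent (the classic frappe updates), which is monotone;
missing dosages are excluded from the likelihood rather than imputed.
K = 1 has the closed form Q = 1, F = pooled frequencies. The solver
differs from the sequential-quadratic-programming optimizer used by the
ADMIXTURE program but climbs the same likelihood; cross-validation errors
are therefore comparable within a run, not across programs.
Cluster number is assessed by masked-entry cross-validation: a fraction of
observed genotype entries is hidden per fold, the model refit, and the
squared error between hidden dosages and `2π` accumulated. The error
curve is exposed rather than auto-thresholded — real datasets often show
no clean minimum — and the per-K fits use fold- and K-specific seeds.

## Differentiation

Pairwise Fst is the Weir & Cockerham (1984) θ as a multi-locus ratio of
sums of the a/b/c variance components over loci genotyped in both
populations and polymorphic in the pair. Population-specific Fst is the
Weir & Goudet allele-matching estimator
`β_i = (M_i − M_b)/(1 − M_b)` (within-population matching of distinct
allele copies versus mean between-population matching), accumulated as
ratios of sums over loci. β is the quantity that flags
founder-bottlenecked introductions as diverged from the common ancestral
pool even when no single pairwise comparison stands out. The NJ tree and
classical MDS (principal coordinates) consume the raw Fst matrix — no
Fst/(1−Fst) linearization by default, matching common practice of feeding
the pairwise matrix directly to `nj` and MDS; both are delegated to
scikit-bio, with negative NJ branch lengths clamped to zero and the clamp
count logged.

## Genotype–environment association

Climate variables are centred and scaled over the native range; pairs
with |r| ≥ 0.7 trigger a collinearity warning. Two scans run on native
populations only, to avoid contaminating the native signal with recently
translocated genotypes:

**Latent-factor scan** (individual dosages). Latent factors are the
leading left singular vectors of the genotype matrix after the
environmental design has been projected off, so the factors model
structure orthogonal to the tested predictors and cannot swallow the
association signal; any structure collinear with a predictor inflates
that predictor's z-score background instead and is absorbed by the
genomic-inflation rescaling (z² median / χ²₀.₅). Per-locus least squares
on [1, climate, factors] yields per-variable z-scores, calibrated
p-values and Benjamini–Hochberg q-values; a locus is a candidate when its
smallest q over variables passes the threshold (default 0.1). With zero
factors the scan reduces exactly to per-locus OLS on climate.

**Partial RDA** (population allele frequencies). Response and predictors
are residualized on the conditioning design (coordinates plus the K = 2
ancestry proportion — one column, since the two proportions are
collinear); the constrained axes are the SVD of the fitted values of the
multivariate regression of residualized response on residualized
predictors. Inertia is sums of squares/(n−1); eigenvalues match vegan's
`rda` to numerical precision (tested against it). The model p-value
permutes rows of the residualized predictors (999 by default, seeded).
Outliers are loci whose axis-1 loading deviates more than 2.5 SD from the
loading mean. If every predictor lies in the conditioning design the
model returns zero constrained inertia (a warning, not an error); a
partially collinear design is an error naming the offending columns.

**Variance partitioning** runs the full model plus the three one-block
partial models; confounded = full − Σ unique, unexplained = total − full,
and raw proportions sum to one by construction. Because raw semipartial
R² carries an O(p/n) positive bias, the partition also reports
Ezekiel-adjusted unique fractions (adjR²(all) − adjR²(other two blocks),
the varpart convention); under a structure-only simulation the adjusted
climate fraction is centred on zero while the raw one is not. The
adjustment is undefined (NaN) when residual degrees of freedom vanish.

**Candidates.** The scan and ordination candidate sets are combined by
union (default) or intersection; the enriched RDA refits an unconditioned
ordination on the combined set and exposes its axis-1 environmental
variable scores (correlations of predictors with fitted site scores).
Per-locus strongest-variable assignment is the argmax |correlation|
between locus frequency and each variable, ties broken to the first
variable in canonical order.

## Genotype–environment index and offset

`index(pixel) = Σ_j score_j · (env_j(pixel) − mean_j)/sd_j`, with means
and sds from the native-range standardization (the ordination was fit on
native data, keeping the index comparable between maps). The index is 0
at the native-mean climate and linear in each standardized variable;
nodata propagates. Each introduced population maps to the native
population with minimal pairwise Fst (ties broken lexicographically,
logged); its offset is the absolute index difference between the
introduced pixel and the source pixel, with the signed difference
retained in an extra column. Absolute values make the offset invariant
to the arbitrary sign of an ordination axis. Classification uses
empirical tertiles (Low = lowest third) or user-supplied fixed breaks;
ties at a breakpoint fall into the lower class. A packaged reference
table (`invoffset/data/tench_introduced_offsets.tsv`) carries published
offsets for 40 introduced tench populations for desk checks; 27 of those
40 fall below the 2.83 small-difference threshold.

## The synthetic range

The generator emulates the study conditions: 36 native, 40 introduced and
19 farmed populations by default, ~8 samples per population, thousands of
SNPs, ~6% missing genotypes. Ancestral frequencies are U(0.05, 0.95);
the two refugial clusters drift apart under Balding–Nichols(p₀, F) with
F = 0.15; native populations sit on a longitudinal cline q_W from 1
(west) to 0 (east) with small jitter so the cline is monotone in
longitude but not an exact affine function of it. Climate is five smooth
surfaces on a 50×50 grid with deliberately distinct spatial structures so
the stack passes the |r| < 0.7 screen at the 36-population design scale:
annual mean temperature runs along the longitudinal expansion axis and is
therefore partially confounded with the cline (as in a real postglacial
range), while the focal selective driver — winter minimum temperature,
the canonical thermal-stress variable for freshwater fish — is
latitudinal and identifiable against the cline. Population-site values
add a 5% microclimate deviation so site climate is not an exact function
of coordinates. Adaptive loci (60 of 2000 by default) shift their
population frequency on the logit scale by `effect × sign_l × z` with
z the standardized focal variable and a random per-locus direction;
effect defaults to 1 per SD. Introductions draw `2 × founder_size` gene
copies (default 10 diploids) from one named native source and then
binomial-sample residents; the expected He retention is `1 − 1/(2N)`,
i.e., 95% for ten founders, and the simulated retention over 200 founder
events reproduces it. One global seed feeds a stream-splitting scheme
(frequencies / genotypes / placement / introductions / missingness) so
stages can be re-simulated independently.

What the generator does **not** emulate: linkage disequilibrium,
coalescent noise shared between nearby populations (isolation by distance
beyond the cline), selection through time, genotyping error, and
reference-panel ascertainment. Passing tests therefore demonstrate that
the estimators recover the truth of this generative model at realistic
sample sizes — not that any particular real dataset satisfies the model.

## Problem sizes and numerical choices

Tests run the estimators at reduced but honest scales: the
association-scan operating characteristics use 60 native populations × 15
samples × 1000 loci with 20 planted loci (power and false-discovery
proportion averaged over replicates); source-assignment recovery uses
clone-like introductions (50 founders) against 8 native populations ×
2000 loci, since recovery against a finely sampled cline is
noise-limited — the acceptance script also reports the honest
study-condition accuracy, which is far lower because most misses are
cline neighbours of the true source. EM convergence is declared at a
log-likelihood gain below 1e-4; frequencies are clipped to
[1e-9, 1−1e-9]; PCA mean-imputes missing dosages; RDA mean-imputes
missing frequency cells (logged). The ±2.5 SD outlier rule on Gaussian
loadings flags ≈1.24% of loci, matching the normal-tail expectation.

## Known limitations

- The admixture solver is plain EM: slower to converge than SQP near the
  optimum; `max_iter` bounds the cost and non-convergence is flagged,
  not raised.
- The latent-factor scan is the projection (non-ridge) variant; when
  neutral structure is nearly collinear with a predictor, calibration
  preserves the false-positive rate but power against that predictor
  degrades — an identifiability limit, not an implementation one.
- The offset uses a single argmin source population even for admixed
  introductions, and a single ordination axis; both follow the study
  design the package reimplements.
- Raster support is ESRI ASCII grids (one per variable, shared
  geotransform); GeoTIFF is not read.
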