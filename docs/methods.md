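# Methods

`plaquescape` re-implements, as a tested reusable library, a spatial
transcriptomics analysis of amyloid-plaque- and genotype-driven expression
changes in MERFISH coronal mouse brain sections, together with a synthetic
section generator that supplies ground truth for every procedure.  This
note describes the models, the defaults and why they were chosen, what the
generator does and does not emulate, and the numerical choices that affect
results.

## The analysis problem

Four mouse genotypes are compared: wild-type (WT), Trem2-R47H (an
Alzheimer's risk variant), 5xFAD (an amyloid model), and the
Trem2-R47H;5xFAD cross.  Only the two 5xFAD-carrying genotypes develop
A-beta plaques.  Each animal contributes one 10-um coronal section imaged
with a ~300-gene MERFISH panel in one of several batches of mixed genotype
composition.  The analyses ask three questions: how does expression change
near plaques (within 100 um of a plaque centroid, against a 100-500 um
distal background, and continuously per um of distance); how do the
genotypes differ per cell type; and which transcriptomic subpopulations
(disease-associated microglia and astrocytes, DAM/DAA) are enriched in
which genotypes and regions.

## Cell-level processing

Cells with volume above 1800 um^3 or fewer than 50 transcripts are
discarded; both cutoffs are strict inequalities, so boundary cells are
kept.  Counts are scaled to the median library size and transformed as
log2(1+x).  For embedding, total transcript count is regressed out of each
gene (ordinary least squares; residuals are exactly orthogonal to depth),
residuals are standardized and projected onto principal components
(deterministic full SVD).  Clustering builds a symmetrized k-nearest-
neighbour graph (k = 15) and partitions it with seeded Leiden modularity
optimization.  Batch integration is a pluggable `integrate` hook with an
identity default: the synthetic data's batch effects are mild multiplicative
log-normal shifts, and the mixed model downstream absorbs them; real data
with stronger batch structure can plug in any embedding-level integrator.

Subclusters of a cell type whose top-10 markers include at least two genes
annotated as exclusive to a different major type are excluded as
contaminated (segmentation spillover).  The "2 of top 10" quantification is
a configurable convention; it tolerates a single noisy marker.

## Pseudobulk differential expression

Counts are summed per (cell type, sample) stratum, optionally further split
by plaque zone or region.  Strata with fewer than 50 cells are dropped;
genes detected in fewer than 15% of a type's cells are not tested for that
type.

The response is log2(1 + normalized counts) on a counts-per-million-like
scale.  Depth normalization uses median-of-ratios (DESeq-style) size
factors rather than raw totals: with a 300-gene panel, a handful of
strongly regulated genes (disease-associated microglia markers change
up to ~20-fold) can carry a fifth of the library, and dividing by the raw
total would shift every other gene in the opposite direction, inflating
false fold-change calls.  Size factors are additionally re-estimated in a
second pass that excludes genes significant in the first pass, then the
model is refitted; the same two-pass scheme is used in the single-cell
distance regression.

Each gene is modeled as y ~ group with a random intercept per batch,
fitted by profiled REML.  The solver exploits the closed form of the
single-random-intercept model (Woodbury block inverse; scalar optimization
of the variance ratio), which makes thousands of per-gene fits cheap; it
agrees with a generic mixed-model fitter to numerical precision and is more
reliable at the variance boundary (lambda = 0).  The group coefficient is
the reported log2 fold change.

Two small-sample choices matter at the cohort scale of a few pseudobulk
rows per comparison:

- Wald tests use a t reference with residual degrees of freedom
  (n - rank(X)); a standard-normal reference is anti-conservative at n ~ 6
  and measurably inflates the null call rate.
- Residual variances are moderated across genes with an empirical-Bayes
  scaled-inverse-chi-square prior (limma-style; prior df estimated from the
  moments of log s^2 via digamma identities).  With ~4 residual degrees of
  freedom, occasional variance underestimates otherwise produce spuriously
  tiny standard errors.  The prior degrees of freedom add to the residual
  ones in the t reference.

Significance requires BH-adjusted p < 0.05 and |log2FC| >= 0.35 for the
genotype and proximal-vs-distal contrasts.  The region-vs-rest procedure
uses the unadjusted p-value with the same fold-change cutoff and flags its
rows as nominal; the continuous-distance procedure uses the adjusted
p-value alone.  The BH family is all tested genes within one (cell type,
comparison).  Five genotype contrasts are run: 5xFAD vs WT, R47H;5xFAD vs
R47H, R47H vs WT, R47H;5xFAD vs 5xFAD, and R47H;5xFAD vs WT, each
restricted to samples of the two genotypes involved.

The continuous procedure is a per-gene negative-binomial regression at the
single-cell level on cells within the proximal radius of amyloid samples:
log mean = intercept + beta * distance + log(size factor), dispersion by
method of moments (floored at 1e-8), Wald test on beta, and the reported
effect is the per-um log2 change beta/ln 2.  Genotype is not a model
factor.

## Spatial statistics

Distances are Euclidean to the nearest plaque centroid.  Zones: proximal
d < 100 um (strict), distal 100 <= d <= 500 um (closed at 500).
Proximal/distal areas are exact polygon unions of disks (64 segments per
quarter circle, area error well below the 1% contract) clipped to the
section; densities divide zone cell counts by these areas.  Annulus
composition bins cells at 25-um intervals of plaque distance; the
abundance-normalized variant divides each type's annulus count by its
section-wide total before renormalizing within the annulus (the
section-wide convention is recorded output metadata).

Region and cell-type areas come from alpha shapes: Delaunay triangles with
circumradius below 1/alpha (alpha = 0.015 per um on um coordinates),
unioned; alpha = 0 degenerates to the convex hull.  Before area inference
for a single type, spatial outliers are removed by the distance to the 5th
nearest neighbour, keeping points inside [median - 1.5 IQR,
median + 1.5 IQR]; boundary values count as inside, so perfectly regular
patterns (IQR = 0 by ties) keep their median-valued points.  Sparse cell
types use the alpha shape of all cells within 50 um of any cell of the
type.

## Plaque detection and validation

The detector is a transparent threshold pipeline standing in for a trained
segmentation model while exercising the same validation machinery: global
intensity-quantile threshold (default 0.90), 8-connected components,
removal of components with equivalent diameter below 15 um (nuclei render
at 8.5 um; plaques at ~22.4 um) and of components with Crofton circularity
above 0.90 (round somata).  Validation matches predicted to annotated
objects greedily by pixel overlap (ties by lower label); an annotated
object is a true positive when its match covers at least half its area
(configurable), a predicted object with zero annotated overlap is a false
positive.  F1 = 2tp/(2tp+fp+fn); the false-positive rate is reported under
two conventions, per prediction fp/(fp+tp) and per annotated object
fp/(tp+fn).  Plaque volumes convert 2-D mask areas by the 10-um section
thickness.

## The synthetic generator

One simulated section draws, per rectangular region (defaults stand for
cortex, corpus callosum, hippocampus and thalamus in a 3x3 mm frame):

- plaques from a homogeneous Poisson process whose intensity per (region,
  genotype) follows the per-region plaque densities of 12-month
  amyloid-model brains (highest in the corpus callosum, ~5.6-6.2e-5 /um^2;
  zero for non-amyloid genotypes), with log-normal areas;
- cells from Poisson processes with region- and type-dependent intensity;
  microglial intensity is multiplied by 2.0 within 100 um of a plaque
  centroid (implemented by thinning from the ceiling intensity), emulating
  plaque-attracted microgliosis;
- counts from a negative binomial (gamma-Poisson) whose log2 mean is a
  deterministic per-(type, gene) baseline plus per-(batch, gene) log-normal
  batch effects, planted genotype effects, planted distance effects
  (exponential decay amplitude*exp(-d/decay) or log-linear slope*d),
  planted region effects, latent-subpopulation shifts, and a log-normal
  per-cell library factor (sigma 0.35);
- volumes such that a configurable fraction (default 2%) exceeds the QC
  cutoff.

The panel names ~30 genes after real markers (DAM: Itgax, Cst7, Csf1,
Ccl6, Cd74, Apoe; homeostatic microglia: P2ry12, Tmem119; DAA: Gfap, C4b,
Clu; plus type markers) so that planted disease programs read naturally;
the remainder are filler genes with log-normal baselines drawn once from a
fixed internal stream.  Default planted effects mirror the disease biology:
DAM genes up ~1.5-3.3 log2 in amyloid microglia, homeostatic genes down,
DAA genes up in amyloid astrocytes, Bdnf/Ntrk2 up under R47H, Fos down in
mutant excitatory neurons, DAM-like distance decays with 50-um decay
length, and two genotype-biased latent subpopulations.  Latent
subpopulations support bidirectional signatures (genes up and genes down):
real activation states are bidirectional, and a purely one-sided shift is
partly absorbed by library normalization and depth regression, which makes
it a poor planted truth for subclustering recovery.

Rendered validation images place nuclei as 8.5-um disks at moderate
brightness and plaques as brighter (>= 2x) four-lobed footprints whose
union area is calibrated to the requested equivalent diameter, with
fibril-like internal texture and Gaussian background noise, at 0.108 um/px
by default.  The paired label mask of plaque footprints is the detector's
ground truth.

All randomness flows from one root seed; per-section streams derive from
(seed, section index) and per-batch gene effects from (seed, crc32(batch)),
so cohorts are bit-reproducible and sections of one batch share their batch
effect.

What the generator does not emulate: optical artifacts, z-structure,
transcript-level spot noise, segmentation errors and spillover between
adjacent cells (the contamination filter is therefore tested on constructed
marker tables, not emergent spillover), anterior-posterior gradients, and
curved anatomical region shapes.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
structure, not robustness to every artifact of real MERFISH data.

## Validation benchmarks and problem sizes

`plaquescape.validation` (driven by `scripts/acceptance.py` and the
end-to-end test suite) regenerates every headline number from scratch at
sizes chosen to run in seconds to a couple of minutes per suite: cohorts of
4 genotypes x 3 batches at ~225 cells per type per section for the
differential-expression calibration (5 cohorts) and recovery (4 cohorts,
pooled counts — a single ~20-discovery cohort gives a Poisson-noise-
dominated FDR estimate); two amyloid sections (~1600 proximal microglia)
for the distance regression; 20 rendered 2000x2000-px fields of view for
the detector; one dense microglia section (~2600 analyzed cells) for the
attraction ratio; the full 176,851-composition simplex grid for the bias
classifier; and two byte-compared end-to-end runs for determinism.

## Genotype-bias classification

Subcluster genotype composition is normalized in two steps: each
subcluster's count from genotype g is divided by the genotype's total cell
count in the analyzed type (cohort imbalance cancels; duplicating every
cell of a genotype leaves the matrix unchanged), then rows are normalized
to sum to 1.  A subcluster is called biased toward a single genotype when
its share exceeds 1/3 (uniform is 1/4) — single calls take precedence and
ties break by the fixed order WT, R47H, FAD, R47H;FAD — and otherwise
toward an allowed pair when the combined share exceeds 0.60 (uniform 1/2).
Allowed pairs are {WT, R47H}, {FAD, R47H;FAD}, {R47H, R47H;FAD} and
{WT, FAD}; the two diagonal pairs ({WT, R47H;FAD} and {R47H, FAD}) are
never called because they do not correspond to a single driving mutation.
At most one call is emitted per subcluster.  Regional class proportions
(e.g. DAM fraction per region) are compared between genotype groups with a
seeded permutation test on sample-level proportions, since cell-level
proportions are not independent observations.

## Known limitations

- The threshold plaque detector is a stand-in: it exercises the validation
  machinery but does not reach trained-model accuracy on real images.
- The contamination rule and the "significant overlap" fraction are
  quantified conventions where the underlying description is qualitative;
  both are configurable.
- The continuous-distance model treats cells as independent; spatial
  autocorrelation within sections is not modeled.
- Whether the 15% detection filter should be computed before or after
  genotype subsetting is a convention; it is computed per cell type over
  all cells present at pseudobulk construction.
- Region polygons in the generator are rectangles; area estimators are
  validated on known geometries separately.
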