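# Methods

This note documents the models, the numerical choices, and the synthetic
data that the test suite and `scripts/acceptance.py` rely on. Problem sizes
quoted here are the package's defaults for desk-scale analysis.

## Data model and preprocessing

An `OtuTable` holds non-negative integer counts (samples × OTUs) with a
stage label per sample from the ordered vocabulary
C9 < P9 < P12 < P16 < P21 < P28 < P35. Rarefaction subsamples each sample
without replacement to a common depth (multivariate hypergeometric — the
exact distribution of read subsampling), by default the minimum per-sample
total; the common depth is a configurable assumption since equalized
coverage can be achieved at any depth up to the minimum. OTU filtering keeps
the top `ceil(fraction · n_otus)` OTUs by summed raw counts (ties broken
lexicographically by OTU id for determinism); 5% is the analysis default for
study-scale tables, while the synthetic study (50 OTUs) uses 0.5 so that
enough OTUs survive for the downstream network and trajectory stages.
Taxonomic aggregation sums counts within a rank value and pools unannotated
OTUs into an explicit `unannotated` row, preserving the grand total.

## Alpha diversity and stage tests

Shannon uses natural-log units (a log2 option exists); Chao1 uses the
bias-corrected form, defined also when no doubletons exist. The
Jonckheere–Terpstra statistic counts concordant cross-group pairs with ties
at ½; z uses the tie-corrected null variance and a 0.5 continuity
correction, with two-sided p (one- vs two-sidedness is not always reported
in the field; output records the convention). The continuity correction
keeps the normal tail within ~0.02 of the exact permutation tail at the
per-stage sizes (2–4 samples) this design produces.

Kruskal–Wallis reports the tie-corrected H. Its p-value is exact
(full enumeration) when the design has at most 100,000 group splits, a
seeded Monte-Carlo permutation tail (999 draws, mid-p for the lattice atom
at the observed H) for designs up to n = 100, and chi-square (k−1 df)
beyond. The chi-square tail is visibly conservative at small n (measured
type-I ≈ 0.045 at three groups of ten), which motivated the permutation
branches; the Monte-Carlo stream is derived deterministically from the data
so the function remains pure.

The Wilcoxon rank-sum test is exact when `n1·n2 ≤ 400` without ties,
otherwise a tie- and continuity-corrected normal approximation.

PERMANOVA partitions the squared Bray–Curtis distances into within- and
between-group sums (pseudo-F with k−1 and N−k df) and permutes labels
freely, 9999 permutations by default, with the add-one rule
`p = (#{F_perm ≥ F_obs} + 1)/(B + 1)`. Permutations that reproduce the
observed partition are redrawn: they are the observed arrangement itself
and would tie F by construction, which distorts the minimal attainable p.

## Dirichlet multinomial mixture community typing

Counts from a sample with depth n are modelled as Dirichlet-multinomial
within each mixture component; the marginal includes the multinomial
coefficient, so `dm_log_likelihood` is a proper log pmf. Fitting is MAP EM:
responsibilities in the E-step, mixture weights plus per-component L-BFGS
maximization of the weighted DM log posterior over log α in the M-step. A
weak Gamma(0.1, 0.1) prior (mean 1, high variance) on every α serves two
purposes: it keeps boundary parameters finite (all-zero OTU columns would
otherwise drive α to 0, and single-sample components would drive the
precision to infinity), and its *normalized* density is what the evidence
integrates over — the per-parameter normalization constant is the Occam
penalty that stops K from growing without bound. The EM trace records the
penalized objective (log likelihood + log prior), which is the quantity
guaranteed non-decreasing.

Model choice minimizes a Laplace approximation to the negative log
evidence: `−log Z ≈ −(log L + log prior) − (d/2)·log 2π + ½·log det H` with
`d = K·J + (K−1)` free parameters. H is the Hessian of the negative log
posterior in log-α space, computed per component as diagonal plus rank-one
(the Σα terms couple coordinates; the matrix determinant lemma gives the
log-determinant), with a mixture-weight block in logit space and a floor of
1e-8 on curvature entries for degenerate corners. Five seeded restarts per
K guard against EM local optima; the best-evidence fit is kept. On the
default two-type study the evidence curve dips at K = 2 and on one-type
data at K = 1.

The "contribution" of an OTU to the two-type contrast is the absolute
difference of fitted component mean proportions, normalized to sum one.
This is an explicit stand-in for a ranking the original analysis used but
never defined; it matches how the DMM literature displays discriminating
taxa, and the ranking object carries the cumulative curve so any threshold
(default: the smallest prefix exceeding 0.5) can be read off. Alternative
rankings (e.g. per-OTU evidence decomposition) can be swapped in at the
call site since the ranking consumes only the fitted model.

## Trajectories

Trajectory clustering operates on per-stage mean relative abundances,
row-standardized to mean 0, SD 1; zero-variance rows carry no shape and are
dropped with a record. Fuzzy c-means uses Euclidean distances, fuzzifier
m = 1.25 (typical for short standardized time courses; memberships approach
uniform as m grows), c = 9 clusters by default, farthest-point seeding so
well-separated profile groups each attract a center, and stops when the
maximum membership change falls below 1e-6. Profiles that coincide with a
center (or close enough that the inverse-distance power overflows) receive
hard membership for the nearest center; clusters that lose all mass retain
their previous center rather than dividing by zero. Whether to cluster
OTU-level or genus-level profiles is left to the caller — both are
reachable through `aggregate_rank`.

## SparCC cooccurrence

Compositional counts make naive correlations spurious; SparCC instead
estimates basis (absolute-abundance) correlations from log-ratio variances
`t_ij`, solving `(p−2)·ω + 1·Σω = t_rowsums` for the basis variances under
the sparsity assumption that most pairs are uncorrelated. Pairs whose |ρ|
exceeds 0.1 are iteratively excluded from the system (up to 10 pairs), the
fractions are resampled from a per-sample Dirichlet posterior (pseudocount
1) over 20 inner iterations, and the elementwise median ρ is reported,
clamped to [−1, 1] with unit diagonal. These internals follow the original
algorithm's defaults and are all configurable. A singular exclusion system
(possible on very small OTU sets) falls back to least squares.

Significance comes from an empirical null: each bootstrap permutes every
OTU's counts independently across samples, destroying pairwise association
while preserving marginals; two-sided `p = (#{|ρ_null| ≥ |ρ_obs|} + 1)/(B + 1)`
with B = 100 by default. Network edges require |ρ| > 0.3 and p < 0.05; the
absolute value matters because exclusion (negative) relationships are real
and drawn dashed in the field's figures.

## Host integration

The pipeline consumes a per-gene statistics table (log2 fold change, BH
FDR) from an upstream DE tool — DE testing itself is out of scope. DEGs
pass FDR < 0.05 and |log2FC| > 1; the rank value `−log10(FDR)·log2FC` uses
base 10 with the FDR floored at 1e-300. Expression is log2(x+1) transformed
before correlation. The coexpression network keeps gene pairs with
|r| > 0.9 and p < 0.05 (the unsigned rule: up- and downregulated programs
co-occur; a signed mode exists) and drops isolated genes. Louvain
modularity optimization (|r| edge weights, seeded, resolution 1.0)
partitions the network; module eigengenes are the first principal component
of the standardized module expression, unit variance, sign-fixed to
correlate positively with the module mean profile. Microbe–module
association is Pearson r of OTU relative abundance vs eigengene with BH
applied jointly across all (OTU × module) pairs; significance means
FDR < 0.05. The RV coefficient on column-centered matrices, with a
permutation p over sample rows of Y, quantifies concordance between two
multivariate views of the same samples.

A power caveat the synthetic study makes visible: with the design's six
shared microbiome–transcriptome samples (three per stage), a single true
coupling cannot clear the joint BH correction — the smallest attainable
two-sided p at n = 6 (~4e-3 even at r = 0.95) exceeds 0.05/112. Recovery
tests for the association stage therefore use six samples per stage; at the
three-per-stage design the association table is still computed and the
coupling appears as the strongest (non-significant) pair.

## Synthetic data

The generator is the study-design mirror: 7 stages × 4 samples (2 at P35),
50 OTUs, sequencing depths log-normal around 20,000 reads (σ_log = 0.3,
floored at 100). Community type 1 spans C9–P12 and type 2 spans P16–P35.
Both types share a power-law background (total α 15); five discriminating
OTUs have α = 8 in type 1 and 0.3 in type 2, with type 2's background
rescaled so both types have equal precision (~55) — strong overdispersion,
so within-type samples vary realistically. Eighteen background OTUs (two
per shape) carry one of nine canonical stage shapes (monotone up/down,
early/mid/late peaks and troughs, step-up), applied as a multiplicative
`exp(0.3 · shape_z)` modulation of their Dirichlet parameter. The amplitude
0.3 (roughly ±50% abundance swings) keeps the two community types the
dominant structure — at much larger amplitudes the per-stage modulation
itself becomes the clustering signal and the planted "two types" truth
record would be wrong.

`simulate_correlated_counts` draws basis abundances as exp of a correlated
Gaussian (planted pairwise correlations, identity elsewhere; the requested
matrix must be positive definite), normalizes to fractions, and draws
multinomial counts; the truth records the basis correlation matrix and the
latent log abundances.

Expression covers two stages (P9 and P28, three samples each by default,
mirroring the six epithelial samples of the source design). Each of four
25-gene modules has a latent factor per sample; non-coupled modules get an
alternating-sign stage offset of 1.5 added to a standard normal factor,
while the coupled module's factor is the standardized relative abundance of
its OTU plus N(0, 0.33) noise — giving a coupling correlation near 0.95.
Gene values are `baseline · 2^(0.95·factor + ε)`, ε ~ N(0, 0.3); the stage
effect acts through the factor, so within-module correlation stays above
the 0.9 edge threshold while between-module correlation (≈0.4 via the
shared stage) stays safely below it. The surrogate DEG table is derived
from the planted truth (DE genes: |log2FC| ≥ 1.2, FDR ≤ 1e-2; nulls fail a
filter by construction) because DE testing is consumed, not implemented.
Optional `n_de_up`/`n_de_down` plant exact stand-alone DE gene counts among
the background.

What the generator does not emulate: sequencing error, chimeras, taxonomic
mis-annotation, library-size confounding with stage, or phylogenetic
correlation among OTUs. Passing recovery tests therefore demonstrate the
estimators' correctness under the assumed generative structure, not
robustness to those artifacts.

## Problem sizes and determinism

The default study (26 samples × 50 OTUs, depth ~2e4; 200 genes × 6
samples) runs the full pipeline in seconds; recovery suites use 10–20
seeded replicates, SparCC power checks n = 200 samples × 20 OTUs with 100
bootstraps, and null calibrations 1000–2000 simulations. All randomness
flows from explicit seeds: the pipeline expands one master seed per stage
via CRC32-mixed substreams, and rerunning any entry point with the same
seed reproduces every artifact byte for byte.

## Known limitations

- The Laplace evidence uses a blockwise (diagonal + rank-one) Hessian;
  cross-component curvature is ignored. Adequate for K selection at desk
  scale, but the absolute evidence values are approximate.
- The DMM contribution metric is a defined stand-in (see above).
- SparCC p-values are bootstrap-granular (min 1/(B+1)); with B = 100 the
  0.05 threshold has coarse resolution.
- PERMANOVA assumes exchangeable samples (no strata), matching the default
  behavior of the field's Adonis implementations.
- The fuzzy c-means cluster count c = 9 follows the trajectory count
  reported for this system; nothing in the package estimates c.
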