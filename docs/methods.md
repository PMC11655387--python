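# Methods

`archoffset` implements a landscape-genomics conservation-planning
pipeline for a fragmented island tree system: from filtered SNP
genotypes and climate layers to gradient-forest turnover models, genomic
offsets, a climate suitability index, and ranked seed-source /
planting-site pairings under three management scenarios. This note
documents the models, the defaults and why, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Data model

Genotypes are held as an individuals × SNPs dosage matrix (0/1/2 copies
of the alternate allele, −1 = missing) with per-SNP metadata (chromosome,
1-based position, alleles, mean depth) and per-sample metadata (island,
coordinates, field species id). Climate is a table of six predictors —
BIO5 (max temperature of the warmest month, °C), BIO6 (min temperature of
the coldest month, °C), BIO15 (precipitation seasonality, CV%), BIO18 and
BIO19 (precipitation of the warmest/coldest quarter, mm) and elevation
(m) — for samples and for grid cells, in a historic and a future slice.

## Filtering (genio)

The filter ladder runs in a fixed order: keep biallelic SNPs; drop sites
with mean depth < 5; mask genotypes with depth < 5; drop sites with minor
allele frequency < 0.01 (computed on non-missing dosages after masking)
and with > 10% missingness. A `FilterReport` enforces the ledger identity
input = output + Σ removed. LD pruning slides a 50-variant window by 10,
removing one SNP of any retained pair with squared pairwise-complete
Pearson correlation > 0.1 until no pair offends. PLINK dialects differ in
which SNP of a pair is dropped; ours drops the lower-MAF SNP (tie: the
later position), is oracle-tested against a brute-force restatement, and
a `keep-first` dialect is available. Pruning is idempotent whenever the
window covers pair comparisons consistently (always true when the window
spans the panel); after pruning, renumbering can bring previously
never-compared SNPs into a common window, as in any windowed pruner.
Mode imputation fills missing genotypes with the SNP's modal dosage,
breaking ties toward the lower dosage (deterministic, slightly
reference-biased — documented rather than randomized). Predictor
screening greedily removes, from the worst-correlated pair, the predictor
with the larger mean |r| to all others, until all pairwise |r| ≤ 0.7.

## Structure summaries (popstruct)

Pairwise F_ST uses the Weir–Cockerham (1984) variance components a, b, c
with observed (not HWE-assumed) heterozygote frequencies; the multi-locus
estimate is the ratio of averages Σa/Σ(a+b+c). The dispersion band is the
sample SD of per-locus θ around the multi-locus value, which reproduces
the negative lower bands typical of low-differentiation systems (negative
values carry no meaning beyond zero). Loci monomorphic across the
compared groups, or with fewer than two genotyped individuals in a group,
are excluded and counted. Genotype PCA is an ordinary centered PCA of the
imputed dosage matrix. IBS distance is the proportion of allele
mismatches over shared non-missing sites, d = Σ|g_i − g_j| / (2·shared).
Isolation by distance is fit as a four-parameter sigmoid
g = L/(1+exp(−k(x−x0))) + c by least squares; because pairwise distances
are not independent, the p value is a Mantel-style permutation of
individuals, not an analytic one. (A GLM with logit link is a defensible
alternative reading of "logistic model"; the sigmoid is implemented, the
alternative is noted here.) Ancestry groups are designated from a Q
matrix by the inclusive rule: argmax ancestry ≥ 0.9 → that group, else
hybrid.

## Constrained ordination (rda)

RDA is multivariate least squares of the column-centered dosage matrix on
standardized predictors followed by an SVD of the fitted values;
eigenvalues are singular values squared over n−1, R² is fitted over total
sum of squares, and adjusted R² is Ezekiel's 1−(1−R²)(n−1)/(n−p−c−1).
Partial models residualize both sides on the conditioning set first.
Permutation p values use the pseudo-F statistic with
p = (1+#{F≥F_obs})/(1+n_perm) (99 permutations → smallest p 0.01);
partial models permute the reduced-model residuals (Freedman–Lane).
Variance partitioning computes full = adjR²(climate+geography),
climate-alone = full − adjR²(geography), geography-alone symmetric, and
the joint (confounded) fraction as the remainder — additive by
construction and verified to 1e-10. The combined model skips the
collinearity guard because full confounding is a legitimate input there.

Candidate ("climate-associated") SNPs are loadings more than 4 SD from
the mean of their own axis's loading distribution on any of the first
three constrained axes; each candidate is then assigned the predictor
with the largest |Pearson r| against its dosage, with ties going to the
declared predictor order and |r| < 0.1 flagged low-confidence. No
population-structure conditioning is applied by default — appropriate
when differentiation is weak, where conditioning costs power and inflates
false positives — but a conditioning hook exists.

## Spatial eigenvectors (spatial)

PCNM axes: pairwise distances (Euclidean km for synthetic planes,
haversine for lon/lat), distances beyond the truncation t replaced by 4t
(the standard Borcard–Legendre replacement; any value ≥ 4t gives the same
positive axes), then a Gower double-centered principal-coordinates
decomposition. Axes with eigenvalue > 1e-10 × max are kept; "the first
half of the positive axes" uses floor by default with a ceil flag, since
the halving convention is ambiguous in common usage. Scores are
eigenvectors scaled by √eigenvalue; the orthonormal vectors are also
exposed.

## Gradient-forest turnover (gfturnover)

Each SNP gets its own regression forest (default 500 trees, bootstrap
resampling, depth capped at max(1, round(log₂(0.368·n/2))) — 0.368 is the
expected out-of-bag fraction, so the cap keeps terminal nodes populated;
n = 127 gives depth 5). Only SNPs with positive out-of-bag R² contribute.
Every split's impurity reduction is accrued to an equal-frequency bin of
the split predictor's observed range (default 50 bins; 30 in the desk
fixtures); a SNP's binned mass is rescaled to sum to its out-of-bag R²,
so a predictor receives R² × (its share of that SNP's split importance).
Pooling over SNPs and cumulating per predictor yields the non-decreasing
turnover function f_v with f_v(min) = 0 and f_v(max) = the predictor's
overall R²-weighted importance; Σ_v f_v(max) equals the summed R² of
contributing SNPs (mass conservation, asserted to 1e-8).

Deviations from the R reference method, by design: importance is raw
impurity importance binned over equal-frequency bins (which equalizes
data density per bin) rather than density-standardized splits, and
conditional permutation importance for correlated predictors is not
implemented — instead a warning is logged whenever two predictors
correlate above the stored threshold (0.5), flagging where importances
may share credit. The monotonicity/normalization properties above are
the contract; numerical parity with the R package is not.

A single integer seed fans out deterministically to per-SNP forest seeds
via a `SeedSequence`, so identical inputs and seed give bit-identical
models. Transforming a climate table evaluates each f_v, clamping values
outside the training range (step functions are flat beyond their
endpoints). Models serialize to a single JSON file.

## Offsets, scenarios, suitability (offset)

The genomic offset between a seed source (historic climate) and a
planting site (future climate) is the Euclidean norm of the difference of
their transformed climate vectors. Spatial (PCNM) predictors are excluded
from the transform by default: unsampled grid cells have no training-time
PCNM coordinates, and mapping practice for turnover models predicts from
climate alone. An `--include-spatial` path exists for sampled-site-only
comparisons.

Scenarios: *status quo* pairs each population's historic and future
climate at its own cell; *ecosystem preservation* gives each existing
site the source with minimum offset against that site's future climate;
*species preservation* gives each population the site with minimum future
offset, over either the sampled cells or all grid cells. Because the
local pairing is a member of both minimized sets, ecosystem ≤ status quo
per site, species ≤ status quo per population, and widening the site pool
can only lower the species minimum — asserted on every report.

Suitability is S = 1 − O/max(O), with max(O) taken over the full
source × site table of the current model run, so values are comparable
across scenarios within a run. S = 1 iff the offset is zero (the site's
future climate is, in genomic-scaled space, identical to the source's
climate of origin) and S = 0 at the maximal pair. A literal quotient
O/max(O) would invert these endpoints; the endpoint definition is
normative. Offsets from models fit on different SNP sets (e.g. disjoint
lineages analyzed separately) are never mixed: offset tables carry a
model id and comparisons across ids raise.

Pair ranking sorts, per planting site, sources by descending suitability,
and orders rows by mean suitability so the best sites lead — the layout
used for seed-sourcing heat maps.

## Maps (maps)

A transformed grid is reduced to its first three principal components and
min-max rescaled per channel to 0–255 over land cells, so similar colours
mean similar predicted genomic composition; degenerate dimensions pad
with zero channels. Two maps are compared by similarity-transform
Procrustes superposition (translation + rotation + uniform scaling, via
the SVD of the cross-product of centered 3-D PC configurations); the
per-cell residual distance localizes disagreement. Comparing a
configuration with itself returns exact zeros.

## Synthetic archipelagos (simdata)

The generator emulates the study conditions: six islands as clusters of
climate-grid cells on a km plane (a northern and a southern row, so
east-west and north-south directions are not confounded), ~20 individuals
per island (120 total, matching the order of the study's 127), six
climate predictors with linear spatial gradients plus noise — cooler and
wetter in the north, precipitation seasonality varying east-west — and a
deterministic future displacement (defaults: +2.5 °C BIO5, +2.0 °C BIO6,
+5 CV% BIO15, −4 mm BIO18, −40 mm BIO19), in the range of mid-century
Mediterranean-climate projections. Gradient noise levels are set so
pairwise predictor correlations sit at or below ~0.7, emulating a
predictor set already reduced by collinearity screening. A per-island
displacement scale allows pinning an island's future climate to its
historic one, which plants an exact zero-offset pairing for endpoint
tests.

Neutral loci follow the Balding–Nichols model: ancestral frequency
p0 ~ Uniform(0.05, 0.95), island frequency ~ Beta(p0(1−F)/F,
(1−p0)(1−F)/F) at differentiation F (default 0.05, the realized
multi-locus θ recovered within ±0.015 at 2,000 loci). Adaptive loci take
per-cell frequency logistic(logit(p0) + b·z) with z the standardized
driving predictor — one driver per locus, cycled over the six or pinned
to one. Introgression is a two-pool mixture: a second ancestral frequency
pool mixed per individual at island-specific expected rates, a
qualitative stand-in for an introgression gradient with no coalescent
machinery. Missingness is per-genotype Bernoulli, or depth-driven
(DP ~ Poisson(λ), masked below 5) to exercise the depth filter.

What the generator does *not* emulate: linkage disequilibrium beyond
planted duplicate columns, selection acting on genotypes (clines are
imposed on frequencies directly), clonality, coalescent demography, and
realistic island coastline geometry. Passing tests therefore demonstrate
that the estimators and decision rules behave correctly under their
stated models, not that the pipeline's ecological assumptions (local
adaptation to 30-year climate normals, independence of loci) hold in any
real system.

## Problem sizes and determinism

Desk-scale defaults keep the full test suite in single-digit minutes on
one core: the scenario fixture uses 6 islands × 10 cells, 120
individuals, 2,000 simulated SNPs with the forest stage run on 200
retained SNPs at 500 trees; signal-recovery replicates use 60 individuals
and 100 trees, where the causal-predictor ranking is already stable
because it aggregates importance over 100 causal loci. Candidate-recovery
runs use 5,100 loci. All randomness flows from explicit integer seeds;
every simulation, forest and permutation test is reproducible
bit-for-bit.

## Known limitations

- Exact parity with PLINK `--indep-pairwise` or the R gradientForest /
  vegan implementations is not promised; the oracle-tested contracts
  above are.
- The IBD sigmoid can fail to converge on degenerate inputs; it then
  falls back to a monotone spline and flags the fit.
- Mode imputation biases toward the major allele; for ordination on data
  with heavy missingness, consider external imputation first.
- Offsets are proxies for maladaptation only under the local-adaptation
  assumption; the package computes them, it cannot validate that
  assumption.
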