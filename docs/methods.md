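# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `popembed`, and what the synthetic test bed does and does
not establish about behaviour on real cohorts.

## Genotype model and QC

Genotypes are diploid biallelic alternate-allele counts in {0, 1, 2} with a
missing sentinel.  QC applies, in one fixed pass, variant filters — minor
allele frequency strictly greater than `maf_min` (default 0.05), exact
Hardy–Weinberg p strictly greater than `hwe_p_min` (default 10⁻⁶),
missing rate strictly below `max_variant_missing` (default 0.1) — and then a
sample filter (missing rate strictly below `max_sample_missing`, default
0.1, computed over the retained variants).  Variants-then-samples in a
single pass is a deliberate choice: it is deterministic and matches common
genotyping-array practice; iterating to a joint fixed point changes little
on clean data and complicates provenance.  Multiallelic and non-SNP records
are skipped, not split, because everything downstream consumes biallelic
counts.

The Hardy–Weinberg test is the exact conditional (hypergeometric) two-sided
test: conditional on the allele totals, the heterozygote count h has
probability proportional to the multinomial weight N!/(n_mm! h! n_MM!)·2^h,
and the p-value sums the probabilities of all h no more probable than the
observed one.  The weights are computed as exact integers (via a ratio
recurrence, w(h+2)/w(h) = 4·n_mm·n_MM/((h+1)(h+2)), whose division is
exact), so the "no more probable" comparison involves no floating-point
ties and the test agrees with rational-arithmetic enumeration to better
than 10⁻¹² on every table tested.  A chi-square alternative is deliberately
not the default: it misbehaves at the small genotype counts QC exists to
police.

## PCA and projection

Standardization is the usual genotype scaling x = (g − 2p̂)/√(2p̂(1−p̂)),
with missing calls mean-imputed to 0 after centering; unscaled centering is
available as an option (the choice shifts variance-accounting figures on
real data — an acknowledged source of irreproducibility when comparing
published percentages).  The fit is an economy SVD; per-component variance
fractions are s_i²/Σs² over *all* singular values, so fractions over
disjoint PC ranges add and reach 1 at full rank, and
`variance_explained_range` is a simple inclusive sum.  Determinism is
imposed by a sign convention (each loading column's largest-magnitude entry
is positive).  Requesting more components than the numerical rank truncates
with a warning.

Projection of a new cohort matches variants by `chrom:pos:ref:alt`, drops
mismatches with a warning (refusing below 50% overlap), and standardizes
the new samples with the *model's* frequencies — never frequencies
recomputed from the projected cohort — so the projected scores live on the
reference axes.  No shrinkage correction for projection bias is applied;
for the moderate dimensionalities used here the bias is visible only as a
slight contraction and is documented as a caveat rather than corrected.

## Embeddings

UMAP is delegated to `umap-learn`; this package owns parameterization,
seeding, sweeping, projection of new samples, and metric attachment.
Defaults are 15 neighbours, `min_dist` 0.5, 10 PCs — the configuration that
in biobank-scale practice makes both discrete clusters and admixture
"trails" legible.  Sensible ranges (5–50 neighbours, 0.001–0.5 minimum
distance) are logged, not enforced.  With a fixed `random_state` umap-learn
runs single-threaded and bit-reproducibly; that determinism contract is the
basis of manifest-driven reruns.  Axes of the embedding are arbitrary and
long-range distances between clusters are not meaningful; deliberately, no
API summarizes inter-cluster distances, and embedding coordinates are only
ever used to *select* samples for statistics, never as regression
covariates.

The family/neighbour-count report declares a family "separate" when the
embedded mutual-k-NN graph (k equal to the neighbour setting) contains a
component of at least two points consisting solely of that family's
members.  The ≥2-and-solely rule tolerates a married-in founder being
absorbed into the population — the typical picture for a three-generation
pedigree — while still demanding a family-only cluster.

### t-SNE comparison harness

`fit_tsne` exists to compare initialization strategies on an equal footing,
which requires the KL objective at every iteration — something the standard
scikit-learn estimator does not expose.  The joint probabilities and the
KL objective/gradient are therefore taken from scikit-learn's t-SNE
internals, and only the plain gradient-descent loop (momentum 0.5→0.8,
adaptive gains, learning rate max(n/48, 50)) lives here, recording the
objective per iteration.  Default initialization is the small random
Gaussian start with early exaggeration (factor 12 for 250 iterations);
embedding initialization rescales the supplied coordinates to the small
spread t-SNE expects and disables early exaggeration.  The recorded trace
is always the KL against the *unexaggerated* joint probabilities so the two
modes are directly comparable, and `align_error_traces` offsets one trace
by the epochs already spent building the initial embedding.

## Metrics

All neighbour computations exclude self and break distance ties by
ascending sample index (determinism).  k-NN label accuracy operationalizes
"distinct clusters"; neighbourhood preservation |kNN_high ∩ kNN_low|/k
measures local-structure retention (random arrangements score ≈ k/(n−1));
mutual-k-NN components operationalize "disjoint clusters"; gradient
alignment is |Spearman ρ| between a quantity and position along the point
cloud's first principal axis, invariant to monotone transforms and rigid
motions.  Each metric is validated against a brute-force oracle on small
fixtures.

## Privacy randomization

Displayed attributes are binned, then each point independently copies the
original (binned) value of a uniformly chosen one of its k nearest
neighbours in the figure's coordinate space — k = 9 for attributes, k = 50
for colours (copied as whole RGB triples, never mixed channels).  The donor
set excludes self, but donors keep their own values, so a value can appear
twice.  Spatial coordinates instead get Normal(0, 50 km) jitter then
binning to the nearest 50 km (5 km noise / 1 km bins for
distance-from-a-landmark).  Bin counts are attribute-specific; the default
is 20 equal-width bins.  Width-based bins are anchored at multiples of the
width and map values to bin midpoints; count-based bins span the observed
range, with data already at or below the requested number of distinct
values returned unchanged — this makes binning idempotent.  Each
figure/attribute should be randomized with a fresh seed so draws are
independent across visualizations.  These are plotting safeguards that
provably preserve the k-neighbourhood provenance of every displayed value;
they are not formal differential-privacy guarantees, and no
re-identification risk is quantified.

## Phenotype contrasts

The phenotype is residualized once by OLS on the pooled table (intercept
plus age, age², height, sex by default); pooled rather than within-group
residualization matches adjusting for covariates *before* group contrasts,
and a per-group option exists.  Each group is then compared to a reference
with Welch's unequal-variance t (Welch–Satterthwaite df); the pooled-variance
t is available as an option but unequal variances are the norm across
population groups.  Bonferroni multiplies by the declared number of tested
groups (configurable; the number of non-reference groups by default).
Sex-stratified analyses split the table and drop sex from the covariates.
Sample selection by embedding region (centroid+radius or polygon, boundary
inclusive) is logged, because cluster membership in an embedding is a
manual, figure-driven choice.

## Synthetic data: what it emulates and what it does not

The generator provides the structural features the pipeline claims to
reveal, each with an analytic handle for testing:

- **Demes** — Balding–Nichols: ancestral p ~ Uniform(0.05, 0.95) (the lower
  bound keeps near-monomorphic variants, which QC would discard anyway,
  rare); deme frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F); genotype ~
  Binomial(2, deme frequency).  F targets Hudson's F_ST between deme pairs:
  E[(p₁−p₂)²] = 2F·p(1−p) against an expected denominator 2p(1−p), so the
  ratio-of-averages estimator recovers F (realized values land within ±0.01
  at L = 5,000, n = 100/deme — the Monte-Carlo tolerance used in tests).
  F = 0 short-circuits to the ancestral frequency; F = 1 is rejected.
- **Admixture trails** — genotype ~ Binomial(2, θ·p_a + (1−θ)·p_b) over a θ
  grid, giving mean allele count 2(θ·p_a + (1−θ)·p_b) exactly.
- **Families** — founders drawn from the deme frequencies; each parent
  transmits one allele uniformly (so opposite-homozygote parent–offspring
  pairs are impossible and the standardized parent–child correlation is
  0.5).  Pedigrees are nuclear by default; a three-generation pedigree
  (grandparents, uncle, mother, married-in father, child) is provided for
  neighbour-sensitivity studies, where a maximally related nuclear family
  is unrealistically tight and separates at any neighbour count.
- **Spatial structure** — per-variant frequency surfaces are logistic
  transforms of a smooth Gaussian random field (squared-exponential
  covariance, correlation length in grid cells, amplitude 0.8 on the logit
  scale) over a km-scaled grid.  This is a desk-scale stand-in with a
  controllable correlation length, not a coalescent model.
- **Phenotypes** — group mean + covariate effects + Gaussian noise, with
  age ~ Uniform(40, 70), sex ~ Bernoulli(0.5), height ~ Normal(175, 7) /
  Normal(162, 6) cm by sex; all overridable.

Each `simulate_*` call takes one seed; all randomness derives from that
generator, so outputs are bit-identical across runs.

What passing tests on this bed does **not** show: behaviour under linkage
disequilibrium (variants are independent given frequencies), realistic site
frequency spectra, sequencing artefacts, relatedness beyond the declared
pedigrees, or the sample-size imbalances that make UMAP spend visual space
unevenly on real cohorts.  Cluster-recovery accuracies near 1.0 here mean
the machinery is correct, not that real populations separate this cleanly.

## Problem sizes and study conditions

The test suite and `scripts/acceptance.py` run the pipeline at desk scale,
chosen to keep each stage's statistical expectation comfortably resolved:
deme checks at L = 5,000 and 100–200 samples/deme; the family study at one
200-sample deme, 15 PCs (the setting under which family clusters appear at
5 neighbours and are absorbed at 15), and five replicate simulations with
the majority behaviour asserted, since the embedding layout is stochastic
across simulations; privacy invariants at n = 10,000 points; test
calibration over 10,000 null replicates; the t-SNE comparison at n = 1,000
over 500 iterations.  One check — full-rank variance accounting over PCs
100–3450 of the 1000 Genomes Affy 6.0 cohort — requires the
accession-controlled genotypes and reports its data requirement when they
are absent; the variance-accounting code itself is oracle-tested on
synthetic full-rank problems.

## Known limitations

No LD pruning before PCA; no projection-bias (shrinkage) correction; no
imputation, phasing, or dosage support; the exact HWE path is integer-exact
but per-variant Python-loop speed, fine for 10⁴–10⁵ variants, not 10⁸;
UMAP/t-SNE internals are upstream dependencies, so numerical changes there
move embeddings (manifests record package versions for this reason).
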