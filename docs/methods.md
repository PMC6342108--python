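# Methods

This note documents the statistical models, numerical choices and
synthetic-data design behind `microscape`, and what the test suite does and
does not establish about real data.

## Population genetics

**Diversity.** Per locus, over typed individuals only: Na is the observed
allele count; Ne = 1/Σp² the effective allele number; Ho the observed
heterozygote fraction; uHe = 2n/(2n−1)·(1 − Σp²) the unbiased expected
heterozygosity. Per-locus F_IS = 1 − Ho/uHe. The across-locus inbreeding
coefficient is defined as 1 − mean(Ho)/mean(uHe), i.e. the ratio of means
rather than the mean of ratios; monomorphic loci (uHe = 0) have undefined
F_IS and are excluded from per-locus F_IS reporting but kept in the Ho/uHe
means. Missing data are handled by pairwise deletion (D_PS, relatedness)
or locus-wise complete cases (HWE, diversity), so no individual is dropped
globally for scattered missing calls.

**Hardy–Weinberg.** The exact test conditions on the observed allele
counts: the probability of a genotype table is Levene's multinomial form
n!·2^h·Πc_a!/( (2n)!·Πf_g! ) with h heterozygotes, genotype counts f_g and
allele counts c_a. The Monte-Carlo p is the fraction of allele-list
shuffles (observed table included, +1/+1 correction) whose conditional
probability does not exceed the observed one; the default is 100,000
shuffles, and a Bonferroni helper adjusts across loci. An exhaustive
enumeration over all genotype tables (feasible below ~8 distinct alleles)
serves as the exact reference in the validation studies.

**F_ST.** Weir–Cockerham variance components (a, b, c) per allele and
locus, summed over alleles and loci before forming θ = Σa/Σ(a+b+c);
negative estimates are reported as computed. Pairwise θ uses the two
groups' typed individuals per locus and requires at least two per group.

**D_PS.** For each dyad, the shared-allele count per co-typed locus is the
multiset intersection of the two genotypes (0, 1 or 2); the dissimilarity
is 1 − Σshared/(2·L_cotyped). It is a pseudo-metric: zero on identical
multilocus genotypes, symmetric, bounded by [0, 1].

**Relatedness.** Dyads are scored by the multilocus likelihood under the
IBD coefficient vectors U = (1,0,0), HS = (.5,.5,0), FS = (.25,.5,.25),
PO = (0,1,0), with loci independent and allele frequencies treated as
known. The one-gene-IBD transition probabilities are the standard
conditional forms (e.g. P(ab→ac | 1 IBD) = p_c/2). A locus with no shared
allele forces the PO likelihood to zero (Mendelian exclusion). Recovery of
full sibs exceeds 80% with 8 loci × 10 equifrequent alleles when the
frequencies are known; re-estimating frequencies from a small,
family-structured sample biases them and costs roughly ten points of
recovery — a caveat for small empirical panels.

**Pruning.** First-order dyads (best call FS or PO) form a graph; the
highest-degree individual is removed repeatedly (ties broken by smallest
id) until no edge remains — a deterministic greedy vertex cover, so the
"unrelated" dataset is reproducible. Any rule that removes one member per
dyad is admissible when dyads share members; this one minimizes removals
greedily.

## Clustering

Genotypes are encoded as an individuals × (locus, allele) matrix of allele
counts 0/1/2, with missing calls imputed by locus-allele means (keeping
column means unchanged). The K-scan runs K-means (20 restarts) on retained
PCs for K = 1..K_max and scores each partition with the spherical
Gaussian-mixture BIC for hard partitions (Pelleg–Moore form): a shared
variance σ² = WSS/(d(n−K)), mixing proportions n_k/n in the likelihood, and
(K−1) + Kd + 1 parameters. The simpler n·log(WSS/n) + K·log(n) score was
rejected: under hard assignment the WSS drop of splitting pure noise always
beats the K·log(n) penalty, so it never selects K = 1 even on panmictic
data. With the mixture BIC, simulations recover K = 1 on panmictic panels
and K = 2 on disjoint-allele-pool panels essentially always.

DAPC retains an explicit number of PCs (reported with the fraction of total
variance they carry) and fits an LDA on them; PC selection heuristics
(cross-validation, a-score) are left to the user because they are
implementation-specific — a train/test re-assignment check is the
recommended diagnostic.

## Landscape surfaces

NDVI = (NIR − Red)/(NIR + Red), masking cells with zero band sum and
propagating input masks. Ordinary kriging solves the standard system with a
Lagrange multiplier; the variogram (exponential default, spherical
available, "range" meaning the 95% practical range) is fitted by weighted
least squares on the empirical semivariogram with pair-count weights when
set to `auto`. With a zero nugget the predictor interpolates exactly;
far from all data it relaxes to the sample mean. Binary reclassification is
presence iff value ≥ threshold; the vegetation threshold default of
NDVI ≥ 0.1 reflects that bare rock and sand typically sit below 0.1.
Resampling is bilinear for continuous surfaces, nearest/majority for
categorical. Raster I/O uses the ESRI ASCII grid, a plain-text format that
round-trips nodata masks bit-exactly; coordinates are planar meters
throughout (study extents of ~1 km make geodesy irrelevant).

## Resistance transformations and connectivity

The transformation pipeline is: (1) affine rescale of the covariate to
[0, 10]; (2) "reverse" replaces x by 10 − x; (3) the base curve,
monomolecular 1 − e^(−bx) or Ricker x·e^(−bx); (4) "inverse" reflects the
output, y ← (max + min) − y; (5) affine rescale to [1, r]. Thus r is the
maximum resistance (capped at 2,500 by default) and every surface has
minimum exactly 1, nesting the flat null surface. The Ricker family is
implemented with the leading x — the standard hump-shaped form with
argmax at x = 1/b — since a pure exponential decay is already covered by
the monomolecular family's reflections.

The raster graph connects 8-neighbors; edge conductance is the arithmetic
mean of the two cell conductances 1/R (a `mean_resistance` alternative is
available), divided by √2 for diagonal steps. Commute distance is
vol(G)·R_eff(i, j), vol(G) = 2 × total edge conductance. Effective
resistances come from sparse LU solves of the grounded Laplacian — one
factorization, one solve per distinct sample cell — which is
ground-invariant and matches dense least-squares solutions to machine
precision. (A dense SVD pseudoinverse is *not* used: on this platform it
loses ~3 decimal digits on modest Laplacians; the validation oracle instead
uses the exact identity L⁺ = (L + J/n)⁻¹ − J/n.) Multiplying all
resistances by a constant leaves the commute matrix unchanged (volume and
resistance scale inversely), consistent with predictors being standardized
before model fitting. Points are snapped to their containing cell under
half-open cell intervals; points in masked cells and disconnected pairs are
errors, not silent repairs.

## MLPE estimation

The model is y_ij = β₀ + Σβ_m x_m,ij + u_i + u_j + ε_ij with u ~ N(0, σ²_u)
per individual, giving cov(y) = σ²_ε I + σ²_u Z Zᵀ. Estimation is exact
maximum likelihood: for a fixed variance ratio φ = σ²_u/σ²_ε, GLS estimates
of β and σ²_ε are closed-form through the Woodbury identity (only an
n_individuals-sized Cholesky is formed; log|V| via Sylvester's
determinant identity), leaving a smooth one-dimensional profile in log φ
minimized by bounded scalar search from three overlapping brackets, with an
explicit comparison against the φ = 0 boundary. Tolerance is 1e-10 on the
profile argument; restarts agree to <1e-6 in log-likelihood. Predictors
are standardized over the lower-triangle pairs before fitting, matching the
convention for resistance distances. This variance-components form induces
the same covariance family as the compound-symmetry correlation
parameterization used elsewhere for MLPE; the two are reparameterizations
of one model.

Parameter counts for information criteria follow a fixed convention:
null = 1, distance = 2, categorical surface = categories + 1, single
continuous surface = 4, composite = 2·(surfaces) + 1; a `k_override`
escape hatch exists because no single per-parameter rule reproduces all
published usages. AICc uses n = number of individuals, not pairs — pairs
are heavily dependent, and individuals are the effective replication unit.
The GA objective is AIC; model selection across optimized surfaces uses
AICc; both are always reported.

## Optimization

The GA is real-coded: tournament selection (size 3), BLX-0.5 blend
crossover, Gaussian mutation (sd = 15% of the gene span; log-scaled genes
mutate on the log scale), uniform resampling for the categorical
family/mode gene, elitism of one, and termination on 15 stagnant
generations (default) or the generation cap. Defaults are population 40 and
100 generations; the validation studies use population 16 and 25
generations on a 16×16 raster, sizes chosen so twenty full replicates run
on one CPU in a few minutes. Fitness evaluations are cached by chromosome.

Because the GA is stochastic and the transformation families can mimic one
another locally, convergence is confirmed by independent runs:
`fit_runs(n_runs=3)` takes the best of three seeded runs, which in the
bundled scenario recovers the true family/mode in ≥95% of replicates where
single runs reach ~60–70%. Curve-family identifiability is intrinsic:
x·e^(−bx) at large b approximates a convex decay, so weak-curvature
inverse-monomolecular truths are genuinely ambiguous — the bundled
strong-signal scenario therefore uses b = 1.0 (see below).

Composites sum the individually transformed surfaces and shift the sum to
minimum 1; the contribution of a surface to a composite is its mean
transformed value as a percentage of the sum of means (contributions add to
100%). Surface pairs enter composite candidacy when their cell-wise
Spearman |ρ| < 0.29 (small-to-medium correlation); a matrix-wise
alternative is available via the commute predictors.

Bootstrap model selection subsamples ⌈0.75·n⌉ individuals without
replacement per iteration, refits every candidate by MLPE on the subsetted
matrices with its already-optimized transformation frozen (re-optimizing
inside each of thousands of iterations would be computationally incoherent)
and tallies average AICc rank, average Akaike weight and top-model
percentage. With fraction 1.0 and one iteration it reproduces the full-data
comparison exactly. The full-scale 10,000-iteration setting is supported;
validation studies use 30–500 iterations.

## Isolation by distance

The Mantel statistic correlates lower triangles (Spearman by default);
significance comes from simultaneous row/column permutations of one matrix,
two-tailed, p = (#{|r_perm| ≥ |r_obs|} + 1)/(n_perm + 1). The correlogram
tests 0/1 distance-class membership indicators (50 m classes by default,
the focal species' reported mean dispersal scale) against the genetic
matrix, flags classes with <20 pairs as low-power, and applies Holm
correction across classes (progressive Bonferroni would be slightly more
liberal at far classes; Holm is uniformly valid).

## Home ranges

The utilization distribution is a bivariate Gaussian kernel density with
the reference bandwidth h_ref = ((sd_x + sd_y)/2)·n^(−1/6), evaluated on a
grid covering the fixes padded by 3h at cell size h/4, renormalized to
integrate to one on the grid. The home range at level q is the smallest set
of highest-density cells whose mass reaches q; area is cell count × cell
area, reported in hectares. Least-squares cross-validated bandwidths are
omitted (reference and LSCV areas are equivalent for this design, and LSCV
is unstable at 10 fixes). Overlap(A→B) is the percentage of A's isopleth
covered by B's, computed after re-evaluating both UDs on a common grid
(finest cell size; coarsened automatically if widely separated ranges would
exceed ~4M cells). Activity metrics group fixes into noon-to-noon nights
and report consecutive step distances and nightly maxima. Mann–Whitney U is
computed exactly via the counting recurrence when n₁n₂ ≤ 400 and the data
are tie-free, otherwise by normal approximation with tie correction and
continuity correction; the reported U is min(U_a, U_b) with both one-sided
values alongside.

## Synthetic data

The generators emulate the statistical structure of a microgeographic
desert study:

* **Random fields** — Gaussian smoothing of white noise at a correlation
  length (50 m default), affinely scaled to target mean/sd. Defaults:
  NDVI-like mean 0.17, sd 0.13, clipped to [−1, 1] (≈30% of cells below
  0.1, the bare-soil fraction typical of arid shrubland); humidity 44%,
  sd 8; temperature 30 °C, sd 3; elevation 1152 m, sd 15.
* **Genetic distances** — generated directly from the MLPE model on the
  standardized commute distances of the true resistance surface, clipped to
  [0, 1] as a D_PS-like dissimilarity. Distance-level simulation matches
  the model being fit and keeps recovery tests sharp; genotype-level
  processes (drift, coalescence on a landscape) are deliberately not
  simulated, so passing tests demonstrate correct inference under the
  model, not robustness to model misspecification.
* **Microsatellite families** — allele frequencies from a symmetric
  Dirichlet per locus, founders in Hardy–Weinberg proportions, PO/FS/HS
  dyads by Mendelian transmission, with a truth table emitted. Real
  microsatellite data additionally carry null alleles, stutter and
  genotyping error, which these panels do not.
* **Telemetry** — bivariate-normal fixes around per-individual centers, ten
  fixes on a 30-minute lattice inside the 21:00–01:30 nightly tracking
  window over consecutive nights. Real movement is autocorrelated and
  habitat-dependent; these tracks are exchangeable draws, adequate for
  testing estimators, not behavior.

The bundled scenario ("mapimi-small") is a 60×60 grid of 5 m cells, four
surfaces, 40 individuals placed uniformly, an 8-locus × 10-allele panel,
and nine telemetry animals. Its true signal is an inverse-monomolecular
transformation of the greenness surface with b = 1.0 and r = 200, β₁ = 0.15
and σ²_u = σ²_ε = 5·10⁻⁴. The curvature and noise level define what
"strong signal" means here: a pilot identifiability analysis showed that at
b ≈ 0.5 the rescaled inverse-monomolecular and Ricker curves are nearly
indistinguishable, making family/mode recovery ill-posed regardless of
sample size; at b = 1.0 the true curve has strictly better AIC and
best-of-three GA runs recover it reliably. All generators are
bit-reproducible under a fixed seed.

## Validation studies and problem sizes

`validation.py` (run by `scripts/acceptance.py` and the acceptance tests)
uses these sizes, chosen so the full set completes in minutes on one CPU:

* commute oracle: one 40×50 raster (2,000 vertices), 8 points, max relative
  error vs the dense L⁺ identity (<1e-8 required, ~1e-14 observed);
* MLPE recovery: 200 replicates at n = 40 individuals (780 pairs) with
  β₁ = 0.5, σ²_u = 0.3, σ²_ε = 0.2 on a 30×30-raster commute predictor;
  ≥95% of slopes within 3 SE required;
* optimization recovery: 20 seeded replicates on a 16×16 raster with 25
  individuals; GA population 16, 25 generations, best of 3 runs for the
  true surface; bootstrap 30 iterations; the true surface must top the
  bootstrap and the true family/mode be recovered in ≥80%;
* null calibration: 20 replicates with β₁ = 0; the optimized surface must
  not beat the plain-distance model by more than 2 AICc in ≥90%;
* closed forms: Akaike weights at ΔAIC {0, 2}; Ricker argmax on a
  2001-cell ramp; the 95% kernel area of 1,000 isotropic-normal fixes
  against 5.991πσ² (±15%); h_ref on a constructed sd-4, n-64 sample;
* exact tests: Monte-Carlo HWE vs full enumeration (6 individuals, 3
  alleles, 20,000 shuffles, within 3 MC standard errors); Mantel p
  uniformity under independence (200 runs, KS p > 0.01); exact
  Mann–Whitney vs brute-force enumeration (3 vs 5).

The home-range sex comparison uses a worked table of nine radio-tracked
kangaroo rats (six male, two female, one undetermined): male mean 0.6955
ha, female mean 0.2455 ha, U_male = 8 by exhaustive pair counting. Note
that with six and two animals the largest possible U is 12; any much larger
published U for such a comparison cannot arise from these group sizes.

## Known limitations

* Genetic distances are simulated at the distance level; no spatially
  explicit coalescent or forward-time simulation is provided.
* Curve families overlap at weak curvature; family/mode labels from a
  single GA run should not be over-interpreted — use `fit_runs` and treat
  the fitted response curve, not its label, as the result.
* Kriging assumes stationarity and an isotropic variogram; no anisotropy.
* The exact Mann–Whitney path requires tie-free data; ties fall back to
  the corrected normal approximation regardless of sample size.
* Commute distances require a connected graph between all sample points;
  barriers that disconnect the raster are reported as errors rather than
  treated as infinite resistance.
* AICc's small-sample correction uses individuals as n; with very small
  panels (n close to k) the correction is aggressive by design.
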