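# Methods

This note documents the models, estimator conventions, numerical choices and
known limitations behind `broompop`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A dataset is a matrix of unordered diploid allele-size pairs (individuals ×
loci), with per-individual metadata. A *population* is the set of individuals
collected in one agricultural field growing a single host crop; the
population → host mapping must therefore be a function, and this is asserted
at construction. Missing calls are encoded as 0 in GenAlEx-style files and as
−1 internally; a half-missing pair is treated as fully missing. Allele sizes
(bp) convert to repeat counts as `(size − offset) / motif_length` per locus —
Bruvo distance, the mutation simulator, and the allele-size summary
statistics all operate on repeat counts, while files store fragment sizes.

## Diversity and differentiation estimators

- **Per-population diversity.** Na (alleles/locus), effective alleles
  `1/Σp²`, observed heterozygosity, and unbiased expected heterozygosity
  `(2n/(2n−1))(1−Σp²)`, averaged over loci, missing calls excluded per locus.
- **F-statistics.** Weir–Cockerham variance components a (among populations),
  b (among individuals within populations), c (within individuals), computed
  per allele per locus and combined by ratio of sums:
  θ = Σa/Σ(a+b+c), F_IS = 1 − Σc/Σ(b+c). The ratio-of-sums weighting (not a
  mean of per-locus ratios) matches the common R implementation of these
  estimators. 95% CIs are percentile bootstrap over loci (999 replicates by
  default); with fewer than two polymorphic loci the CI is flagged as
  degenerate. Note that θ estimated between *identical finite samples* is
  slightly negative — the estimator subtracts within-sample variance — so
  "no differentiation" means θ near 0, not exactly 0.
- **Jost's D.** Per locus, `D = (k/(k−1))(Ht−Hs)/(1−Hs)` with Nei–Chesser
  unbiased estimates: `Hs = (2ñ/(2ñ−1)) hs` (ñ = harmonic mean sample size),
  `Ht = ht + Hs/(2ñk)`. Across loci the summary is the variance-corrected
  (Chao) harmonic mean after flooring negative per-locus values at zero:
  `1/(1/D̄ + var(D)/D̄³)`. The CI bootstraps individuals within populations.
- **AMOVA.** Three strata (among host crops / among populations within hosts
  / within populations), computed on per-individual allele-count indicators
  (0/1/2 per allele column), one locus at a time and summed — not on squared
  Euclidean genotype distances. Mean squares convert to variance components
  with the standard unequal-sample-size coefficients of the nested design.
  Degrees of freedom are reported from the actual input. Negative components
  are reported as estimated, never truncated. Φ-statistics are ratios of
  component sums; CIs bootstrap loci. Groups holding a single population are
  pooled into a `_pooled` stratum with a warning.
- **Geography.** Haversine great-circle distance, Earth radius 6371.0 km.
  Mantel tests correlate off-diagonal upper triangles, permute rows/columns
  of the second matrix jointly, and report the one-tailed (greater) p-value
  with the +1 correction. Type-I error at α = 0.05 is verified at ~5% by
  simulation in the test suite.

## Clone correction

Individuals with identical complete genotypes share a raw MLG. Raw MLGs are
collapsed by complete-linkage (farthest-neighbour) agglomeration on Bruvo
distance: per locus the allele distance is `1 − 2^−|Δrepeats|`, the diploid
genotype distance is the better of the two one-to-one allele pairings, and
the genotype distance is the locus mean. Clusters merge only while their
*maximum* pairwise distance stays at or below the threshold, so the collapse
is conservative and monotone in the threshold. No collapse threshold is
universal; by default the package places it in the widest gap of the sorted
pairwise distances below their median, reports it in every output, and
accepts an override. Rarefied eMLG uses the exact hypergeometric expectation
`Σᵢ[1 − C(N−nᵢ, g)/C(N, g)]` (log-gamma evaluation for large N); when a unit
holds fewer than g genotypes the eMLG is reported at the unit's own size and
flagged. Sharing classes: singleton (one individual), host-specific
(non-singleton, one host), shared (non-singleton, ≥2 hosts; counted for
every host involved). The minimum-spanning network over non-singleton MLGs
keeps every edge that ties the minimal joining weight between two components
(classic MSN semantics, same construction as the haplotype network).

## DAPC

Individuals are encoded as centred allele counts (no variance scaling —
common practice for SSRs), reduced by PCA, clustered by k-means (10 restarts)
for K = 1..k_max, and scored by `BIC(K) = n·ln(WSS/n) + K·ln(n)` on the
retained PCs (default: enough PCs for ≥90% variance). The discriminant step
is a linear discriminant analysis on the retained PCs; membership
coefficients are the LDA posterior probabilities (rows sum to 1). The
a-score — mean over clusters of (observed correct-reassignment proportion −
its mean under random relabelings) — selects the PC count for the
discriminant step; note its ceiling is 1 − 1/K, ~0.5 for two balanced
clusters. An individual is *assigned* when its maximum membership exceeds
the threshold (default 0.9), otherwise *admixed*.

Membership posteriors are sharp sigmoids of the discriminant coordinates:
between strongly separated clusters only genotypes very near the exact
midpoint fall below a 0.9 threshold. Detecting intermediate (admixed)
genotypes therefore requires the admixing clusters to be close relative to
their internal spread — which is also the biologically relevant regime,
since recent hybrids occur between compatible, related lineages.

## Migrant detection

The test statistic is L_H, the likelihood of a multilocus genotype in its
home population under the Rannala–Mountain multinomial-Dirichlet predictive
with prior mass 1/k per allele (k = distinct alleles at the locus in the
whole dataset, so unseen alleles never get probability zero): the first
allele has probability `(n_a + 1/k)/(n + 1)`, the urn is updated for the
second, and heterozygotes carry the factor 2. Missing loci are skipped.
Critical values follow the resampling scheme: per population, 10,000
multilocus genotypes are simulated from the empirical allele frequencies and
the p-value is the (+1-corrected) fraction of simulated log-likelihoods at
or below the observed one; individuals with p < 0.01 are flagged.

Two deliberate conventions:

- **Leave-one-out defaults OFF.** Simulated null genotypes are never part of
  the reference counts, so evaluating observed individuals against the full
  reference keeps both sides of the comparison on the same footing. With
  reference populations of ~11 selfed individuals, removing the focal
  individual deletes its private alleles from the reference entirely, and
  the measured false-positive rate at α = 0.01 rises from ~2% to ~18%. The
  flag remains available for larger reference samples.
- **HWE null by default, selfing-aware null as an option.** The default
  assembles simulated genotypes from two independent allele draws, mirroring
  the standard resampling. For a highly selfing organism this null contains
  too few rare-allele homozygotes; `null_autozygosity=F` duplicates a single
  draw with probability F instead. The default keeps the conventional
  behaviour; the test suite demonstrates the difference.

The most likely source population (argmax likelihood) is reported but never
used for flagging, since not all source populations are assumed sampled.

## Coalescent simulator

Backward-in-time coalescent on gene copies within demes connected by a
rooted tree of merge events: within a deme holding j lineages, the waiting
time to the next coalescence is exponential with rate `j(j−1)/(4N)` per
generation (N in diploid individuals); at a merge event all lineages of the
derived deme transfer instantaneously into the source deme; each deme keeps
a constant N along its branch. Verified against closed forms: mean pairwise
TMRCA = 2N; mean total tree length for n copies = 4N·Σ1/i.

Mutations are Poisson on branches with per-locus rates (Gamma-distributed
around a dataset-level mean, shape 2 by default). Each mutation moves the
repeat count ±1 with probability 1−P, otherwise by a geometric multi-step
(GSM); P = 0 is the strict stepwise model. Boundaries reflect on a
contiguous grid of 40 allele states by default. At equilibrium the sample
allele-size variance matches the SMM expectation θ/2 = 2Nμ (verified to
Monte-Carlo error). Mutation priors default to μ̄ ∈ U[1e−4, 1e−3] and
P ∈ U[0.1, 0.3] — conventional choices for SSR ABC when a study does not
publish its mutation priors — and are fully configurable.

Selfing enters as post-hoc autozygosity: each individual's two gene copies
are identical by descent with Wright's equilibrium probability F = s/(2−s)
(sample one lineage and duplicate), otherwise two independent copies. This
reproduces the observed inbreeding coefficient without restructuring the
genealogy; it does *not* model the reduced effective size or increased
identity disequilibrium of real selfing lineages.

Scenario builders: the six serial-derivation topologies over three sampled
demes (ancient pair × which member spawns the third deme; ancient time
U[100, 100000] generations, recent U[10, 10000], all Ne U[10, 1000], ancient
> recent enforced by rejection); a four-deme ghost topology (ghost splits
from the third deme at t_ancient ∈ U[1000, 50000], the second deme derives
from the third at U[10, 5000], the first derives from the *ghost* at
U[10, 1000]); and six "toy" variants with narrow priors and a bottlenecked
derived deme, used wherever a desk-scale check needs scenarios that are
actually distinguishable from 10 loci. Note that within one serial topology
pair the two scenarios differ only through the ancestral branch's effective
size, so the six wide-prior study scenarios are *not* fully separable — the
toy set makes each scenario identifiable by (which pair split recently,
which deme lost diversity).

## Synthetic study fixture

`make_study_fixture` generates the stand-in for the deposited genotypes: 5
host clusters × 15 field populations × 11 individuals, 10 loci, simulated on
a single divergence tree — one strongly divergent cluster derived from an
unsampled ghost lineage (t = 400 of 20,000 generations), deep backbone
clusters (t = 2000–3500), and one recently diverged "sibling" cluster pair
(t = 1000, small ancestral Ne = 50, nearly panmictic fields). Selfing rate
0.97 (autozygosity 0.94, inside the study system's plausible range),
μ = 2.5e−4, GSM P = 0.2. Planted events with emitted truth labels:

- **Migrants (9%)**: genotype drawn from another population — same host
  cluster with probability 0.8 (host-constrained migration dominates in
  these systems), otherwise another cluster.
- **Admixed (3%)**: F1 between the sibling clusters (one gene copy from a
  home parent, one from a donor-cluster parent), planted only within the
  sibling pair with the within-pair rate scaled to keep the dataset-wide
  fraction at 3%. Because the siblings differ by near-fixed differences,
  these F1s sit squarely between the clusters in discriminant space, which
  is what makes threshold-based admixture detection a structural property
  of the fixture rather than a lottery over drift realizations.

Across seeds the fixture shows overall θ ≈ 0.73–0.81, pooled F_IS ≈
0.78–0.88, mean within-population uHe ≈ 0.14, among-host Φ well above
within-host Φ, detected migration 6–11%, and detected admixture 2–4%.

What the fixture does **not** emulate: genotyping error and missing data
(calls are complete), unequal population sizes (1–48 in real surveys),
linkage between loci, null alleles, seed banks, and temporal sampling. Tests
passing on the fixture show the estimators and detection machinery recover
planted truth under the modelled conditions; they do not certify behaviour
under those unmodelled artefacts.

## ABC random forests

Each dataset reduces to a named statistic vector: per deme — mean allele
number, mean expected heterozygosity, mean allele-size variance (repeat
units), mean Garza–Williamson M (alleles / span of the sampled repeat
range); per deme pair — Weir–Cockerham θ, an allele-frequency shared-allele
distance `1 − Σ_a min(p1_a, p2_a)` averaged over loci, Goldstein's (δμ)² on
repeat counts, and the symmetrized mean log10 cross-assignment likelihood.
With three demes that is 24 statistics; the manifest of names travels with
every training table, and the set is configurable.

Scenario choice trains a classification forest (1000 trees, 10 replicate
forests by default) on the statistics plus up to three linear discriminant
axes fitted on the scenario labels. Votes on the observed point are per-tree
vote shares; the selected scenario maximizes the replicate-averaged votes.
The posterior probability of the selected scenario is obtained by regressing
the out-of-bag correctness indicator (pooled across replicates) on the
predictors and evaluating at the observed point. Global error is the OOB
misclassification rate; local error is the OOB error among the 500 nearest
training points in LDA space.

Parameter estimation uses quantile regression forests: the observed point's
leaf-co-occupancy weights over training simulations define weighted 2.5/50/
97.5% quantiles. Trees keep at least 5 training points per leaf — fully
grown single-point leaves underestimate the conditional spread and gave
measurably anticonservative intervals (~91% coverage of nominal 95%); with
5-point leaves coverage sits at 93–95% over 200 pseudo-observed datasets.
Global NMAE is `mean(|OOB prediction − truth|/truth)` over (a sample of) the
training rows; local NMAE re-weights the same OOB errors with the observed
point's leaf weights. The prior/scenario check reports the empirical
quantile of every observed statistic among prior-predictive simulations and
flags values outside [0.005, 0.995].

## Haplotypes

Aligned sequences collapse into haplotypes over the columns free of N/gaps
in every record (complete-deletion); a site is variable iff ≥2 distinct
unambiguous residues occur there. The minimum-spanning network uses Kruskal
construction with tie retention: within one weight class, every edge joining
components that were distinct before the class is kept, so all
equally-parsimonious connections survive. Median-joining networks (with
inferred median vectors) are deliberately not implemented.

## Problem sizes in the test suite

The suite validates at desk scale: oracle comparisons on ≤20 individuals,
simulator physics on 200–5000 replicates of small samples, ABC checks on
6 × 100 training simulations with 200-tree forests and 200 pseudo-observed
datasets, and fixture-level checks on the default 825-individual fixture.
These sizes give Monte-Carlo error well inside the asserted tolerances while
keeping the whole suite under a few minutes; all full-scale defaults
(10,000 simulations per scenario, 1000 trees, 999 bootstraps) remain the
package defaults and are exercised at reduced size through the same code
paths.

## Known limitations

- The coalescent is approximated in continuous time; for extremely small N
  (≲5 diploids) discrete-generation effects are not captured.
- Post-hoc autozygosity reproduces equilibrium F_IS but not the genome-wide
  correlation structure of real selfing (identity disequilibrium), so
  statistics sensitive to multilocus homozygosity correlations would be
  optimistic.
- The AMOVA is limited to three levels; Φ CIs come from bootstrap over loci
  only (no permutation p-values).
- Bruvo distance is used with both genomes known (pure diploid data); genome
  addition/loss models for mixed ploidy are out of scope.
- The triangle inequality is not guaranteed for the diploid pairing-minimum
  extension of Bruvo distance; it is treated as a dissimilarity, not a
  metric.
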