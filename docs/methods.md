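# Methods

## Scope and data model

`polyssr` analyses dominant-scored microsatellite (SSR) panels in
polyploids, the typical situation for autotetraploid forage crops scored by
capillary electrophoresis: each distinct fragment length at a locus is one
binary character (1 = fragment present), and dosage among the four
homologues is unobservable. The central object is the individuals × alleles
presence/absence matrix with allele columns grouped into marker loci.
Structural invariants are enforced on construction: binary entries, unique
ids and columns, and no all-zero columns — an allele never observed in the
panel is not an allele of the panel, so subsetting drops columns that
become unobserved and reports them.

A whole individual × locus block of zeros is legal and is interpreted as
amplification failure; it affects statistics only through the fixed
denominator n (the full panel size) and is surfaced by a per-locus
missingness report. The occurrence denominator is always n, never the
number of amplifying individuals, so the smallest observable occurrence
frequency is 1/n.

## Polymorphism statistics

For dominant data the gametic allele frequency cannot be recovered, so
informativeness is computed per allele from its occurrence frequency
f = count/n:

    PIC = 2 f (1 − f)

with maximum 0.5 at f = 1/2 and 0 for absent or fixed fragments. Per-marker
summaries report the unweighted mean, minimum and maximum of PIC over *all*
alleles of the locus, monomorphic (f = 1) alleles included — a biallelic
locus with one fixed fragment and one at f = 0.5 therefore has
PIC_Av = mean(0, 0.5) = 0.25. Private alleles are columns with occurrence
count 1; per-individual and per-marker private tallies are consistent by
construction (both sum to the number of such columns). Report rounding is
half-up at 2 decimals (1 decimal for per-panel means); internal computation
is at full precision.

Group tallies (allele totals and mean alleles per individual within a
group) accept any individual → label map; a helper collapses passport
status into the cultivar (cultivar + cultivated) vs non-cultivar split.

## Distances

* Euclidean distance between 0/1 rows (the square root of the Hamming
  distance).
* Modified Rogers' distance D_w = Euclidean / sqrt(2L), L the number of
  marker loci. The classical D_w divides summed squared frequency
  differences by 2L; with presence/absence coding in place of frequencies
  this constant rescaling is the only convention that keeps D_w exactly
  linear in the Euclidean distance with zero intercept and a slope shared
  by all pairs. Consequence: the theoretical [0, 1] range of D_w on
  frequency data is *not* guaranteed for dominant coding, so
  `DistanceMatrix.observed_range()` reports the realised range rather than
  asserting the bound.
* Nei & Li / Dice similarity S = 2·n_ab/(n_a + n_b) — the proportion of
  shared fragments, the standard for dominant fragment data. The simple
  matching coefficient was rejected because absence/absence matches are not
  shared fragments. The conversion −ln S maps S = 1 to distance 0 and is
  undefined at S ≤ 0 (disjoint fragment sets), which is raised as a domain
  error.

## Dendrogram support: multiscale bootstrap and AU p-values

The dendrogram is average linkage (UPGMA) on D_w via
`scipy.cluster.hierarchy`; since D_w is a constant rescaling of the
Euclidean metric, the tree equals the Euclidean tree with rescaled heights.
Average linkage is the default, with complete and Ward available behind a
flag. Cluster support uses multiscale bootstrap resampling of features:

1. For each scale r in {0.5, …, 1.4} (ten scales, step 0.1), draw B
   resamples of round(A·r) allele columns with replacement. Multiplicities
   act as integer column weights; the weighted squared Euclidean distance
   is computed by a Gram-matrix identity (x² = x for binary data), which is
   exactly equivalent to duplicating columns. An option resamples whole
   marker blocks instead, to respect within-locus dependence; allele
   columns are the default resampling unit.
2. BP_r(cluster) is the fraction of resample trees containing the cluster
   as a leaf set (leaf sets are compared as bitmasks).
3. Per cluster, the signed-distance/curvature model
   z_r = v·s_r + c/s_r with s_r = sqrt(1/r) and z_r = Φ⁻¹(1 − BP_r) is
   fitted by weighted least squares with delta-method binomial weights
   B·φ(z_r)²/(BP_r(1 − BP_r)). The approximately unbiased p-value is
   AU = 1 − Φ(v − c); the corrected BP at scale 1 is 1 − Φ(v + c), and the
   two coincide when the fitted curvature c is 0.

Numerical choices: BP values are clamped to [1/(2B), 1 − 1/(2B)] before the
probit transform; scales whose BP sits at a clamp bound carry no model
information and receive weight zero. When fewer than two informative scales
remain the fit is flagged degenerate and AU falls back to 1 if the mean
clamped BP exceeds 0.5 (a cluster observed in essentially every resample)
and 0 otherwise (never observed) — this covers both limits without
extrapolating a two-parameter model from fewer than two points. At least
two distinct scales and B ≥ 100 are required; fewer is refused rather than
silently producing meaningless AU values. Newick export annotates internal
nodes as `[au=97,bp=85]` (percentages), and a flat table exposes AU, BP, v,
c and the degenerate flag per node.

## k-means cascade and Calinski–Harabasz

Lloyd's algorithm runs on the binary data rows for k = 2..10 by default
(configurable up to n − 1), best of `restarts` random-point initialisations
per k by within-cluster sum of squares. Because D_w is a rescaled Euclidean
metric on those rows, partitions in D_w geometry and raw-row geometry
coincide. The within-cluster objective is asserted non-increasing across
Lloyd iterations on every run; emptied clusters are re-seeded at the
worst-fit point. Each k is scored by

    CH(k) = [B/(k − 1)] / [W/(n − k)]

(between- vs within-cluster sum of squares), and the selected k is the
argmax with ties broken toward smaller k (parsimony). A panel of identical
rows is reported as degenerate input rather than scored; W = 0 for a
non-trivial partition yields CH = ∞ rather than an exception. Lloyd and CH
are implemented in-package so the monotonicity invariant can be asserted
per iteration; scikit-learn's `KMeans` and `calinski_harabasz_score` serve
as independent cross-checks in the test suite.

## PCA

Principal components of the raw binary matrix: columns centred, not
scaled, scores U·S from the singular value decomposition, percent variance
from the squared singular values. Keeping all min(n − 1, A) components
reproduces the pairwise Euclidean geometry of the centred data exactly
(verified in tests).

## Synthetic panels

The generator emulates a diversity panel of autotetraploid individuals in
latent origin groups:

| parameter | default | meaning |
|---|---|---|
| n_individuals / group_sizes | 32, (16, 16) | panel size and latent groups |
| n_loci | 101 | marker loci |
| alleles_per_locus | 2..24 (uniform) | potential alleles per locus |
| base_freq_concentration | 1.8 | symmetric Dirichlet concentration of ancestral gametic frequencies |
| divergence_f (F) | 0.15 | Balding–Nichols divergence: group frequencies ~ Dirichlet(p·(1−F)/F) |
| dropout_rate | 0 | per individual × locus amplification-failure probability |

Each individual draws four allele copies iid from its group's gametic
frequencies (autotetraploid, polysomic, no double reduction — the minimal
inheritance assumption) and dominant scoring keeps the set of distinct
copies, so an allele at gametic frequency p is visible in an individual
with probability 1 − (1 − p)⁴. Unobserved columns are dropped from the
matrix but kept in the truth object.

Calibration: the concentration default 1.8 was fixed by a one-off scan so
that default panels land at roughly 9.5 observed alleles per locus and 2.7
distinct alleles per individual per locus over 10 seeds, with ~12 % of
observed alleles private. Under this model the two realistic targets
(≈11 alleles/locus together with ≈2.3 distinct alleles/individual/locus)
are in tension: matching the lower per-individual count requires a skewed
frequency spectrum whose rare alleles mostly go unobserved in a 32-plant
panel, and matching the higher locus-level count pushes the per-individual
count toward 3.5. Real diversity panels escape this because individuals
come from many more than two differentiated populations, which inflates
locus-level allele counts without inflating per-individual counts; the
generator deliberately keeps the two-group Balding–Nichols structure for
interpretability. Passing calibration tests therefore show the generator is
in the right statistical regime, not that it reproduces any particular real
panel. It also simulates no stepwise mutation, stutter artefacts, scoring
error or linkage between loci.

`recovery_report` closes the loop: it runs the cascade, PCA and bootstrap
on a simulated panel and scores the result against the generator truth
(adjusted Rand index, selected k vs true group count, |PC1–group|
correlation, AU of the true group clades and of the two children of the
dendrogram root).

## Pipeline and reproducibility

A single YAML config (exactly one of an input matrix path or a simulate
block) drives the full chain; every stochastic stage takes an explicit
integer seed recorded in the output bundle, and a rerun with the same
config produces byte-identical outputs. Wall-clock timings are emitted on
the console logger only, so they never enter the bundle. On any stage
failure partial outputs are removed and the error names the stage and the
offending record. The `polyssr` CLI is a thin layer over these functions.

## Problem sizes used in the shipped checks

Unit and property tests run on panels of 2–12 individuals plus one shared
simulated study-scale panel (32 × 101 loci). Simulation-based checks use 10
seeds at study scale with B = 1000 bootstrap replicates across ten scales;
the closed-form presence check uses one undiverged group of 400–500
individuals at 10–12 loci. These sizes keep the whole suite in the order of
a minute while leaving the Monte-Carlo error well below the asserted
margins.

## Known limitations

* AU p-values inherit the usual caveats of the multiscale bootstrap: they
  are asymptotic, and clusters with BP pinned at 0 or 1 across all scales
  get the degenerate fallback rather than a model-based value.
* D_w values from binary coding are not comparable in absolute terms to
  D_w computed from dosage-resolved allele frequencies; only the geometry
  (rankings, linear structure) carries over.
* The generator's iid-copies model ignores double reduction and
  preferential pairing; both would lower observed heterozygosity slightly.
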