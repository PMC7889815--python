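# Methods

`msatpop` re-implements, as one tested pipeline, the statistical arc of a
range-wide microsatellite survey of a structured tree species: per-population
diversity, hierarchical variance partitioning, a pure/admixed population
partition from ancestry coefficients, coalescent ABC over competing
demographic scenarios, isolation-by-distance vs isolation-by-environment
testing, and climatic niche overlap. This note records the models, the
conventions behind every estimator, the synthetic-data design, and the
numerical choices that were genuinely open.

## Diversity statistics and their conventions

Per population and locus, from allele frequencies `p` over typed gene copies:
number of alleles `Na`, effective alleles `Ne = 1/Σp²`, Shannon index
`I = −Σ p ln p`, observed heterozygosity `Ho` (fraction of heterozygous typed
individuals), and expected heterozygosity `He = 1 − Σp²` — Nei's gene
diversity *without* small-sample correction, the GenAlEx convention. The
inbreeding coefficient `FIS` is Weir & Cockerham's (1984) `f`, a ratio of
sums of variance components over alleles and loci, the GENEPOP convention.
Because `He` and `FIS` come from different estimator families,
`FIS ≠ 1 − Ho/He` computed from the same table; this mirrors the mixed
toolchains such studies actually use and is why the packaged reference table
is internally consistent without satisfying that identity.

`H_S`/`H_T` follow the FSTAT convention: `H_S` is the unweighted mean
within-population gene diversity per locus, `H_T` the diversity of the
unweighted mean allele-frequency vector (a copy-weighted variant is a flag).
PIC is the standard `1 − Σp² − Σ_{i<j} 2 p_i² p_j²`. PPL is the percentage of
loci with at least two alleles in the population.

Pairwise differentiation is Weir–Cockerham `θ` (multi-locus,
multi-allele, ratio of sums). Negative estimates are retained in the raw
matrix and clamped to zero only in the distance view used downstream.
Half-missing genotypes are promoted to fully missing at load time (a single
documented decision point) so `Ho` is not biased by single dropped alleles.

## AMOVA with R-statistics

The hierarchical AMOVA operates at the gene-copy level: each diploid
contributes two multilocus copies, and the squared distance between two
copies is the squared difference of repeat counts summed over loci (the
R-statistic frame appropriate for stepwise-mutating loci; an
allele-identity distance gives Φ-style statistics instead). Pairs typed at
only a subset of loci contribute their typed loci rescaled to the full locus
count. Sums of squares follow the classical
`SSD(S) = Σ_{i<j∈S} d²_ij / n_S` decomposition; variance components use the
standard unequal-sample-size coefficients; `R_CT = σ²_a/σ²_T`,
`R_SC = σ²_b/(σ²_b+σ²_c)`, `R_ST = (σ²_a+σ²_b)/σ²_T`. Significance comes
from the standard permutation schemes — individuals among populations within
groups for `R_SC`, whole populations among groups for `R_CT`, individuals
among all populations for `R_ST` — with 1,000 permutations by default and a
mandatory seed. Percentages of variance sum to 100 by construction; with few
populations per group the `R_CT` permutation distribution is coarse and its
p-value granular, which is a property of the design, not the code.

## Partitioning populations by ancestry

Individuals with maximum ancestry coefficient `q ≥ 0.9` are genetically
pure; each population's `Qp` is its fraction of pure individuals;
populations with `Qp ≥ 0.8` are "pure" and are routed to group 1 or group 3
by the argmax of the population's mean ancestry vector (the assignment rule
itself is never stated in the literature this mirrors; mean-q majority is
the natural choice). Both thresholds are boundary-inclusive — forced by the
packaged table, where two populations sit exactly at `Qp = 0.80` and belong
to pure groups. `ΔK` follows Evanno: second difference of mean log-evidence
over replicate runs divided by the replicate standard deviation, undefined
at the boundary or where replicates agree exactly. The clustering MCMC
itself is out of scope; Q-matrices are inputs or synthetic truth.
Introgressed individuals inside pure populations are kept for downstream
analysis by default (a flag can drop them).

## Demographic scenarios and the coalescent simulator

Three sampled groups (two "pure", one admixed) are modelled under eight
histories: (1) a trichotomy at `ta`; (2–5) the four hierarchical orderings
in which one group merges into another at `t1` and the remainder join at
`ta`; (6) isolation-with-admixture — the admixed group formed at `t1` as a
mixture (fraction `r` from group 1) of the two pure groups, which merge at
`ta`; (7–8) admixture of a sampled group with an unsampled "ghost" lineage.
Backward in time every merge is a total lineage movement and admixture is a
probabilistic one; event times are generations, strictly increasing toward
the past (`t1 < ta`), with the root population dropping to the ancestral
size `NA` at the final event.

Ancestry is simulated per locus with msprime (continuous-time coalescent;
fast and accurate for `N ≫ n`). Mutations follow a generalized stepwise
model: counts Poisson in branch length, step size geometric with parameter
`P` (`P = 0` is the strict SMM), implemented with msprime's microsatellite
matrix models (the two-phase model with a vanishing single-step phase and
geometric success `1 − P` has exactly the geometric step law). Alleles live
on 40 contiguous repeat states with reflecting bounds; the root allele is
the central state. Per-locus rates are Gamma-distributed around the mean
rate (shape 2 by default). Simulator correctness is pinned to closed forms
in the test suite: mean pairwise coalescence time `2N`, and SMM equilibrium
heterozygosity `1 − 1/√(1 + 8Nμ)` (the unbiased estimator is required at
modest sample sizes; the bounded allele range costs at most ~0.01 of He at
the tested `8Nμ = 4`).

### Priors

Default priors are uniform: `N1, N2, N3 ~ U(10², 10⁵)`,
`NA, N4 ~ U(10, 10⁴)`, `ta ~ U(10³, 10⁵)`, `t1 ~ U(10, 10⁴)` with `t1 < ta`
by rejection, `r ~ U(0.05, 0.95)`, mean mutation rate `U(10⁻⁴, 10⁻³)`, GSM
`P ~ U(0.1, 0.3)`. These are explicit reconstructions of a plausible
full-scale design (the upper population-size bound is implied by posterior
mass accumulating near 10⁵ in the regime this emulates), all overridable.

### Summary statistics and ABC

Per group: mean allele number, mean unbiased gene diversity, mean
allele-size variance, mean Garza's M; per group pair: Weir–Cockerham FST,
`(δμ)²`, and pooled allele number — the standard one- and two-sample
microsatellite set. The reference table stores scenario id, parameter draws
and statistics per simulation, with row seeds derived deterministically from
`(seed, scenario, row)` so tables are reproducible and resumable.

Model choice standardizes statistics by the reference spread, accepts the
nearest Euclidean fraction, reports direct posterior probabilities
(scenario frequencies among accepted) and a multinomial-logistic smoothed
estimate evaluated at the observed vector with a binomial-approximation 95%
CI. **Accepted-count rule:** the rejection fraction should be chosen so the
accepted set holds a few hundred simulations — at full scale (10⁵ per
scenario) the classical 1% rule gives thousands of accepted rows, but at
desk scale (5×10³ per scenario) 1% leaves too few rows for a stable
logistic fit, so desk-scale analyses here use ~300 accepted rows. Parameter
posteriors use Beaumont local-linear regression with Epanechnikov weights on
logit-transformed parameters (so adjusted draws cannot leave their prior
bounds) and weighted quantiles for the median and 90% CI; a singular
regression falls back to the unadjusted rejection posterior. Validation
simulates pseudo-observed datasets with known truth for type I/II error of
model choice and the per-parameter relative median absolute error; the
selector and estimator are injectable so the validation harness can itself
be validated against an oracle. A PCA model check projects observed and
posterior-predictive statistics into the reference cloud and flags an
observation outside the 99% hull of the predictive points. Generations
convert to years with an 80-year default generation time.

## Landscape analyses

Geographic distance is Euclidean-on-degrees by default (matching the
"Euclidean method" convention of the matrix-comparison software this
mirrors) with great-circle kilometres (haversine, mean Earth radius
6371.0088 km) as the option used for PCNM construction. Climatic distance is
Euclidean on z-scored values of the six bioclimatic variables (BIO1, BIO4,
BIO11, BIO12, BIO15, BIO17); without standardization annual precipitation
dominates by sheer unit size, which is the documented motivation for the
default. Mantel tests correlate off-diagonal entries with significance from
simultaneous row/column permutations (999 by default, two-tailed, seeded);
the partial Mantel residualizes both matrices on the control and permutes
the residualized first matrix (the Legendre scheme — permutation
conventions differ across software, so the choice is stated). Calibration
of the permutation null is part of the test suite.

PCNM eigenvectors come from principal coordinates of the geographic distance
matrix with entries beyond a truncation threshold (default: longest
minimum-spanning-tree edge) replaced by four times the threshold; unit-norm
vectors with positive eigenvalues are returned and match `vegan::pcnm` to
seven digits on a reference transect. The RDA response is the population ×
allele frequency table with one (globally most frequent) allele dropped per
locus and the remainder ranked by global frequency down to the target column
count (~200 at full scale). Predictors are six forward-selected PCNMs
(permutation α = 0.05) and the six z-scored climate variables — equal block
sizes by design to avoid biasing the comparison. Variance partitioning uses
Ezekiel-adjusted R²: pure climate = adjR²(full) − adjR²(geo), pure
geography = adjR²(full) − adjR²(clim), joint = adjR²(clim) + adjR²(geo) −
adjR²(full); slightly negative fractions are reported as computed (an
adjusted-R² artifact, expected under collinearity). Block significance uses
permutation F-tests on the residualized response.

## Niche analyses

The standard PCA is a correlation-matrix PCA of site climates with signs
fixed (largest loading positive). PCA-env calibrates the PCA on the pooled
available environment: each group's background is a regular grid of points
inside the minimum convex polygon of its sites buffered by 0.3°, with
climate attached from a climate surface (a raster adapter is deliberately
out of scope; synthetic linear surfaces stand in at desk scale). Occurrences
and backgrounds are projected onto the first two axes, smoothed by Gaussian
kernels (Silverman-style bandwidth, 100×100 grid spanning the pooled
background), and corrected for availability:
`z = (o/max o)/(e/max e)` where background density is positive, else 0
(a raw-density mode exists because published scripts vary on this point).
Schoener's `D = 1 − ½ Σ|p_A − p_B|` on normalized occupancy ranges from 0
(disjoint niches) to 1 (identical). Density contours at 20% and 100% are the
smallest cell sets holding those fractions of total density, so the core is
always nested in the support.

## Synthetic studies

`synthetic.generate_study` emulates the target sampling design: 29
populations of 6–21 diploids at 17 loci, organized as 5 + 6 + 18 populations
in groups 1/2/3, each population budding off its group 10 generations back
(so among-population-within-group variance is small but nonzero). The
default truth is scenario 6 with the full-scale posterior regime scaled down
~30× in effective sizes and proportionally in event times
(`N1, N2, N3, NA = 2610, 2063, 2950, 104`; `ta = 1663`, `t1 = 22`,
`r = 0.449`): coalescent observables depend on `t/N` and `Nμ`, so
divergence structure is preserved while a study simulates in tens of
milliseconds. Sites cluster west/center/east with the admixed group in the
contact zone; climate is linear in latitude/longitude with WorldClim-like
magnitudes plus configurable correlated noise, so isolation by distance and
by environment hold by construction. True ancestry is emitted with the
genotypes: pure groups at `q = 1` minus half-normal noise, the admixed group
centred on `r`.

What the generator does **not** emulate — genotyping error, null alleles,
linkage, within-group migration–drift equilibrium, real WorldClim rasters —
bounds what passing tests show: they certify the estimators and the
inference machinery on data with known truth, not the field properties of
any particular empirical dataset.

## Problem sizes in the shipped tests

The test suite runs the full machinery at desk scale as its own design
choice: ABC self-classification uses 700 simulations per scenario on two
strongly divergent scenarios; scenario recovery uses 5,000 simulations per
scenario against 20 independently generated studies subsampled to 15
diploids per group (accepted set ~300); the Mantel calibration uses 200
null trials at 999 permutations; coalescent closed forms use 200 loci / 4,000
replicates. Full-scale analyses (10⁵ simulations per scenario, 500 pods)
run through exactly the same entry points by changing the counts.

## Known limitations

- The logistic-regression CI is a binomial normal approximation, not the
  (unpublished) exact construction of the reference software.
- Great-circle distances use the spherical haversine formula, not an
  ellipsoid geodesic (≲0.3% error, well inside every analysis tolerance).
- Whether field alleles are recorded as fragment sizes or repeat counts is
  dataset-dependent; both encodings are supported and conversion happens on
  demand (`(size − offset)/repeat_unit`), defaulting to offset 0.
- AMOVA reports copy-level degrees of freedom from the individual counts;
  loci untyped in some individuals shift per-locus sample sizes, which is
  absorbed by the typed-locus rescaling of pair distances, not by per-locus
  degrees of freedom.
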