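# msatpop

Population-genetic and landscape-genetic analysis of co-dominant
microsatellite (SSR) data, built for range-wide studies of structured plant
species — the motivating case is a survey of the subtropical Chinese oak
*Quercus fabri*: 490 individuals from 29 populations genotyped at 17 nuclear
SSR loci, organized as two diverged regional gene pools plus an admixed
contact-zone group. The package covers the full analysis arc of such a
study:

- **Diversity and differentiation** — per-population `Na`, `Ne`, Shannon
  `I`, `Ho`, `He` (Nei), `PPL`, Weir–Cockerham `FIS`; per-locus `H_S`/`H_T`
  and PIC; pairwise Weir–Cockerham `F_ST`; hierarchical AMOVA on squared
  repeat-count distances with R-statistics
  (`R_CT`, `R_SC`, `R_ST`) and permutation tests; PCoA; IDW diversity
  surfaces; diversity–geography correlations.
- **Population partitioning** — Evanno `ΔK`; genetically pure individuals
  (`q ≥ 0.9`), per-population proportion of pure individuals (`Qp`), and
  the two-pure-groups-plus-admixed partition (`Qp ≥ 0.8`, boundary
  inclusive).
- **Demographic inference** — coalescent simulation (msprime) of
  microsatellite data under eight competing histories (trichotomy,
  hierarchical divergences, isolation-with-admixture, ghost-lineage
  admixture) with a generalized stepwise mutation model, and DIYABC-style
  ABC: rejection + multinomial-logistic model choice, Beaumont
  local-linear parameter posteriors, pods-based type I/II error and RMAE,
  PCA model checking, generation-time scaling of event times.
- **Isolation by distance vs environment** — seeded Mantel and partial
  Mantel tests; PCNM spatial eigenvectors; RDA / partial RDA
  variance partitioning of ~200 allele frequencies into pure-climate,
  pure-geography and joint fractions.
- **Niche overlap** — correlation-matrix PCA of site climates; PCA-env
  kernel-density occupancy grids over buffered convex-polygon backgrounds;
  Schoener's `D`.
- **Synthetic studies** — a first-class generator producing complete
  studies (genotypes, coordinates, climates, true ancestry) under the
  isolation-with-admixture demography, so every stage is testable with
  known truth and no downloads.

The printed 29-population diversity table of the motivating study ships as
a packaged fixture (`msatpop.io.load_table1_fixture`).

## Worked example

Recompute the headline statistics from the packaged per-population table:

```python
import pandas as pd
from msatpop.io import load_table1_fixture
from msatpop.popgen import diversity_coordinate_correlation
from msatpop.partition import partition_populations
from msatpop.abc import generations_to_years, format_age

div, sites, qp = load_table1_fixture()
print(diversity_coordinate_correlation(div, sites).to_string(index=False))
part = partition_populations(qp, pd.Series(1, index=qp.index))
print("admixed populations:", ", ".join(part.admixed))
print("ta:", format_age(generations_to_years(4.99e4)),
      " t1:", format_age(generations_to_years(6.72e2)))
```

prints

```
statistic      axis         R        p  undefined
       Ho  latitude -0.375010 0.045018      False
       Ho longitude -0.236225 0.217313      False
       He  latitude -0.008860 0.963619      False
       He longitude -0.264302 0.165904      False
admixed populations: BJ, LL, GY, XY, WY, JY
ta: 3.99 Ma  t1: 53.76 ka
```

Observed heterozygosity declines significantly with latitude (R = −0.375,
p = 0.045) while the other three diversity–coordinate associations are not
significant; the `Qp ≥ 0.8` rule isolates exactly six admixed contact-zone
populations; and at an 80-year generation time the inferred divergence and
admixture events date to 3.99 Ma and 53.76 ka.

The same machinery runs end-to-end on synthetic data with known truth:

```python
from msatpop.synthetic import generate_study, StudyConfig
from msatpop import popgen

cfg = StudyConfig(n_pops_per_group=(2, 2, 2), n_loci=10)
gm, sites, qm, truth = generate_study(seed=1, config=cfg)
res = popgen.amova(gm, groups=truth.group_of_pop, n_perm=199, seed=1)
print(res.strata.round(2).to_string())
for k, v in res.statistics.items():
    print(f"{k} = {v:.3f} (p = {res.p_values[k]:.3f})")
```

```
                                  df       SS  variance  percent
among_groups                       2   119.51      0.94     5.53
among_populations_within_groups    3    38.85     -0.12    -0.73
within_populations               154  2498.41     16.22    95.19
R_CT = 0.055 (p = 0.075)
R_SC = -0.008 (p = 0.695)
R_ST = 0.048 (p = 0.005)
```

Most variance sits within populations, the among-groups component reflects
the two diverged gene pools, and the slightly negative within-group
component is the usual signature of no structure below the group level.
Percentages always sum to 100.

A thin CLI wraps the library for shell use:

```sh
msatpop generate-study --scale desk --seed 1 --out study/
msatpop diversity study/study_genalex.csv
msatpop amova study/study_genalex.csv --n-perm 999 --seed 1
msatpop mantel geo.tsv fst.tsv --n-perm 999 --seed 1
msatpop reftable --scenarios 1,3,6 --n-per-scenario 5000 --out ref.tsv
msatpop abc-choose ref.tsv observed_stats.tsv
msatpop niche-overlap study/study_sites.tsv groups.tsv
```

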