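"""Synthetic microsatellite studies with known truth.

``generate_study`` emulates the sampling design the pipeline targets: 29
populations of 6-21 diploid individuals genotyped at 17 loci, organized as
two geographically and genetically diverged "pure" groups plus an admixed
contact-zone group formed by recent mixing of the two (the
isolation-with-admixture history, scenario 6).  Each population is a recent
subdivision of its group, so among-population-within-group variance is small
but nonzero.  Site coordinates place the groups west / center / east;
climate follows configurable linear latitude/longitude gradients plus noise,
so isolation by distance and by environment both hold by construction.
True individual ancestry coefficients are emitted alongside the genotypes.

Default demographic truth scales the full-size posterior regime down by
about 30x in effective sizes with event times rescaled proportionally:
coalescent-scale quantities depend on t/N and N*mu, so the diversity and
divergence regime is preserved while simulation stays fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .demography import MutationModel, Scenario, scenario_library, \
    simulate_from_demography
from .io import (CLIMATE_COLUMNS, GenotypeMatrix, QMatrix, validate_site_table,
                 write_genalex, write_qmatrix, write_site_table,
                 write_structure_format)

__all__ = [
    "StudyConfig",
    "StudyTruth",
    "ClimateModel",
    "generate_study",
    "generate_climate",
    "end_to_end_fixture",
    "DESK_TRUTH",
]

#: Desk-scale truth: full-scale posterior medians (N1, N2, N3 of order 1e4-1e5,
#: ancestral size 3.1e3, divergence 5e4 and admixture 6.7e2 generations) divided
#: by ~30, with the admixture fraction from group 1 r = 0.449.
DESK_TRUTH = {
    "N1": 2610.0, "N2": 2063.0, "N3": 2950.0, "NA": 104.0,
    "ta": 1663.0, "t1": 22.0, "r": 0.449,
}


@dataclass
class ClimateModel:
    """Linear climate surfaces: value = intercept + a*(lat - lat0) +
    b*(lon - lon0) + correlated Gaussian noise."""

    lat0: float = 29.0
    lon0: float = 112.0
    # variable -> (intercept, lat_coef, lon_coef, noise_sd), WorldClim-like units
    coefficients: dict = field(default_factory=lambda: {
        "BIO1": (16.0, -0.8, -0.10, 0.3),    # annual mean temperature, deg C
        "BIO4": (800.0, 15.0, -2.0, 15.0),   # temperature seasonality
        "BIO11": (4.0, -1.0, 0.15, 0.4),     # coldest-quarter temperature
        "BIO12": (1300.0, -40.0, 25.0, 40.0),  # annual precipitation, mm
        "BIO15": (60.0, 1.5, -1.0, 2.0),     # precipitation seasonality
        "BIO17": (90.0, -8.0, 6.0, 5.0),     # driest-quarter precipitation, mm
    })
    noise_correlation: np.ndarray | None = None
    temperature_times_ten: bool = False      # WorldClim v1 integer convention

    def surface(self, lat, lon, rng: np.random.Generator) -> dict:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        names = list(self.coefficients)
        sds = np.array([self.coefficients[v][3] for v in names])
        R = self.noise_correlation
        if R is None:
            R = np.eye(len(names))
        cov = np.outer(sds, sds) * np.asarray(R)
        if np.allclose(cov, 0):
            noise = np.zeros((lat.shape[0], len(names)))
        else:
            noise = rng.multivariate_normal(np.zeros(len(names)), cov,
                                            size=lat.shape[0], method="svd")
        out = {}
        for j, v in enumerate(names):
            c0, alat, alon, _ = self.coefficients[v]
            vals = c0 + alat * (lat - self.lat0) + alon * (lon - self.lon0) \
                + noise[:, j]
            if self.temperature_times_ten and v in ("BIO1", "BIO11"):
                vals = vals * 10.0
            out[v] = vals
        return out


def generate_climate(sites: pd.DataFrame, model: ClimateModel | None = None,
                     seed: int | None = None) -> pd.DataFrame:
    """Attach the six bioclimatic columns to a lat/lon site table."""
    model = model or ClimateModel()
    rng = np.random.default_rng(seed)
    clim = model.surface(sites["lat"].to_numpy(), sites["lon"].to_numpy(), rng)
    out = sites.copy()
    for v in CLIMATE_COLUMNS:
        out[v] = clim[v]
    return validate_site_table(out)


@dataclass
class StudyConfig:
    scenario_id: int = 6
    params: dict = field(default_factory=lambda: dict(DESK_TRUTH))
    n_pops_per_group: tuple[int, int, int] = (5, 6, 18)  # group 1, 2, 3
    size_range: tuple[int, int] = (6, 21)
    n_loci: int = 17
    pop_split_time: float = 10.0   # each population buds off its group here
    mutation: MutationModel = field(default_factory=MutationModel)
    q_noise: float = 0.03          # ancestry noise for pure-group individuals
    admixed_q_sd: float = 0.08     # spread of admixed-group ancestry around r
    group_centers: dict = field(default_factory=lambda: {
        "G1": (29.0, 104.5), "G2": (28.5, 109.5), "G3": (29.5, 116.5)})
    coord_jitter: tuple[float, float] = (2.0, 1.6)  # lat, lon spread
    climate: ClimateModel = field(default_factory=ClimateModel)

    def validate(self):
        if self.pop_split_time >= self.params.get("t1", np.inf):
            raise ValueError("pop_split_time must predate (be below) t1")
        for k, v in self.params.items():
            if k != "r" and v <= 0:
                raise ValueError(f"parameter {k} must be positive")
        if not 0 < self.params.get("r", 0.5) < 1:
            raise ValueError("admixture rate r must be in (0, 1)")


@dataclass
class StudyTruth:
    scenario_id: int
    params: dict
    group_of_pop: dict
    pop_sizes: dict
    q_true: np.ndarray
    seed: int

    def manifest(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "params": self.params,
            "group_of_pop": self.group_of_pop,
            "pop_sizes": self.pop_sizes,
            "seed": self.seed,
        }


def _study_demography(sc: Scenario, cfg: StudyConfig,
                      pop_group: dict[str, str]) -> msprime.Demography:
    params = cfg.params
    dem = msprime.Demography()
    for pop, g in pop_group.items():
        dem.add_population(name=pop, initial_size=params[f"N{g[1:]}"])
    for g in sc.groups:
        dem.add_population(name=f"G{g}", initial_size=params[f"N{g}"])
    for pop, g in pop_group.items():
        dem.add_mass_migration(time=cfg.pop_split_time, source=pop,
                               dest=g, proportion=1.0)
    for ev in sc.events:
        t = params[ev.time]
        if hasattr(ev, "sources"):
            dem.add_mass_migration(time=t, source=f"G{ev.target}",
                                   dest=f"G{ev.sources[0]}",
                                   proportion=params[ev.rate])
            dem.add_mass_migration(time=t, source=f"G{ev.target}",
                                   dest=f"G{ev.sources[1]}", proportion=1.0)
        else:
            for d in ev.derived:
                dem.add_mass_migration(time=t, source=f"G{d}",
                                       dest=f"G{ev.ancestral}", proportion=1.0)
    dem.add_population_parameters_change(
        time=params[sc.events[-1].time], population=f"G{sc.root_group}",
        initial_size=params["NA"])
    dem.sort_events()
    return dem


def generate_study(seed: int = 1, config: StudyConfig | None = None):
    """Generate a complete synthetic study.

    Returns ``(genotypes, sites, qmatrix, truth)``; identical seeds give
    identical outputs.
    """
    cfg = config or StudyConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    sc = {s.id: s for s in scenario_library()}[cfg.scenario_id]

    n1, n2, n3 = cfg.n_pops_per_group
    pops = [f"P{i + 1:02d}" for i in range(n1 + n2 + n3)]
    groups = ["G1"] * n1 + ["G2"] * n2 + ["G3"] * n3
    pop_group = dict(zip(pops, groups))
    lo, hi = cfg.size_range
    sizes = {p: int(rng.integers(lo, hi + 1)) for p in pops}

    dem = _study_demography(sc, cfg, pop_group)
    gm = simulate_from_demography(
        dem, sizes, cfg.n_loci, cfg.mutation,
        seed=int(rng.integers(1, 2**31 - 1)))

    # --- geography: regional clusters, admixed group in between -----------
    jlat, jlon = cfg.coord_jitter
    lat = np.empty(len(pops))
    lon = np.empty(len(pops))
    for i, p in enumerate(pops):
        cla, clo = cfg.group_centers[pop_group[p]]
        lat[i] = np.clip(cla + rng.normal(0, jlat / 2), -90, 90)
        lon[i] = np.clip(clo + rng.normal(0, jlon), -180, 180)
    sites = pd.DataFrame({"lat": lat, "lon": lon}, index=pd.Index(pops, name="pop"))
    sites = generate_climate(sites, cfg.climate,
                             seed=int(rng.integers(1, 2**31 - 1)))

    # --- true ancestry ------------------------------------------------------
    r = cfg.params["r"]
    q1 = np.empty(gm.n_individuals)
    for i, p in enumerate(gm.populations):
        g = pop_group[p]
        if g == "G1":
            q1[i] = 1.0 - abs(rng.normal(0, cfg.q_noise))
        elif g == "G3":
            q1[i] = abs(rng.normal(0, cfg.q_noise))
        else:
            q1[i] = rng.normal(r, cfg.admixed_q_sd)
    q1 = np.clip(q1, 0.0, 1.0)
    qm = QMatrix(gm.individuals, gm.populations,
                 np.column_stack([q1, 1.0 - q1]))

    truth = StudyTruth(cfg.scenario_id, dict(cfg.params), pop_group,
                       sizes, qm.q.copy(), seed)
    return gm, sites, qm, truth


def end_to_end_fixture(scale: str = "smoke", out_dir=None, seed: int = 1):
    """Write a complete study in every supported input format plus a JSON
    manifest of the generating truth.

    ``scale='smoke'``: 3 populations, 5 loci; ``'desk'``: the full 29 x 17
    default.  Returns ``(paths, manifest)``.
    """
    if scale == "smoke":
        cfg = StudyConfig(n_pops_per_group=(1, 1, 1), n_loci=5)
    elif scale == "desk":
        cfg = StudyConfig()
    else:
        raise ValueError("scale must be 'smoke' or 'desk'")
    gm, sites, qm, truth = generate_study(seed=seed, config=cfg)
    out_dir = Path(out_dir or ".")
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genalex": out_dir / "study_genalex.csv",
        "structure": out_dir / "study_structure.txt",
        "sites": out_dir / "study_sites.tsv",
        "qmatrix": out_dir / "study_q.tsv",
        "manifest": out_dir / "study_manifest.json",
    }
    write_genalex(gm, paths["genalex"])
    write_structure_format(gm, paths["structure"])
    write_site_table(sites, paths["sites"])
    write_qmatrix(qm, paths["qmatrix"])
    manifest = truth.manifest()
    manifest["scale"] = scale
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1)
    return paths, manifest
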