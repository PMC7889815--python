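"""Coalescent simulation of microsatellite data under competing demographies.

Three sampled population groups (an admixed group flanked by two diverged
"pure" groups) are modelled under eight alternative histories: a trichotomy,
four hierarchical-divergence orderings, isolation-with-admixture (the
admixed group formed by mixing of the two pure groups), and two variants in
which the admixed group draws ancestry from an unsampled "ghost" lineage.
Each locus evolves on an independent coalescent genealogy (simulated with
msprime) under a generalized stepwise mutation model: mutation count
Poisson in branch length, step size geometric with parameter P (P = 0 is the
strict stepwise model), repeat number reflected inside a bounded contiguous
allele range.

Backward in time a merge of group B into group A is a lineage movement
B -> A; an admixture of target T from sources (S1, S2) with rate r moves
each T lineage to S1 with probability r, else to S2.  Event times are in
generations and must increase toward the past (t1 < ta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .io import GenotypeMatrix, Locus

__all__ = [
    "PriorSpec",
    "DEFAULT_PRIORS",
    "MutationModel",
    "Split",
    "Admixture",
    "Scenario",
    "scenario_library",
    "draw_parameters",
    "simulate_msat_dataset",
    "simulate_from_demography",
    "summary_statistics",
    "build_reference_table",
]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Independent uniform priors with the ordering constraint t1 < ta.

    ``bounds`` maps parameter name to (low, high); draws violating a
    constraint are rejected and redrawn.
    """

    bounds: dict[str, tuple[float, float]]
    max_rejections: int = 10_000

    def __post_init__(self):
        for k, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"prior {k}: need finite lo < hi, got {lo},{hi}")

    def draw(self, rng: np.random.Generator,
             names: tuple[str, ...] | None = None) -> dict[str, float]:
        names = names or tuple(self.bounds)
        for _ in range(self.max_rejections):
            params = {k: rng.uniform(*self.bounds[k]) for k in names}
            if "t1" in params and "ta" in params and not params["t1"] < params["ta"]:
                continue
            return params
        raise RuntimeError("prior constraints unsatisfiable within rejection budget")


#: Reconstructed default priors (documented reconstructions, overridable).
DEFAULT_PRIORS = PriorSpec({
    "N1": (1e2, 1e5),
    "N2": (1e2, 1e5),
    "N3": (1e2, 1e5),
    "N4": (10, 1e4),
    "NA": (10, 1e4),
    "ta": (1e3, 1e5),
    "t1": (10, 1e4),
    "r": (0.05, 0.95),
    "mu_mean": (1e-4, 1e-3),
    "gsm_p": (0.1, 0.3),
})


def draw_parameters(priors: PriorSpec, seed=None,
                    names: tuple[str, ...] | None = None) -> dict[str, float]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return priors.draw(rng, names)


# ---------------------------------------------------------------------------
# Mutation model
# ---------------------------------------------------------------------------

@dataclass
class MutationModel:
    """Generalized stepwise model with per-locus rate heterogeneity.

    Mean rate ``mu_mean`` per locus per generation; per-locus rates drawn
    from a Gamma with that mean and shape ``gamma_shape`` (None = constant).
    Step sizes are geometric with parameter ``gsm_p`` in [0, 1): step k has
    probability (1 - P) P^(k-1); P = 0 reduces to the strict SMM.  Alleles
    live on ``n_states`` contiguous repeat counts with reflecting bounds.
    """

    mu_mean: float = 5e-4
    gsm_p: float = 0.22
    gamma_shape: float | None = 2.0
    n_states: int = 40
    lo: int = 1

    def __post_init__(self):
        if self.mu_mean <= 0:
            raise ValueError("mu_mean must be positive")
        if not 0 <= self.gsm_p < 1:
            raise ValueError("gsm_p must be in [0, 1)")

    @property
    def hi(self) -> int:
        return self.lo + self.n_states - 1

    @property
    def root_state(self) -> int:
        return self.lo + self.n_states // 2

    def locus_rates(self, n_loci: int, rng: np.random.Generator) -> np.ndarray:
        if self.gamma_shape is None:
            return np.full(n_loci, self.mu_mean)
        scale = self.mu_mean / self.gamma_shape
        return rng.gamma(self.gamma_shape, scale, size=n_loci)

    def msprime_model(self):
        root = np.zeros(self.n_states)
        root[self.n_states // 2] = 1.0
        if self.gsm_p == 0:
            return msprime.SMM(lo=self.lo, hi=self.hi, root_distribution=root)
        # geometric steps: TPM with vanishing single-step phase and
        # success probability 1 - P reproduces P(step=k) = (1-P) P^(k-1)
        return msprime.TPM(p=1e-12, m=1.0 - self.gsm_p,
                           lo=self.lo, hi=self.hi, root_distribution=root)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    """Backward-time merge of ``derived`` groups into ``ancestral``."""

    time: str
    derived: tuple[int, ...]
    ancestral: int


@dataclass(frozen=True)
class Admixture:
    """Backward-time admixture: ``target`` lineages move to ``sources[0]``
    with probability given by the ``rate`` parameter, else ``sources[1]``."""

    time: str
    target: int
    sources: tuple[int, int]
    rate: str = "r"


@dataclass(frozen=True)
class Scenario:
    id: int
    name: str
    events: tuple
    has_ghost: bool = False

    @property
    def groups(self) -> tuple[int, ...]:
        return (1, 2, 3, 4) if self.has_ghost else (1, 2, 3)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["N1", "N2", "N3"]
        if self.has_ghost:
            names.append("N4")
        names.append("NA")
        names += sorted({e.time for e in self.events},
                        key=lambda s: {"t1": 0, "ta": 1}[s])
        if any(isinstance(e, Admixture) for e in self.events):
            names.append("r")
        return tuple(names)

    @property
    def root_group(self) -> int:
        return self.events[-1].ancestral

    def validate(self, params: dict[str, float]) -> None:
        for k in self.param_names:
            if k not in params:
                raise ValueError(f"scenario {self.id}: missing parameter {k}")
        for g in self.groups:
            if params[f"N{g}"] <= 0:
                raise ValueError(f"scenario {self.id}: N{g} must be positive")
        if params["NA"] <= 0:
            raise ValueError("NA must be positive")
        times = [params[e.time] for e in self.events]
        if any(t <= 0 for t in times):
            raise ValueError("event times must be positive")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"scenario {self.id}: event times must strictly increase "
                "toward the past (t1 < ta)"
            )
        if "r" in self.param_names and not 0 < params["r"] < 1:
            raise ValueError("admixture rate r must be in (0, 1)")

    def demography(self, params: dict[str, float]) -> msprime.Demography:
        self.validate(params)
        dem = msprime.Demography()
        for g in self.groups:
            dem.add_population(name=f"G{g}", initial_size=params[f"N{g}"])
        for ev in self.events:
            t = params[ev.time]
            if isinstance(ev, Admixture):
                r = params[ev.rate]
                dem.add_mass_migration(time=t, source=f"G{ev.target}",
                                       dest=f"G{ev.sources[0]}", proportion=r)
                dem.add_mass_migration(time=t, source=f"G{ev.target}",
                                       dest=f"G{ev.sources[1]}", proportion=1.0)
            else:
                for d in ev.derived:
                    dem.add_mass_migration(time=t, source=f"G{d}",
                                           dest=f"G{ev.ancestral}", proportion=1.0)
        dem.add_population_parameters_change(
            time=params[self.events[-1].time],
            population=f"G{self.root_group}",
            initial_size=params["NA"],
        )
        dem.sort_events()
        return dem


def scenario_library() -> list[Scenario]:
    """The eight competing demographic histories for the three groups."""
    return [
        Scenario(1, "trichotomy at ta",
                 (Split("ta", (2, 3), 1),)),
        Scenario(2, "2 into 1 at t1, 3 into 1 at ta",
                 (Split("t1", (2,), 1), Split("ta", (3,), 1))),
        Scenario(3, "2 into 3 at t1, 3 into 1 at ta",
                 (Split("t1", (2,), 3), Split("ta", (3,), 1))),
        Scenario(4, "1 into 2 at t1, 3 into 2 at ta",
                 (Split("t1", (1,), 2), Split("ta", (3,), 2))),
        Scenario(5, "3 into 2 at t1, 1 into 2 at ta",
                 (Split("t1", (3,), 2), Split("ta", (1,), 2))),
        Scenario(6, "2 admixed from 1 and 3 at t1, 3 into 1 at ta",
                 (Admixture("t1", 2, (1, 3)), Split("ta", (3,), 1))),
        Scenario(7, "2 admixed from 1 and ghost 4 at t1",
                 (Admixture("t1", 2, (1, 4)), Split("ta", (3, 4), 1)),
                 has_ghost=True),
        Scenario(8, "2 admixed from 3 and ghost 4 at t1",
                 (Admixture("t1", 2, (3, 4)), Split("ta", (3, 4), 1)),
                 has_ghost=True),
    ]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _genotypes_from_ts(mts, n_dip: int, root_state: int) -> np.ndarray:
    if mts.num_sites == 0:
        return np.full((n_dip, 2), root_state, dtype=np.int64)
    var = next(mts.variants())
    states = np.array([int(a) for a in var.alleles if a is not None])
    vals = states[var.genotypes]
    return vals.reshape(n_dip, 2)


def simulate_from_demography(
    dem: msprime.Demography,
    samples: dict[str, int],
    n_loci: int,
    mut: MutationModel,
    seed: int,
) -> GenotypeMatrix:
    """Simulate ``n_loci`` independent microsatellite loci on one demography.

    ``samples`` maps population name to diploid sample count.  Returns a
    genotype matrix with repeat-count alleles and populations in ``samples``
    order.
    """
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed0 = rng.integers(1, 2**31 - 1, size=2)
    rates = mut.locus_rates(n_loci, rng)
    model = mut.msprime_model()
    n_dip = sum(samples.values())
    reps = msprime.sim_ancestry(
        samples, demography=dem, sequence_length=1, discrete_genome=True,
        num_replicates=n_loci, random_seed=int(anc_seed),
    )
    calls = np.empty((n_dip, n_loci, 2), dtype=np.int64)
    for l, ts in enumerate(reps):
        mts = msprime.sim_mutations(ts, rate=rates[l], model=model,
                                    random_seed=int(mut_seed0) + l)
        calls[:, l, :] = _genotypes_from_ts(mts, n_dip, mut.root_state)
    pops, inds = [], []
    for name, k in samples.items():
        pops += [name] * k
        inds += [f"{name}_{i + 1}" for i in range(k)]
    loci = [Locus(f"L{l + 1}", allele_encoding="repeat_count")
            for l in range(n_loci)]
    return GenotypeMatrix(inds, np.array(pops, dtype=object), loci, calls)


def simulate_msat_dataset(
    scenario: Scenario,
    params: dict[str, float],
    samples: dict[int, int],
    n_loci: int,
    mut: MutationModel | None = None,
    seed: int = 1,
) -> GenotypeMatrix:
    """Simulate a dataset under one scenario.

    ``samples`` maps sampled group number (1..3) to diploid count; mutation
    parameters present in ``params`` (``mu_mean``, ``gsm_p``) override the
    ``mut`` defaults so that prior draws propagate.
    """
    mut = mut or MutationModel()
    if "mu_mean" in params or "gsm_p" in params:
        mut = MutationModel(
            mu_mean=params.get("mu_mean", mut.mu_mean),
            gsm_p=params.get("gsm_p", mut.gsm_p),
            gamma_shape=mut.gamma_shape,
            n_states=mut.n_states,
            lo=mut.lo,
        )
    dem = scenario.demography(params)
    named = {f"G{g}": n for g, n in samples.items()}
    return simulate_from_demography(dem, named, n_loci, mut, seed)


# ---------------------------------------------------------------------------
# Summary statistics (DIYABC-style one- and two-sample microsatellite set)
# ---------------------------------------------------------------------------

def _group_arrays(gm: GenotypeMatrix, group_of_pop: dict[str, str] | None):
    counts = gm.repeat_counts()  # n x L x 2 float, NaN missing
    if group_of_pop is None:
        labels = gm.populations
        order = gm.population_order
    else:
        labels = np.array([group_of_pop[p] for p in gm.populations], dtype=object)
        order = list(dict.fromkeys(group_of_pop[p] for p in gm.population_order))
    return counts, labels, order


def _theta_pair(x1: np.ndarray, x2: np.ndarray) -> float:
    """Weir-Cockerham theta over loci for two groups of (n, L, 2) counts."""
    a_s = b_s = c_s = 0.0
    L = x1.shape[1]
    for l in range(L):
        g1 = x1[:, l, :]
        g2 = x2[:, l, :]
        g1 = g1[~np.isnan(g1[:, 0])]
        g2 = g2[~np.isnan(g2[:, 0])]
        n1, n2 = len(g1), len(g2)
        if n1 == 0 or n2 == 0:
            continue
        alleles, inv = np.unique(np.concatenate([g1.ravel(), g2.ravel()]),
                                 return_inverse=True)
        k = len(alleles)
        if k < 2:
            continue
        inv1 = inv[:2 * n1].reshape(n1, 2)
        inv2 = inv[2 * n1:].reshape(n2, 2)
        P = np.empty((2, k))
        H = np.empty((2, k))
        for j, (gi, ni) in enumerate(((inv1, n1), (inv2, n2))):
            P[j] = np.bincount(gi.ravel(), minlength=k) / (2.0 * ni)
            het = gi[gi[:, 0] != gi[:, 1]]
            H[j] = np.bincount(het.ravel(), minlength=k) / float(ni)
        ns = np.array([n1, n2], dtype=float)
        r = 2
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        pbar = (ns[:, None] * P).sum(axis=0) / (r * nbar)
        s2 = (ns[:, None] * (P - pbar)**2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (ns[:, None] * H).sum(axis=0) / (r * nbar)
        a_c = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - hbar / 4) / (nbar - 1))
        b_c = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        a_s += a_c.sum()
        b_s += b_c.sum()
        c_s += (hbar / 2).sum()
    den = a_s + b_s + c_s
    return a_s / den if den != 0 else 0.0


def summary_statistics(gm: GenotypeMatrix,
                       group_of_pop: dict[str, str] | None = None) -> pd.Series:
    """Fixed-order summary-statistic vector over groups of populations.

    Per group: mean allele number, mean unbiased gene diversity, mean
    allele-size variance, mean Garza's M (Na / (size range + 1)).  Per group
    pair: Weir-Cockerham FST, (delta mu)^2 (squared difference of mean
    repeat counts, averaged over loci), and mean allele number of the pooled
    pair.  Monomorphic loci give M = 1 and variance 0.
    """
    counts, labels, order = _group_arrays(gm, group_of_pop)
    if len(order) < 2:
        raise ValueError("need >= 2 groups")
    L = gm.n_loci
    stats: dict[str, float] = {}
    per_group = {g: counts[labels == g] for g in order}
    for g in order:
        x = per_group[g]
        na, he, var, m = [], [], [], []
        for l in range(L):
            v = x[:, l, :].ravel()
            v = v[~np.isnan(v)]
            if len(v) == 0:
                continue
            alleles, cnt = np.unique(v, return_counts=True)
            k = len(alleles)
            na.append(k)
            n = len(v)
            p = cnt / n
            h = 1.0 - (p**2).sum()
            he.append(h * n / (n - 1) if n > 1 else 0.0)
            var.append(v.var(ddof=1) if n > 1 else 0.0)
            m.append(k / (alleles.max() - alleles.min() + 1.0))
        stats[f"na_{g}"] = float(np.mean(na)) if na else np.nan
        stats[f"he_{g}"] = float(np.mean(he)) if he else np.nan
        stats[f"var_{g}"] = float(np.mean(var)) if var else np.nan
        stats[f"m_{g}"] = float(np.mean(m)) if m else np.nan
    for i, g1 in enumerate(order):
        for g2 in order[i + 1:]:
            x1, x2 = per_group[g1], per_group[g2]
            stats[f"fst_{g1}_{g2}"] = _theta_pair(x1, x2)
            dmu, na2 = [], []
            for l in range(L):
                v1 = x1[:, l, :].ravel()
                v2 = x2[:, l, :].ravel()
                v1 = v1[~np.isnan(v1)]
                v2 = v2[~np.isnan(v2)]
                if len(v1) == 0 or len(v2) == 0:
                    continue
                dmu.append((v1.mean() - v2.mean()) ** 2)
                na2.append(len(np.unique(np.concatenate([v1, v2]))))
            stats[f"dmu2_{g1}_{g2}"] = float(np.mean(dmu)) if dmu else np.nan
            stats[f"na2_{g1}_{g2}"] = float(np.mean(na2)) if na2 else np.nan
    return pd.Series(stats)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

def build_reference_table(
    scenarios: list[Scenario],
    priors: PriorSpec,
    n_per_scenario: int,
    samples: dict[int, int],
    n_loci: int = 17,
    seed: int = 1,
    chunk_size: int = 1000,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate the ABC reference table: per row a scenario id, its drawn
    parameters, and the summary-statistic vector.

    Row seeds derive deterministically from ``(seed, scenario id, row
    index)``, so the table is reproducible and resumable chunk by chunk.
    Degenerate simulations (any undefined statistic) are redrawn with a
    perturbed seed; the redraw count is recorded in ``df.attrs``.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario >= 1 required")
    rows = []
    n_redrawn = 0
    for sc in scenarios:
        for i in range(n_per_scenario):
            for attempt in range(20):
                ss = np.random.SeedSequence([seed, sc.id, i, attempt])
                rng = np.random.default_rng(ss)
                params = priors.draw(rng, sc.param_names + ("mu_mean", "gsm_p"))
                gm = simulate_msat_dataset(
                    sc, params, samples, n_loci,
                    seed=int(rng.integers(1, 2**31 - 1)),
                )
                stats = summary_statistics(gm, None)
                if not stats.isna().any():
                    break
                n_redrawn += 1
            row = {"scenario": sc.id, **params, **stats.to_dict()}
            rows.append(row)
        if progress:
            print(f"scenario {sc.id}: {n_per_scenario} simulations done")
    df = pd.DataFrame(rows)
    df.attrs["n_redrawn"] = n_redrawn
    df.attrs["stat_columns"] = [c for c in df.columns
                                if c.split("_")[0] in
                                ("na", "he", "var", "m", "fst", "dmu2", "na2")]
    return df


def pairwise_coalescence_times(N: float, n_replicates: int,
                               seed: int = 1) -> np.ndarray:
    """Coalescence times (generations) of one diploid's two gene copies in a
    single panmictic population of size N — a diagnostic for the coalescent
    engine (expectation 2N)."""
    dem = msprime.Demography()
    dem.add_population(name="P", initial_size=N)
    reps = msprime.sim_ancestry({"P": 1}, demography=dem,
                                num_replicates=n_replicates, random_seed=seed)
    return np.array([ts.max_root_time for ts in reps])


def stat_columns(ref: pd.DataFrame) -> list[str]:
    """Summary-statistic columns of a reference table (schema is fixed)."""
    prefixes = ("na_", "he_", "var_", "m_", "fst_", "dmu2_", "na2_")
    return [c for c in ref.columns if c.startswith(prefixes)]
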