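"""Population-genetic summary statistics for microsatellite data.

Conventions follow the toolchains classically used for such data: expected
heterozygosity is Nei's gene diversity ``1 - sum(p^2)`` without small-sample
correction (GenAlEx), the inbreeding coefficient is Weir & Cockerham's (1984)
``f`` as a ratio of sums over alleles and loci (GENEPOP), pairwise
differentiation is Weir & Cockerham's ``theta``, and the hierarchical AMOVA
uses squared differences of repeat counts between gene copies, i.e. the
R-statistics (R_CT, R_SC, R_ST) appropriate for stepwise-mutating loci.
Because He and FIS come from different estimator families, ``FIS`` is *not*
``1 - Ho/He`` computed from the same table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import GenotypeMatrix

__all__ = [
    "allele_frequencies",
    "diversity_table",
    "pic",
    "hs_ht",
    "pairwise_fst",
    "PairwiseFst",
    "amova",
    "AmovaResult",
    "pcoa",
    "idw_surface",
    "diversity_coordinate_correlation",
]


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_counts(gm: GenotypeMatrix) -> list[pd.DataFrame]:
    """Per locus, a population x allele table of gene-copy counts."""
    pops = gm.population_order
    out = []
    for l in range(gm.n_loci):
        col = gm.calls[:, l, :]
        alleles = np.unique(col[col > 0])
        tab = pd.DataFrame(0, index=pops, columns=alleles, dtype=int)
        for p in pops:
            vals = col[gm.populations == p].ravel()
            vals = vals[vals > 0]
            a, c = np.unique(vals, return_counts=True)
            tab.loc[p, a] = c
        out.append(tab)
    return out


def allele_frequencies(gm: GenotypeMatrix, by: str = "population"):
    """Allele frequencies per locus.

    ``by='population'`` returns one population x allele frequency table per
    locus; rows with zero typed copies are all-NaN (undefined, flagged in the
    returned ``undefined`` list of ``(population, locus)`` pairs).
    ``by='total'`` pools all populations.
    """
    counts = allele_counts(gm)
    undefined: list[tuple[str, str]] = []
    freqs = []
    for l, tab in enumerate(counts):
        if by == "total":
            tot = tab.sum(axis=0).astype(float)
            n = tot.sum()
            if n == 0:
                undefined.append(("__total__", gm.loci[l].name))
                freqs.append(tot * np.nan)
            else:
                freqs.append(tot / n)
            continue
        n = tab.sum(axis=1).astype(float)
        f = tab.div(n.replace(0, np.nan), axis=0)
        for p in tab.index[n == 0]:
            undefined.append((p, gm.loci[l].name))
        freqs.append(f)
    if by not in ("population", "total"):
        raise ValueError("by must be 'population' or 'total'")
    return freqs, undefined


# ---------------------------------------------------------------------------
# Per-population diversity
# ---------------------------------------------------------------------------

def _wc_f_single_pop(tab_counts: pd.Series, het_counts: pd.Series, n: int):
    """Weir-Cockerham within-population components (b, c) for one population.

    ``tab_counts``: gene-copy counts per allele; ``het_counts``: number of
    individuals heterozygous for each allele; ``n``: typed diploids.
    Returns per-allele arrays (b, c); f = 1 - sum(c)/sum(b+c).
    """
    if n < 2:
        return None
    p = tab_counts / (2 * n)
    hbar = het_counts / n
    b = n / (n - 1.0) * (p * (1 - p) - (2 * n - 1.0) / (4.0 * n) * hbar)
    c = hbar / 2.0
    return b.to_numpy(float), c.to_numpy(float)


def diversity_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-population diversity: N, Na, Ne, I, Ho, He, PPL, FIS.

    Per-locus quantities are averaged over loci.  Ne = 1/sum(p^2),
    I = -sum(p ln p), He = 1 - sum(p^2) (Nei), PPL = percent of loci with at
    least two alleles, FIS = Weir-Cockerham f (ratio of sums over loci and
    alleles; NaN for single-individual populations).
    """
    counts = allele_counts(gm)
    pops = gm.population_order
    rows = {}
    for p in pops:
        in_pop = gm.populations == p
        n_ind = int(in_pop.sum())
        na, ne, ii, ho, he = [], [], [], [], []
        n_poly = 0
        f_num, f_den = 0.0, 0.0
        f_defined = False
        for l in range(gm.n_loci):
            cnt = counts[l].loc[p]
            tot = cnt.sum()
            if tot == 0:
                continue
            freq = cnt / tot
            pos = freq[freq > 0]
            na.append(len(pos))
            sp2 = float((pos**2).sum())
            ne.append(1.0 / sp2)
            ii.append(float(-(pos * np.log(pos)).sum()))
            he.append(1.0 - sp2)
            if len(pos) >= 2:
                n_poly += 1
            calls = gm.calls[in_pop, l, :]
            typed = calls[:, 0] > 0
            n_typed = int(typed.sum())
            if n_typed:
                het = calls[typed, 0] != calls[typed, 1]
                ho.append(float(het.mean()))
                het_counts = pd.Series(0, index=cnt.index, dtype=float)
                for a in cnt.index[cnt > 0]:
                    carries = (calls[typed] == a).any(axis=1)
                    het_counts[a] = float((carries & het).sum())
                bc = _wc_f_single_pop(cnt.astype(float), het_counts, n_typed)
                if bc is not None:
                    b, c = bc
                    f_num += c.sum()
                    f_den += (b + c).sum()
                    f_defined = True
        fis = 1.0 - f_num / f_den if f_defined and f_den > 0 else np.nan
        rows[p] = {
            "N": n_ind,
            "Na": float(np.mean(na)) if na else np.nan,
            "Ne": float(np.mean(ne)) if ne else np.nan,
            "I": float(np.mean(ii)) if ii else np.nan,
            "Ho": float(np.mean(ho)) if ho else np.nan,
            "He": float(np.mean(he)) if he else np.nan,
            "PPL": 100.0 * n_poly / gm.n_loci if gm.n_loci else np.nan,
            "FIS": fis,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[pops]


def pic(freqs) -> float:
    """Polymorphism information content: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    s2 = (p**2).sum()
    s4 = (p**4).sum()
    return float(1.0 - s2 - (s2**2 - s4))


def hs_ht(gm: GenotypeMatrix, weighted: bool = False) -> pd.DataFrame:
    """Per-locus within-population (H_S) and total (H_T) gene diversity.

    H_S is the mean over populations of Nei diversity; H_T is the diversity
    of the mean allele-frequency vector.  Populations enter unweighted by
    default (FSTAT convention); ``weighted=True`` weights by typed copies.
    """
    freqs, _ = allele_frequencies(gm)
    counts = allele_counts(gm)
    recs = []
    for l, f in enumerate(freqs):
        ok = f.dropna(how="all")
        if ok.empty:
            recs.append((gm.loci[l].name, np.nan, np.nan))
            continue
        hs = float((1.0 - (ok**2).sum(axis=1)).mean())
        if weighted:
            w = counts[l].loc[ok.index].sum(axis=1).to_numpy(float)
            pbar = (ok.to_numpy(float) * w[:, None]).sum(axis=0) / w.sum()
        else:
            pbar = ok.mean(axis=0).to_numpy(float)
        ht = float(1.0 - (pbar**2).sum())
        recs.append((gm.loci[l].name, hs, ht))
    return pd.DataFrame(recs, columns=["locus", "Hs", "Ht"]).set_index("locus")


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (pairwise FST)
# ---------------------------------------------------------------------------

def _wc_components(gm: GenotypeMatrix, pops: list[str]):
    """Per-locus, per-allele Weir-Cockerham (1984) a, b, c sums over ``pops``."""
    a_sum = b_sum = c_sum = 0.0
    any_locus = False
    r = len(pops)
    for l in range(gm.n_loci):
        ns, pmats, hmats = [], [], []
        alleles = np.unique(gm.calls[:, l, :][gm.calls[:, l, :] > 0])
        if len(alleles) == 0:
            continue
        for p in pops:
            calls = gm.calls[gm.populations == p, l, :]
            typed = calls[:, 0] > 0
            calls = calls[typed]
            n_i = len(calls)
            if n_i == 0:
                break
            flat = calls.ravel()
            pvec = np.array([(flat == a).mean() for a in alleles])
            het = calls[:, 0] != calls[:, 1]
            hvec = np.array([((calls == a).any(axis=1) & het).mean()
                             for a in alleles])
            ns.append(n_i)
            pmats.append(pvec)
            hmats.append(hvec)
        else:
            ns = np.array(ns, dtype=float)
            P = np.stack(pmats)      # pops x alleles
            H = np.stack(hmats)
            nbar = ns.mean()
            if nbar <= 1 or (ns <= 0).any():
                continue
            nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
            if nc <= 0:
                continue
            pbar = (ns[:, None] * P).sum(axis=0) / (r * nbar)
            s2 = (ns[:, None] * (P - pbar)**2).sum(axis=0) / ((r - 1) * nbar)
            hbar = (ns[:, None] * H).sum(axis=0) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            a_sum += a.sum()
            b_sum += b.sum()
            c_sum += c.sum()
            any_locus = True
    return (a_sum, b_sum, c_sum) if any_locus else None


def wc_theta(gm: GenotypeMatrix, pops: list[str] | None = None) -> float:
    """Multi-locus Weir-Cockerham theta over the given populations."""
    pops = pops or gm.population_order
    comp = _wc_components(gm, pops)
    if comp is None:
        return np.nan
    a, b, c = comp
    den = a + b + c
    return a / den if den != 0 else np.nan


@dataclass
class PairwiseFst:
    """Pairwise theta: ``raw`` keeps negative estimates; ``distance`` clamps
    them to zero for use as a genetic distance."""

    raw: pd.DataFrame
    undefined: list[tuple[str, str]]

    @property
    def distance(self) -> pd.DataFrame:
        d = self.raw.clip(lower=0.0)
        np.fill_diagonal(d.values, 0.0)
        return d


def pairwise_fst(gm: GenotypeMatrix) -> PairwiseFst:
    pops = gm.population_order
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    undefined = []
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            th = wc_theta(gm, [p1, p2])
            if np.isnan(th):
                undefined.append((p1, p2))
            mat.loc[p1, p2] = mat.loc[p2, p1] = th
    return PairwiseFst(mat, undefined)


# ---------------------------------------------------------------------------
# AMOVA with R-statistics
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    strata: pd.DataFrame          # df, SS, variance, percent per stratum
    statistics: dict[str, float]  # R_ST always; R_CT/R_SC for two-level
    p_values: dict[str, float]
    n_perm: int

    @property
    def percent_total(self) -> float:
        return float(self.strata["percent"].sum())


def _copy_distance_matrix(gm: GenotypeMatrix, distance: str) -> np.ndarray:
    """Squared distances between the 2n multilocus gene copies.

    Squared repeat-count difference summed over loci (R-statistics frame) or
    allele identity (0/1 mismatch) summed over loci; pairs missing some loci
    contribute only typed loci, rescaled to the full locus count.
    """
    X = gm.repeat_counts()            # n x L x 2
    n, L, _ = X.shape
    copies = np.concatenate([X[:, :, 0], X[:, :, 1]], axis=0)  # 2n x L
    typed = ~np.isnan(copies)
    filled = np.nan_to_num(copies)
    D = np.zeros((2 * n, 2 * n))
    T = np.zeros((2 * n, 2 * n))
    for l in range(L):
        x = filled[:, l]
        t = typed[:, l].astype(float)
        both = np.outer(t, t)
        if distance == "allele_size_squared":
            d = (x[:, None] - x[None, :]) ** 2
        elif distance == "allele_identity":
            d = (x[:, None] != x[None, :]).astype(float)
        else:
            raise ValueError(f"unknown distance {distance!r}")
        D += d * both
        T += both
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(T > 0, D * (L / np.maximum(T, 1)), 0.0)
    np.fill_diagonal(D, 0.0)
    return D


def _ssd(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)]
    return sub.sum() / (2.0 * len(idx))


def _one_level_components(D, pop_of_copy, pops):
    N = D.shape[0]
    P = len(pops)
    ssd_t = _ssd(D, np.arange(N))
    ssd_wp = 0.0
    sizes = []
    for p in pops:
        idx = np.flatnonzero(pop_of_copy == p)
        sizes.append(len(idx))
        ssd_wp += _ssd(D, idx)
    sizes = np.array(sizes, dtype=float)
    ss_ap = ssd_t - ssd_wp
    df_a, df_w = P - 1, N - P
    sig_w = ssd_wp / df_w
    n0 = (N - (sizes**2).sum() / N) / df_a
    sig_a = (ss_ap / df_a - sig_w) / n0
    return ss_ap, ssd_wp, df_a, df_w, sig_a, sig_w


def _two_level_components(D, pop_of_copy, group_of_copy, pops, group_of_pop):
    N = D.shape[0]
    P = len(pops)
    groups = list(dict.fromkeys(group_of_pop.values()))
    G = len(groups)
    ssd_t = _ssd(D, np.arange(N))
    ssd_wp = sum(_ssd(D, np.flatnonzero(pop_of_copy == p)) for p in pops)
    ssd_wg = sum(_ssd(D, np.flatnonzero(group_of_copy == g)) for g in groups)
    ss_ag = ssd_t - ssd_wg
    ss_apwg = ssd_wg - ssd_wp
    n_p = {p: int((pop_of_copy == p).sum()) for p in pops}
    n_g = {g: int((group_of_copy == g).sum()) for g in groups}
    df_a, df_b, df_c = G - 1, P - G, N - P
    sig_c = ssd_wp / df_c
    sum_np2_over_ng = sum(
        sum(n_p[p]**2 for p in pops if group_of_pop[p] == g) / n_g[g]
        for g in groups
    )
    n1 = (N - sum_np2_over_ng) / df_b
    n2 = (sum_np2_over_ng - sum(v**2 for v in n_p.values()) / N) / df_a
    n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_a
    sig_b = (ss_apwg / df_b - sig_c) / n1
    sig_a = (ss_ag / df_a - sig_c - n2 * sig_b) / n3
    return ss_ag, ss_apwg, ssd_wp, df_a, df_b, df_c, sig_a, sig_b, sig_c


def amova(
    gm: GenotypeMatrix,
    groups: dict[str, str] | None = None,
    n_perm: int = 1000,
    distance: str = "allele_size_squared",
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on pairwise gene-copy distances (Excoffier style).

    Without ``groups``: one-level design with R_ST (individual permutations
    among populations).  With ``groups`` (population -> group): three strata
    with R_CT (whole populations permuted among groups), R_SC (individuals
    permuted among populations within groups), and R_ST.  With the default
    squared repeat-count distance the statistics are R-statistics; with
    ``allele_identity`` they are Phi-style F-statistic analogues.
    """
    rng = np.random.default_rng(seed)
    pops = gm.population_order
    n = gm.n_individuals
    D = _copy_distance_matrix(gm, distance)
    ind_pop = gm.populations.copy()

    def copy_labels(ind_labels):
        return np.concatenate([ind_labels, ind_labels])

    if groups is None:
        ss_ap, ssd_wp, df_a, df_w, sig_a, sig_w = _one_level_components(
            D, copy_labels(ind_pop), pops)
        total = sig_a + sig_w
        rst = sig_a / total
        exceed = 0
        for _ in range(n_perm):
            perm = copy_labels(rng.permutation(ind_pop))
            *_rest, pa, pw = _one_level_components(D, perm, pops)
            if pa / (pa + pw) >= rst:
                exceed += 1
        pval = (exceed + 1) / (n_perm + 1) if n_perm else np.nan
        strata = pd.DataFrame(
            {
                "df": [df_a, df_w],
                "SS": [ss_ap, ssd_wp],
                "variance": [sig_a, sig_w],
                "percent": [100 * sig_a / total, 100 * sig_w / total],
            },
            index=["among_populations", "within_populations"],
        )
        return AmovaResult(strata, {"R_ST": rst}, {"R_ST": pval}, n_perm)

    missing = [p for p in pops if p not in groups]
    if missing:
        raise ValueError(f"hierarchy does not cover populations {missing}")
    singleton_groups = [
        g for g in set(groups.values())
        if sum(1 for p in pops if groups[p] == g) == 1
    ]
    if singleton_groups:
        warnings.warn(
            f"groups with a single population {singleton_groups}: the "
            "among-populations-within-groups contrast has no information there"
        )
    ind_group = np.array([groups[p] for p in ind_pop], dtype=object)
    res = _two_level_components(
        D, copy_labels(ind_pop), copy_labels(ind_group), pops, groups)
    ss_ag, ss_apwg, ssd_wp, df_a, df_b, df_c, sig_a, sig_b, sig_c = res
    total = sig_a + sig_b + sig_c
    r_ct = sig_a / total
    r_sc = sig_b / (sig_b + sig_c)
    r_st = (sig_a + sig_b) / total

    def stats_for(pop_lab, grp_lab, grp_map):
        r = _two_level_components(
            D, copy_labels(pop_lab), copy_labels(grp_lab), pops, grp_map)
        _, _, _, _, _, _, sa, sb, sc = r
        tot = sa + sb + sc
        return sa / tot, sb / (sb + sc), (sa + sb) / tot

    ex_ct = ex_sc = ex_st = 0
    group_names = list(dict.fromkeys(groups.values()))
    pops_arr = np.array(pops, dtype=object)
    group_of_pops = np.array([groups[p] for p in pops], dtype=object)
    for _ in range(n_perm):
        # R_SC: individuals among populations within groups
        lab = ind_pop.copy()
        for g in group_names:
            sel = ind_group == g
            lab[sel] = rng.permutation(lab[sel])
        _, sc_stat, _ = stats_for(lab, ind_group, groups)
        if sc_stat >= r_sc:
            ex_sc += 1
        # R_CT: whole populations among groups
        perm_groups = dict(zip(pops_arr, rng.permutation(group_of_pops)))
        grp_lab = np.array([perm_groups[p] for p in ind_pop], dtype=object)
        ct_stat, _, _ = stats_for(ind_pop, grp_lab, perm_groups)
        if ct_stat >= r_ct:
            ex_ct += 1
        # R_ST: individuals among all populations
        lab = rng.permutation(ind_pop)
        grp_lab = np.array([groups[p] for p in lab], dtype=object)
        _, _, st_stat = stats_for(lab, grp_lab, groups)
        if st_stat >= r_st:
            ex_st += 1

    def pv(x):
        return (x + 1) / (n_perm + 1) if n_perm else np.nan

    strata = pd.DataFrame(
        {
            "df": [df_a, df_b, df_c],
            "SS": [ss_ag, ss_apwg, ssd_wp],
            "variance": [sig_a, sig_b, sig_c],
            "percent": [100 * sig_a / total, 100 * sig_b / total,
                        100 * sig_c / total],
        },
        index=["among_groups", "among_populations_within_groups",
               "within_populations"],
    )
    return AmovaResult(
        strata,
        {"R_CT": r_ct, "R_SC": r_sc, "R_ST": r_st},
        {"R_CT": pv(ex_ct), "R_SC": pv(ex_sc), "R_ST": pv(ex_st)},
        n_perm,
    )


# ---------------------------------------------------------------------------
# Ordination and surfaces
# ---------------------------------------------------------------------------

def pcoa(D, labels=None):
    """Classical metric scaling (principal coordinates) of a distance matrix.

    Returns ``(coordinates, eigenvalues, percent_explained)``; axes ordered
    by decreasing eigenvalue.  Accepts a labeled DataFrame or an array plus
    ``labels``.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        D = D.to_numpy(float)
    labels = labels or [str(i) for i in range(len(D))]
    if np.allclose(D, 0):
        k = len(labels)
        coords = pd.DataFrame(np.zeros((k, 1)), index=labels, columns=["PC1"])
        return coords, np.zeros(1), np.zeros(1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(_SkbioDM(D, ids=labels))
    coords = res.samples
    coords.index = labels
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    eig = res.eigvals.to_numpy()
    prop = res.proportion_explained.to_numpy() * 100
    return coords, eig, prop


def idw_surface(points, grid, power: float = 2.0):
    """Inverse-distance-weighted interpolation on a regular lat/lon grid.

    ``points``: iterable of (lat, lon, value).  ``grid``: (lat_min, lat_max,
    lon_min, lon_max, n_lat, n_lon).  Exact at data points; for coincident
    points with different values the first wins (with a warning).
    """
    pts = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    vals = np.asarray([p[2] for p in points], dtype=float)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    uniq, first_idx = np.unique(pts, axis=0, return_index=True)
    if len(uniq) < len(pts):
        dup_vals = {tuple(p) for p in pts}
        if len({(tuple(p), v) for p, v in zip(pts, vals)}) > len(dup_vals):
            warnings.warn("coincident points with different values: first wins")
    lat_min, lat_max, lon_min, lon_max, n_lat, n_lon = grid
    lat = np.linspace(lat_min, lat_max, n_lat)
    lon = np.linspace(lon_min, lon_max, n_lon)
    LA, LO = np.meshgrid(lat, lon, indexing="ij")
    cells = np.column_stack([LA.ravel(), LO.ravel()])
    d = np.sqrt(((cells[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(len(cells))
    exact = d < 1e-12
    has_exact = exact.any(axis=1)
    out[has_exact] = vals[np.argmax(exact[has_exact], axis=1)]
    rest = ~has_exact
    with np.errstate(divide="ignore"):
        w = d[rest] ** (-power)
    out[rest] = (w * vals).sum(axis=1) / w.sum(axis=1)
    return lat, lon, out.reshape(n_lat, n_lon)


def diversity_coordinate_correlation(div: pd.DataFrame,
                                     sites: pd.DataFrame) -> pd.DataFrame:
    """Pearson R and two-sided p for (Ho, He) against (latitude, longitude)."""
    common = div.index.intersection(sites.index)
    if len(common) < 3:
        raise ValueError("need >= 3 populations")
    recs = []
    for stat in ("Ho", "He"):
        for axis, col in (("latitude", "lat"), ("longitude", "lon")):
            x = sites.loc[common, col].to_numpy(float)
            y = div.loc[common, stat].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                recs.append((stat, axis, np.nan, np.nan, True))
                continue
            r, p = sp_stats.pearsonr(y, x)
            recs.append((stat, axis, r, p, False))
    return pd.DataFrame(recs, columns=["statistic", "axis", "R", "p",
                                       "undefined"])
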