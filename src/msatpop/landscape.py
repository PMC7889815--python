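"""Isolation-by-distance vs isolation-by-environment, and spatial-climatic
variance partitioning.

Genetic, geographic and climatic distance matrices are compared with seeded
Mantel and partial Mantel permutation tests (999 permutations by default,
two-tailed).  Spatial predictors are principal coordinates of neighbour
matrices (PCNM): principal coordinates of a geographic distance matrix whose
entries beyond a truncation threshold (default: the longest minimum-spanning-
tree edge) are replaced by four times the threshold.  Population allele
frequencies serve as the multivariate response in a redundancy analysis
(RDA); adjusted-R^2 variance partitioning splits the explained variance into
pure-climate, pure-geography and collinear (joint) fractions.  Equal numbers
of geographic and climatic predictors are used by default to avoid biasing
the comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .io import CLIMATE_COLUMNS, GenotypeMatrix
from .popgen import allele_frequencies

__all__ = [
    "coordinate_distance",
    "climate_distance",
    "mantel",
    "partial_mantel",
    "MantelResult",
    "pcnm",
    "allele_response_matrix",
    "rda_partition",
    "RdaPartition",
    "select_pcnm_forward",
]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _haversine_km(lat1, lon1, lat2, lon2):
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def coordinate_distance(sites: pd.DataFrame,
                        method: str = "euclidean_degrees") -> pd.DataFrame:
    """Pairwise site distances in degrees (Euclidean on lat/lon) or
    great-circle kilometres."""
    lat = sites["lat"].to_numpy(float)
    lon = sites["lon"].to_numpy(float)
    if method == "euclidean_degrees":
        d = np.sqrt((lat[:, None] - lat[None, :]) ** 2
                    + (lon[:, None] - lon[None, :]) ** 2)
    elif method == "great_circle_km":
        d = _haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=sites.index, columns=sites.index)


def climate_distance(sites: pd.DataFrame, standardize: bool = True,
                     columns: list[str] | None = None) -> pd.DataFrame:
    """Euclidean distance on the (optionally z-scored) bioclimatic vectors."""
    columns = columns or CLIMATE_COLUMNS
    X = sites[columns].to_numpy(float)
    if standardize:
        sd = X.std(axis=0)
        const = sd == 0
        if const.any():
            warnings.warn(
                f"constant climate columns dropped: "
                f"{[c for c, k in zip(columns, const) if k]}")
            X = X[:, ~const]
            sd = sd[~const]
        X = (X - X.mean(axis=0)) / sd
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(d, index=sites.index, columns=sites.index)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def _tri(M: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(len(M), k=1)
    return M[i, j]


def _as_array(M, labels=None):
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(float), list(M.index)
    return np.asarray(M, dtype=float), labels


def mantel(A, B, n_perm: int = 999, seed: int | None = None) -> MantelResult:
    """Two-tailed Mantel test: Pearson correlation of distance matrices with
    significance from simultaneous row/column permutations of one matrix."""
    A, la = _as_array(A)
    B, lb = _as_array(B)
    if A.shape != B.shape:
        raise ValueError("matrices must have the same shape")
    if la is not None and lb is not None and la != lb:
        raise ValueError("matrix labels disagree")
    a = _tri(A)
    b = _tri(B)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance distance matrix: r undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(A)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = _tri(B[np.ix_(perm, perm)])
        if abs(np.corrcoef(a, bp)[0, 1]) >= abs(r_obs):
            count += 1
    p = (count + 1) / (n_perm + 1) if n_perm else np.nan
    return MantelResult(r_obs, p, n_perm)


def _residual_matrix(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the off-diagonal entries of M regressed on those of C,
    folded back into a symmetric matrix with zero diagonal."""
    m = _tri(M)
    c = _tri(C)
    beta = np.polyfit(c, m, 1)
    res = m - np.polyval(beta, c)
    out = np.zeros_like(M)
    i, j = np.triu_indices(len(M), k=1)
    out[i, j] = res
    out[j, i] = res
    return out


def partial_mantel(A, B, C, n_perm: int = 999,
                   seed: int | None = None) -> MantelResult:
    """Partial Mantel: correlation of A and B with C held constant.

    Both matrices are residualized on C; significance comes from permuting
    the residualized A matrix (rows and columns together).
    """
    A, _ = _as_array(A)
    B, _ = _as_array(B)
    C, _ = _as_array(C)
    if not (A.shape == B.shape == C.shape):
        raise ValueError("matrices must have the same shape")
    RA = _residual_matrix(A, C)
    RB = _residual_matrix(B, C)
    ra = _tri(RA)
    rb = _tri(RB)
    tol_a = 1e-10 * max(1.0, np.abs(_tri(A)).max())
    tol_b = 1e-10 * max(1.0, np.abs(_tri(B)).max())
    if ra.std() <= tol_a or rb.std() <= tol_b:
        return MantelResult(0.0, 1.0, n_perm)
    r_obs = float(np.corrcoef(ra, rb)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(A)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rap = _tri(RA[np.ix_(perm, perm)])
        if abs(np.corrcoef(rap, rb)[0, 1]) >= abs(r_obs):
            count += 1
    p = (count + 1) / (n_perm + 1) if n_perm else np.nan
    return MantelResult(r_obs, p, n_perm)


# ---------------------------------------------------------------------------
# PCNM spatial eigenvectors
# ---------------------------------------------------------------------------

def pcnm(D, truncation="auto"):
    """Principal coordinates of the truncated neighbour matrix.

    Distances above the truncation threshold are replaced by 4x the
    threshold; ``auto`` sets the threshold to the longest edge of the
    minimum spanning tree (keeping the graph connected).  Returns unit-norm
    eigenvectors with positive eigenvalues, ordered by eigenvalue, and the
    eigenvalues.
    """
    Dm, labels = _as_array(D)
    n = len(Dm)
    if np.allclose(Dm, 0):
        return pd.DataFrame(index=labels or range(n)), np.array([])
    if truncation == "auto":
        mst = minimum_spanning_tree(Dm).toarray()
        truncation = mst.max()
    Dt = np.where(Dm > truncation, 4.0 * truncation, Dm)
    np.fill_diagonal(Dt, 0.0)
    B = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ B @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals)) * 1e-9
    keep = vals > tol
    vals, vecs = vals[keep], vecs[:, keep]
    cols = [f"PCNM{i + 1}" for i in range(vecs.shape[1])]
    return pd.DataFrame(vecs, index=labels or range(n), columns=cols), vals


# ---------------------------------------------------------------------------
# Allele-frequency response table
# ---------------------------------------------------------------------------

def allele_response_matrix(gm: GenotypeMatrix, target_columns: int = 200,
                           min_freq: float | None = None):
    """Population x allele frequency table for constrained ordination.

    Per locus the globally most frequent allele is dropped (sum-to-one
    redundancy); the remaining alleles are ranked by global frequency and
    either filtered at ``min_freq`` or truncated to ``target_columns``.
    Cells undefined because a population is untyped at a locus are filled
    with that allele's global frequency.  Returns ``(table, info)`` where
    ``info`` records the dropped and retained alleles.
    """
    if len(gm.population_order) < 2:
        raise ValueError("need >= 2 populations")
    pop_freqs, _ = allele_frequencies(gm, by="population")
    tot_freqs, _ = allele_frequencies(gm, by="total")
    cols = {}
    global_freq = {}
    dropped = {}
    for l, (pf, tf) in enumerate(zip(pop_freqs, tot_freqs)):
        name = gm.loci[l].name
        if tf.dropna().empty:
            continue
        major = tf.idxmax()
        dropped[name] = major
        for a in tf.index:
            if a == major:
                continue
            key = f"{name}:{a}"
            col = pf[a].fillna(tf[a])
            cols[key] = col
            global_freq[key] = float(tf[a])
    table = pd.DataFrame(cols)
    ranked = sorted(global_freq, key=lambda k: -global_freq[k])
    if min_freq is not None:
        keep = [k for k in ranked if global_freq[k] >= min_freq]
    else:
        keep = ranked[:target_columns]
    if not keep:
        raise ValueError("no allele columns retained")
    if min_freq is None and len(keep) < target_columns:
        warnings.warn(
            f"only {len(keep)} allele columns available (target {target_columns})")
    info = {"dropped_major": dropped, "retained": keep,
            "global_freq": global_freq}
    return table[keep], info


# ---------------------------------------------------------------------------
# RDA and variance partitioning
# ---------------------------------------------------------------------------

def _drop_collinear(X: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    Xc = X - X.mean()
    keep: list[str] = []
    for c in X.columns:
        cand = Xc[keep + [c]].to_numpy(float)
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) \
                == len(keep) + 1:
            keep.append(c)
    if len(keep) < X.shape[1]:
        warnings.warn(f"collinear predictors dropped: "
                      f"{[c for c in X.columns if c not in keep]}")
    return X[keep]


def _fit_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, float, int]:
    """R^2, residual SS and predictor count of the multivariate regression."""
    n = len(Y)
    X1 = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    fit = X1 @ beta
    ss_tot = (Y**2).sum()
    ss_fit = ((fit - Y.mean(axis=0))**2).sum()
    return ss_fit / ss_tot, ss_tot - ss_fit, X.shape[1]


def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    Z1 = np.column_stack([np.ones(len(M)), Z])
    beta, *_ = np.linalg.lstsq(Z1, M, rcond=None)
    return M - Z1 @ beta


def _perm_f_test(Y, X, Z, n_perm, rng):
    """Permutation F-test for Y ~ X (conditioning on Z if given), permuting
    rows of the (residualized) response."""
    if Z is not None:
        Yr = _residualize(Y, Z)
        Xr = _residualize(X, Z)
        q = Z.shape[1]
    else:
        Yr, Xr, q = Y - Y.mean(axis=0), X, 0
    n = len(Y)
    p = Xr.shape[1]

    def fstat(Yp):
        r2, ss_res, _ = _fit_r2(Yp, Xr)
        ss_fit = r2 * (Yp**2).sum()
        df_res = n - p - q - 1
        if df_res <= 0 or ss_res <= 0:
            return np.inf
        return (ss_fit / p) / (ss_res / df_res)

    f_obs = fstat(Yr)
    count = 0
    for _ in range(n_perm):
        Yp = Yr[rng.permutation(n)]
        if fstat(Yp) >= f_obs:
            count += 1
    pval = (count + 1) / (n_perm + 1) if n_perm else np.nan
    return f_obs, pval


@dataclass
class RdaPartition:
    adj_r2: dict[str, float]       # full, geo, clim
    fractions: dict[str, float]    # pure_climate, pure_geography, joint, unexplained
    tests: pd.DataFrame            # F and p for full and both partial models
    biplot_scores: pd.DataFrame    # predictor correlations with first two axes
    site_scores: pd.DataFrame


def rda_partition(Y: pd.DataFrame, X_geo: pd.DataFrame, X_clim: pd.DataFrame,
                  n_perm: int = 999, seed: int | None = None) -> RdaPartition:
    """Adjusted-R^2 variance partitioning of a multivariate response between
    geographic and climatic predictor blocks.

    pure climate = adjR2(full) - adjR2(geo); pure geography = adjR2(full) -
    adjR2(clim); joint = adjR2(clim) + adjR2(geo) - adjR2(full).  Slightly
    negative fractions are reported as computed (adjusted-R^2 artifact).
    Significance: permutation F-tests of the full model and of each block
    conditioned on the other (residualized response permuted).
    """
    if not Y.index.equals(X_geo.index) or not Y.index.equals(X_clim.index):
        raise ValueError("row labels of Y and predictors must agree")
    X_geo = _drop_collinear(X_geo)
    X_clim = _drop_collinear(X_clim)
    n = len(Y)
    p_tot = X_geo.shape[1] + X_clim.shape[1]
    if n <= p_tot + 1:
        raise ValueError(f"{n} rows cannot support {p_tot} predictors")
    Yc = (Y - Y.mean()).to_numpy(float)
    Xg = ((X_geo - X_geo.mean()) / X_geo.std(ddof=0)).to_numpy(float)
    Xc = ((X_clim - X_clim.mean()) / X_clim.std(ddof=0)).to_numpy(float)
    Xfull = np.column_stack([Xg, Xc])

    r2_full, _, p_full = _fit_r2(Yc, Xfull)
    r2_geo, _, p_geo = _fit_r2(Yc, Xg)
    r2_clim, _, p_clim = _fit_r2(Yc, Xc)
    adj = {
        "full": _adj_r2(r2_full, n, p_full),
        "geo": _adj_r2(r2_geo, n, p_geo),
        "clim": _adj_r2(r2_clim, n, p_clim),
    }
    fractions = {
        "pure_climate": adj["full"] - adj["geo"],
        "pure_geography": adj["full"] - adj["clim"],
        "joint": adj["clim"] + adj["geo"] - adj["full"],
        "unexplained": 1.0 - adj["full"],
    }
    rng = np.random.default_rng(seed)
    f_full, p_full_v = _perm_f_test(Yc, Xfull, None, n_perm, rng)
    f_g, p_g = _perm_f_test(Yc, Xg, Xc, n_perm, rng)
    f_c, p_c = _perm_f_test(Yc, Xc, Xg, n_perm, rng)
    tests = pd.DataFrame(
        {"F": [f_full, f_g, f_c], "p": [p_full_v, p_g, p_c]},
        index=["full", "geo_given_clim", "clim_given_geo"],
    )
    # RDA axes: PCA of the fitted values of the full model
    X1 = np.column_stack([np.ones(n), Xfull])
    beta, *_ = np.linalg.lstsq(X1, Yc, rcond=None)
    fit = X1 @ beta
    U, s, Vt = np.linalg.svd(fit - fit.mean(axis=0), full_matrices=False)
    k = min(2, (s > 1e-12).sum())
    sites = pd.DataFrame(U[:, :k] * s[:k], index=Y.index,
                         columns=[f"RDA{i + 1}" for i in range(k)])
    pred_names = list(X_geo.columns) + list(X_clim.columns)
    bip = np.zeros((len(pred_names), k))
    for j in range(k):
        ax = sites.iloc[:, j].to_numpy()
        if ax.std() == 0:
            continue
        for i in range(len(pred_names)):
            x = Xfull[:, i]
            bip[i, j] = np.corrcoef(x, ax)[0, 1] if x.std() > 0 else 0.0
    biplot = pd.DataFrame(bip, index=pred_names,
                          columns=[f"RDA{i + 1}" for i in range(k)])
    return RdaPartition(adj, fractions, tests, biplot, sites)


def select_pcnm_forward(Y: pd.DataFrame, pcnms: pd.DataFrame, k: int = 6,
                        alpha: float = 0.05, n_perm: int = 199,
                        seed: int | None = None) -> list[str]:
    """Forward-select up to ``k`` PCNM predictors by adjusted-R^2 improvement
    with a permutation test on each added variable."""
    rng = np.random.default_rng(seed)
    Yc = (Y - Y.mean()).to_numpy(float)
    chosen: list[str] = []
    remaining = list(pcnms.columns)
    while remaining and len(chosen) < k:
        best_col, best_adj = None, -np.inf
        for c in remaining:
            X = pcnms[chosen + [c]].to_numpy(float)
            r2, _, p = _fit_r2(Yc, X)
            a = _adj_r2(r2, len(Y), p)
            if a > best_adj:
                best_adj, best_col = a, c
        Z = pcnms[chosen].to_numpy(float) if chosen else None
        Xb = pcnms[[best_col]].to_numpy(float)
        _, pval = _perm_f_test(Yc, Xb, Z, n_perm, rng)
        if pval > alpha:
            break
        chosen.append(best_col)
        remaining.remove(best_col)
    return chosen
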