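"""Climatic-niche comparison of population groups in environment space.

A PCA calibrated on the pooled available environment (the "background" of
every group: climates sampled inside each group's buffered minimum convex
polygon) defines a two-axis environment space.  Occurrences and backgrounds
are projected into it, Gaussian kernel densities are evaluated on a common
grid (100 x 100, Silverman bandwidth), and the density of occurrence is
corrected by the density of available environment (occupancy
z = (o / max o) / (e / max e), zero where no environment is available).
Niche overlap between groups is Schoener's D = 1 - 0.5 * sum |pA - pB| over
grid cells, with p the normalized occupancy; D ranges from 0 (no overlap)
to 1 (identical niches).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from shapely.geometry import MultiPoint, Point

from .io import CLIMATE_COLUMNS

__all__ = [
    "standard_pca",
    "background_region",
    "BackgroundRegion",
    "pca_env",
    "NicheGrid",
    "schoener_d",
    "overlap_report",
]


# ---------------------------------------------------------------------------
# Standard PCA on the correlation matrix
# ---------------------------------------------------------------------------

def standard_pca(climate: pd.DataFrame, columns: list[str] | None = None):
    """PCA of z-scored climate variables (correlation-matrix PCA).

    Returns ``(scores, loadings, percent_variance)``.  Component signs are
    fixed so the largest-magnitude loading of each component is positive.
    """
    columns = columns or [c for c in CLIMATE_COLUMNS if c in climate.columns]
    X = climate[columns].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"constant variables dropped: "
                      f"{[c for c, k in zip(columns, const) if k]}")
        columns = [c for c, k in zip(columns, const) if not k]
        X = X[:, ~const]
        sd = sd[~const]
    Z = (X - X.mean(axis=0)) / sd
    n = len(Z)
    C = Z.T @ Z / (n - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    for j in range(vecs.shape[1]):
        if vecs[np.abs(vecs[:, j]).argmax(), j] < 0:
            vecs[:, j] *= -1
    scores = pd.DataFrame(Z @ vecs, index=climate.index,
                          columns=[f"PC{i + 1}" for i in range(len(vals))])
    loadings = pd.DataFrame(vecs, index=columns, columns=scores.columns)
    pct = 100 * vals / vals.sum()
    return scores, loadings, pct


# ---------------------------------------------------------------------------
# Background regions
# ---------------------------------------------------------------------------

@dataclass
class BackgroundRegion:
    group: str
    polygon: object                 # shapely geometry
    points: pd.DataFrame            # lat/lon (+climate if a surface is given)

    @property
    def area(self) -> float:
        return self.polygon.area


def background_region(sites: pd.DataFrame, group: str = "",
                      buffer_deg: float = 0.3,
                      grid_step: float = 0.1,
                      climate_fn=None) -> BackgroundRegion:
    """Minimum convex polygon of the sites buffered by ``buffer_deg`` degrees,
    with regular-grid background points inside it.

    ``climate_fn(lat, lon) -> dict`` (or arrays) attaches climate values to
    the background points; degenerate site sets (1-2 points) yield buffered
    points/segments.
    """
    if len(sites) < 1:
        raise ValueError("need at least one site")
    if buffer_deg < 0:
        raise ValueError("buffer must be >= 0")
    pts = MultiPoint([(lo, la) for la, lo in
                      zip(sites["lat"], sites["lon"])])
    poly = pts.convex_hull.buffer(buffer_deg) if buffer_deg > 0 else pts.convex_hull
    min_lon, min_lat, max_lon, max_lat = poly.bounds
    lats = np.arange(min_lat, max_lat + grid_step / 2, grid_step)
    lons = np.arange(min_lon, max_lon + grid_step / 2, grid_step)
    rows = []
    for la in lats:
        for lo in lons:
            if poly.covers(Point(lo, la)):
                rows.append((la, lo))
    if not rows:  # degenerate zero-buffer point/segment
        rows = [(la, lo) for la, lo in zip(sites["lat"], sites["lon"])]
    bg = pd.DataFrame(rows, columns=["lat", "lon"])
    if climate_fn is not None:
        clim = climate_fn(bg["lat"].to_numpy(), bg["lon"].to_numpy())
        for k, v in clim.items():
            bg[k] = v
    return BackgroundRegion(group, poly, bg)


# ---------------------------------------------------------------------------
# PCA-env occupancy grids
# ---------------------------------------------------------------------------

@dataclass
class NicheGrid:
    group: str
    occurrence: np.ndarray     # o, kernel density of occurrences
    available: np.ndarray      # e, kernel density of the group's background
    occupancy: np.ndarray      # z, normalized to sum 1
    x_edges: np.ndarray
    y_edges: np.ndarray


def _kde_on_grid(xy: np.ndarray, XX: np.ndarray, YY: np.ndarray,
                 bandwidth_factor: float = 1.0) -> np.ndarray:
    if len(xy) < 2 or np.allclose(xy.std(axis=0), 0):
        # degenerate cloud: a point mass on the nearest cell
        out = np.zeros_like(XX)
        i = np.abs(XX[:, 0] - xy[0, 0]).argmin() if len(xy) else 0
        j = np.abs(YY[0, :] - xy[0, 1]).argmin() if len(xy) else 0
        out[i, j] = 1.0
        return out
    kde = gaussian_kde(xy.T)  # Scott/Silverman-style bandwidth
    if bandwidth_factor != 1.0:
        kde.set_bandwidth(kde.factor * bandwidth_factor)
    return kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)


def pca_env(backgrounds: dict[str, pd.DataFrame],
            occurrences: dict[str, pd.DataFrame],
            columns: list[str] | None = None,
            grid_size: int = 100,
            correction: str = "occupancy",
            bandwidth_factor: float = 1.0):
    """Kernel-density occupancy grids in a background-calibrated PCA space.

    ``backgrounds``/``occurrences`` map group id to climate tables.  The PCA
    is calibrated on the pooled backgrounds; each group's occurrences and
    background are projected onto the first two axes and smoothed on a
    common ``grid_size`` x ``grid_size`` grid spanning the pooled background.
    ``correction='occupancy'`` divides occurrence density by available-
    environment density (zero where none is available); ``'raw'`` uses the
    occurrence density alone.  Returns ``(grids, loadings, pct_variance)``.
    """
    columns = columns or CLIMATE_COLUMNS
    pooled = pd.concat(backgrounds.values(), axis=0)
    if len(pooled) < 100:
        warnings.warn(f"pooled background has only {len(pooled)} points")
    mu = pooled[columns].mean()
    sd = pooled[columns].std(ddof=1).replace(0, 1.0)
    _, loadings, pct = standard_pca(pooled, columns)
    axes = loadings.iloc[:, :2].to_numpy()

    def project(df):
        Z = ((df[columns] - mu) / sd).to_numpy(float)
        return Z @ axes

    pooled_xy = project(pooled)
    x_lo, y_lo = pooled_xy.min(axis=0)
    x_hi, y_hi = pooled_xy.max(axis=0)
    pad_x = 0.05 * (x_hi - x_lo or 1.0)
    pad_y = 0.05 * (y_hi - y_lo or 1.0)
    xs = np.linspace(x_lo - pad_x, x_hi + pad_x, grid_size)
    ys = np.linspace(y_lo - pad_y, y_hi + pad_y, grid_size)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    grids = {}
    for g in backgrounds:
        occ = occurrences[g]
        if len(occ) < 2:
            warnings.warn(f"group {g}: <2 occurrences, degenerate density")
        o = _kde_on_grid(project(occ), XX, YY, bandwidth_factor)
        e = _kde_on_grid(project(backgrounds[g]), XX, YY, bandwidth_factor)
        if correction == "occupancy":
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(e > 0,
                             (o / (o.max() or 1.0)) / np.where(e > 0, e / (e.max() or 1.0), 1.0),
                             0.0)
        elif correction == "raw":
            z = o.copy()
        else:
            raise ValueError(f"unknown correction {correction!r}")
        total = z.sum()
        if total > 0:
            z = z / total
        grids[g] = NicheGrid(g, o, e, z, xs, ys)
    return grids, loadings, pct


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------

def schoener_d(a: NicheGrid, b: NicheGrid) -> float:
    """Schoener's D between two occupancy grids on the same axes."""
    if a.occupancy.shape != b.occupancy.shape or \
            not np.allclose(a.x_edges, b.x_edges) or \
            not np.allclose(a.y_edges, b.y_edges):
        raise ValueError("niche grids are not on the same grid")
    pa = a.occupancy / (a.occupancy.sum() or 1.0)
    pb = b.occupancy / (b.occupancy.sum() or 1.0)
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def density_mask(grid: NicheGrid, quantile: float, field: str = "occurrence"):
    """Smallest cell set holding ``quantile`` of the total density (sorted
    densest-first); quantile 1.0 gives the full support."""
    d = getattr(grid, field)
    total = d.sum()
    if total == 0:
        return np.zeros_like(d, dtype=bool)
    flat = np.sort(d.ravel())[::-1]
    cum = np.cumsum(flat) / total
    k = int(np.searchsorted(cum, quantile)) + 1
    thresh = flat[min(k - 1, len(flat) - 1)]
    return d >= max(thresh, np.finfo(float).tiny)


def overlap_report(grids: dict[str, NicheGrid]) -> dict:
    """Pairwise Schoener's D plus 20%/100% occurrence-density contour masks."""
    names = list(grids)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    D = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = schoener_d(grids[a], grids[b])
            D.loc[a, b] = D.loc[b, a] = d
    contours = {
        g: {"core20": density_mask(grids[g], 0.20),
            "full100": density_mask(grids[g], 1.00)}
        for g in names
    }
    return {"D": D, "contours": contours}
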