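"""Data model and file formats for co-dominant microsatellite studies.

Genotypes are diploid calls at length-variable loci, stored as pairs of
positive integers (fragment sizes in base pairs or repeat counts); 0 is the
missing sentinel.  Two interchange formats are supported: the GenAlEx
codominant CSV layout and the STRUCTURE text format (one or two rows per
individual, -9 missing).  Site metadata (coordinates plus six WorldClim
bioclimatic variables) and ancestry (Q) matrices travel as TSV.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0
STRUCTURE_MISSING = -9

CLIMATE_COLUMNS = ["BIO1", "BIO4", "BIO11", "BIO12", "BIO15", "BIO17"]


class FormatError(ValueError):
    """Raised when an input file does not follow the declared layout."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    ``repeat_unit_length`` converts fragment sizes (bp) to repeat counts:
    ``count = (size - offset) / repeat_unit_length``.  When alleles are
    already recorded as repeat counts set ``allele_encoding='repeat_count'``.
    """

    name: str
    repeat_unit_length: int = 1
    allele_encoding: str = "fragment_bp"
    offset: int = 0

    def __post_init__(self):
        if self.repeat_unit_length < 1:
            raise ValueError("repeat_unit_length must be >= 1")
        if self.allele_encoding not in ("fragment_bp", "repeat_count"):
            raise ValueError(f"unknown allele_encoding {self.allele_encoding!r}")


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls: individuals x loci x 2 integer alleles.

    ``calls[i, l, :]`` holds the two allele values for individual ``i`` at
    locus ``l``; 0 marks a missing genotype.  Half-missing genotypes are
    promoted to fully missing on construction so that observed-heterozygosity
    counts are not biased by single dropped alleles.
    """

    individuals: list[str]
    populations: np.ndarray
    loci: list[Locus]
    calls: np.ndarray
    n_half_missing_promoted: int = field(default=0, init=False)

    def __post_init__(self):
        self.populations = np.asarray(self.populations, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != {(n, L, 2)}")
        if self.populations.shape != (n,):
            raise ValueError("one population label per individual required")
        if n and any(p is None or p == "" for p in self.populations):
            raise ValueError("every individual needs a population")
        if np.any(self.calls < 0):
            raise ValueError("allele values must be positive (0 = missing)")
        names = [lc.name for lc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        half = (self.calls == MISSING).sum(axis=2) == 1
        self.n_half_missing_promoted = int(half.sum())
        if self.n_half_missing_promoted:
            self.calls[half] = MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_order(self) -> list[str]:
        """Populations in first-appearance (file) order — canonical ordering."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        return {p: int((self.populations == p).sum()) for p in self.population_order}

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): genotype fully missing."""
        return self.calls[:, :, 0] == MISSING

    def repeat_counts(self) -> np.ndarray:
        """Float (n, L, 2) repeat counts, NaN where missing."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        for l, locus in enumerate(self.loci):
            if locus.allele_encoding == "fragment_bp":
                out[:, l, :] = (out[:, l, :] - locus.offset) / locus.repeat_unit_length
        return out

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.individuals[i] for i in keep],
            self.populations[keep],
            list(self.loci),
            self.calls[keep].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individuals == other.individuals
            and list(self.populations) == list(other.populations)
            and [l.name for l in self.loci] == [l.name for l in other.loci]
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# GenAlEx codominant CSV
# ---------------------------------------------------------------------------

def read_genalex(path) -> GenotypeMatrix:
    """Read a GenAlEx codominant CSV.

    Layout: row 1 = n_loci, n_samples, n_pops, pop sizes...; row 2 = title /
    pop names (ignored); row 3 = column headers (sample, pop, one name per
    locus spanning two columns); data rows = id, pop, 2 columns per locus.
    0 encodes a missing allele.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    if len(rows) < 3:
        raise FormatError(f"{path}: expected >= 3 header rows")
    try:
        head = [int(x) for x in rows[0] if x.strip() != ""]
        n_loci, n_samples, n_pops = head[0], head[1], head[2]
        pop_sizes = head[3:3 + n_pops]
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: line 1: bad numeric header ({exc})") from exc
    header = rows[2]
    if len(header) < 2 + 2 * n_loci:
        raise FormatError(f"{path}: line 3: expected {2 + 2 * n_loci} columns")
    locus_names = [header[2 + 2 * i].strip() or f"L{i + 1}" for i in range(n_loci)]
    data = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(data) != n_samples:
        raise FormatError(
            f"{path}: header declares {n_samples} samples but found {len(data)} "
            f"data rows (first data line is line 4)"
        )
    inds, pops, calls = [], [], []
    for k, r in enumerate(data):
        line_no = k + 4
        cells = [c.strip() for c in r]
        if len(cells) < 2 + 2 * n_loci:
            raise FormatError(f"{path}: line {line_no}: too few allele columns")
        inds.append(cells[0])
        pops.append(cells[1])
        try:
            alleles = [int(float(c)) if c else MISSING for c in cells[2:2 + 2 * n_loci]]
        except ValueError as exc:
            raise FormatError(f"{path}: line {line_no}: non-integer allele") from exc
        calls.append(np.array(alleles).reshape(n_loci, 2))
    gm = GenotypeMatrix(inds, np.array(pops, dtype=object),
                        [Locus(nm) for nm in locus_names], np.stack(calls))
    if pop_sizes and sorted(pop_sizes) != sorted(gm.population_sizes().values()):
        raise FormatError(
            f"{path}: line 1 population sizes {pop_sizes} disagree with data"
        )
    return gm


def write_genalex(gm: GenotypeMatrix, path, title: str = "msatpop export") -> None:
    sizes = gm.population_sizes()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([gm.n_loci, gm.n_individuals, len(sizes), *sizes.values()])
        w.writerow([title, "", "", *sizes.keys()])
        header = ["Sample", "Pop"]
        for lc in gm.loci:
            header += [lc.name, ""]
        w.writerow(header)
        for i, ind in enumerate(gm.individuals):
            w.writerow([ind, gm.populations[i], *gm.calls[i].ravel().tolist()])


# ---------------------------------------------------------------------------
# STRUCTURE text format
# ---------------------------------------------------------------------------

def read_structure_format(path, rows_per_individual: int = 2) -> GenotypeMatrix:
    """Read STRUCTURE-format text (whitespace separated, -9 missing).

    An optional first line of locus names (no id/pop columns, non-numeric) is
    recognized.  Expected data columns: id, pop, then one allele per locus
    (two-row dialect) or two interleaved alleles per locus (one-row dialect).
    """
    if rows_per_individual not in (1, 2):
        raise ValueError("rows_per_individual must be 1 or 2")
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    locus_names = None
    if not any(_is_number(t) for t in lines[0]):
        locus_names = lines[0]
        lines = lines[1:]
    widths = {len(r) for r in lines}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    width = widths.pop()
    per_row = 1 if rows_per_individual == 2 else 2
    n_loci, rem = divmod(width - 2, per_row)
    if n_loci < 1 or rem:
        raise FormatError(f"{path}: row width {width} not id+pop+{per_row}*L")
    if locus_names is None:
        locus_names = [f"L{i + 1}" for i in range(n_loci)]
    elif len(locus_names) != n_loci:
        raise FormatError(f"{path}: {len(locus_names)} locus names for {n_loci} loci")
    if rows_per_individual == 2 and len(lines) % 2:
        raise FormatError(f"{path}: odd line count in two-row dialect")

    inds, pops, calls = [], [], []
    step = rows_per_individual
    for k in range(0, len(lines), step):
        block = lines[k:k + step]
        ident, pop = block[0][0], block[0][1]
        if step == 2 and (block[1][0] != ident or block[1][1] != pop):
            raise FormatError(f"{path}: rows {k + 1}-{k + 2}: id/pop mismatch")
        try:
            if step == 2:
                a = [int(x) for x in block[0][2:]]
                b = [int(x) for x in block[1][2:]]
                geno = np.column_stack([a, b])
            else:
                flat = [int(x) for x in block[0][2:]]
                geno = np.array(flat).reshape(n_loci, 2)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer allele near line {k + 1}") from exc
        geno = np.where(geno == STRUCTURE_MISSING, MISSING, geno)
        inds.append(ident)
        pops.append(pop)
        calls.append(geno)
    return GenotypeMatrix(inds, np.array(pops, dtype=object),
                          [Locus(nm) for nm in locus_names], np.stack(calls))


def write_structure_format(gm: GenotypeMatrix, path,
                           rows_per_individual: int = 2) -> None:
    if rows_per_individual not in (1, 2):
        raise ValueError("rows_per_individual must be 1 or 2")
    out = np.where(gm.calls == MISSING, STRUCTURE_MISSING, gm.calls)
    with open(path, "w") as fh:
        fh.write(" ".join(lc.name for lc in gm.loci) + "\n")
        for i, ind in enumerate(gm.individuals):
            pop = gm.populations[i]
            if rows_per_individual == 2:
                for a in (0, 1):
                    vals = " ".join(str(v) for v in out[i, :, a])
                    fh.write(f"{ind} {pop} {vals}\n")
            else:
                vals = " ".join(str(v) for v in out[i].ravel())
                fh.write(f"{ind} {pop} {vals}\n")


# ---------------------------------------------------------------------------
# Site tables and Q-matrices
# ---------------------------------------------------------------------------

def validate_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Check a site table: index = population, lat/lon + six BIO columns."""
    required = ["lat", "lon"] + CLIMATE_COLUMNS
    missing = [c for c in required if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns {missing}")
    if not sites["lat"].between(-90, 90).all():
        raise ValueError("latitude outside [-90, 90]")
    if not sites["lon"].between(-180, 180).all():
        raise ValueError("longitude outside [-180, 180]")
    if not np.isfinite(sites[required].to_numpy(float)).all():
        raise ValueError("non-finite site values")
    return sites


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    return validate_site_table(df)


def write_site_table(sites: pd.DataFrame, path) -> None:
    validate_site_table(sites).rename_axis("pop").to_csv(path, sep="\t")


@dataclass
class QMatrix:
    """Individual ancestry proportions: rows sum to one over K clusters."""

    individuals: list[str]
    populations: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.populations = np.asarray(self.populations, dtype=object)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.individuals):
            raise ValueError("q must be individuals x K")
        if self.q.shape[1] < 1:
            raise ValueError("K >= 1 required")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("ancestry proportions must lie in [0, 1]")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each q row must sum to 1 +- 1e-6")

    @property
    def n_clusters(self) -> int:
        return self.q.shape[1]


def read_qmatrix(path) -> QMatrix:
    df = pd.read_csv(path, sep="\t")
    qcols = [c for c in df.columns if c.startswith("q_")]
    return QMatrix(df.iloc[:, 0].astype(str).tolist(),
                   df["pop"].to_numpy(dtype=object),
                   df[qcols].to_numpy(float))


def write_qmatrix(qm: QMatrix, path) -> None:
    df = pd.DataFrame({"individual": qm.individuals, "pop": qm.populations})
    for k in range(qm.n_clusters):
        df[f"q_{k + 1}"] = qm.q[:, k]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged reference table (printed per-population diversity summary)
# ---------------------------------------------------------------------------

def load_table1_fixture():
    """Packaged 29-population oak diversity summary.

    Returns ``(diversity, sites, qp)``: per-population diversity statistics
    (N, Na, Ne, I, Ho, He, PPL, FIS), a coordinate table (lat/lon only —
    climate is not part of the printed table), and the per-population
    proportion of genetically pure individuals (Qp).
    """
    ref = importlib.resources.files("msatpop") / "fixtures" / "table1.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t").set_index("pop")
    diversity = df[["N", "Na", "Ne", "I", "Ho", "He", "PPL", "FIS"]]
    sites = df[["lat", "lon"]]
    qp = df["Qp"]
    return diversity, sites, qp
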