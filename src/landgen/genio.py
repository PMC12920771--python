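"""Genotype, site-table and raster input/output.

Core containers for the pipeline:

* :class:`GenotypeMatrix` — diploid codominant calls (individuals x loci),
  population labels and projected site coordinates.
* :class:`ClassRaster` — categorical (integer-coded) landscape raster with a
  nodata mask, consumed by the conductance/commute machinery.

Supported formats: GenePop (2- or 3-digit allele dialects), a long CSV
(``individual,population,locus,a1,a2``), a sites CSV
(``site,name,area,n,x,y``) and ESRI ASCII grids.  Rasters must carry integer
class codes; GeoTIFF input is not supported and is rejected with an explicit
error.  Coordinates must be in a projected CRS (metres); values that look
like geographic lat/lon are rejected rather than treated as planar.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ClassRaster",
    "GenioError",
    "ParseError",
    "ValidationError",
    "read_genotypes",
    "write_genotypes",
    "read_sites",
    "write_sites",
    "read_class_raster",
    "write_class_raster",
    "missing_rate",
]

MISSING = 0  # allele code reserved for "no call"


class GenioError(Exception):
    """Base error for genotype/raster I/O."""


class ParseError(GenioError):
    """Malformed input file; message names the offending line."""


class ValidationError(GenioError):
    """Structurally valid file with inconsistent content."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid allele calls for a set of individuals at a set of loci.

    ``calls`` has shape (n_individuals, n_loci, 2) with positive-integer
    allele codes; ``0`` marks a missing allele.  A call with any missing
    allele is treated as fully missing (the diploid call is the
    observational unit), and pairs are unordered.
    """

    individuals: list[str]
    populations: dict[str, str]
    loci: list[str]
    calls: np.ndarray
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        missing_inds = [i for i in self.individuals if i not in self.populations]
        if missing_inds:
            raise ValidationError(f"individuals without population: {missing_inds[:5]}")
        # promote half-missing calls to fully missing; sort pairs (unordered)
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        self.calls = np.sort(self.calls, axis=2)

    # -- basic views -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def individuals_of(self, population: str) -> np.ndarray:
        """Row indices of the individuals belonging to *population*."""
        idx = [i for i, ind in enumerate(self.individuals)
               if self.populations[ind] == population]
        if not idx:
            raise KeyError(f"unknown population {population!r}")
        return np.asarray(idx, dtype=int)

    def pop_calls(self, population: str, locus: str) -> np.ndarray:
        """Non-missing (n, 2) calls for one population at one locus."""
        col = self.calls[self.individuals_of(population), self.locus_index(locus)]
        return col[col[:, 0] != MISSING]

    def subset_populations(self, keep: list[str]) -> "GenotypeMatrix":
        keep_set = set(keep)
        rows = [i for i, ind in enumerate(self.individuals)
                if self.populations[ind] in keep_set]
        inds = [self.individuals[i] for i in rows]
        return GenotypeMatrix(
            individuals=inds,
            populations={i: self.populations[i] for i in inds},
            loci=list(self.loci),
            calls=self.calls[rows].copy(),
            coords={p: xy for p, xy in self.coords.items() if p in keep_set},
        )

    def drop_loci(self, drop: list[str]) -> "GenotypeMatrix":
        drop_set = set(drop)
        keep = [j for j, l in enumerate(self.loci) if l not in drop_set]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            populations=dict(self.populations),
            loci=[self.loci[j] for j in keep],
            calls=self.calls[:, keep].copy(),
            coords=dict(self.coords),
        )


def missing_rate(gm: GenotypeMatrix, locus: str) -> float:
    """Fraction of individuals with a missing call at *locus* (in [0, 1])."""
    col = gm.calls[:, gm.locus_index(locus)]
    return float((col[:, 0] == MISSING).mean())


def _check_projected(coords: dict[str, tuple[float, float]]) -> None:
    """Reject coordinate sets that look like geographic lat/lon degrees."""
    if not coords:
        return
    xs = np.array([xy[0] for xy in coords.values()], float)
    ys = np.array([xy[1] for xy in coords.values()], float)
    if np.all(np.abs(xs) <= 180.0) and np.all(np.abs(ys) <= 90.0):
        raise ValidationError(
            "site coordinates fall inside lat/lon bounds; a projected CRS in "
            "metres is required (no reprojection is performed)"
        )


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def _parse_genepop_allele(tok: str, lineno: int) -> tuple[int, int]:
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise ParseError(f"line {lineno}: genotype token {tok!r} is not 4 or 6 digits")
    try:
        return int(tok[:w]), int(tok[w:])
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric genotype token {tok!r}") from None


def _read_genepop(text: str) -> GenotypeMatrix:
    lines = text.splitlines()
    if not [l for l in lines if l.strip()]:
        raise ParseError("line 1: empty GenePop file")
    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines):
        line = lines[i].strip()
        if line.lower() == "pop":
            break
        if line:
            loci.extend(t.strip() for t in line.split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"line {len(lines)}: no 'Pop' line found")
    if not loci:
        raise ParseError("line 2: no locus names before first 'Pop'")

    individuals: list[str] = []
    populations: dict[str, str] = {}
    calls: list[list[tuple[int, int]]] = []
    pop_counter = 0
    pop_label = ""
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_counter += 1
            pop_label = f"pop_{pop_counter}"
            continue
        if "," not in line:
            raise ParseError(f"line {lineno + 1}: expected '<id> , <genotypes>'")
        name, geno = line.split(",", 1)
        name = name.strip()
        if ":" in name:
            pop, ind = name.split(":", 1)
        else:
            pop, ind = pop_label, name
        toks = geno.split()
        if len(toks) != len(loci):
            raise ParseError(
                f"line {lineno + 1}: {len(toks)} genotypes for {len(loci)} loci"
            )
        if ind in populations:
            raise ValidationError(f"line {lineno + 1}: duplicate individual {ind!r}")
        individuals.append(ind)
        populations[ind] = pop
        calls.append([_parse_genepop_allele(t, lineno + 1) for t in toks])

    if not individuals:
        raise ParseError("no individuals after 'Pop' lines")
    return GenotypeMatrix(individuals, populations, loci, np.array(calls))


def _write_genepop(gm: GenotypeMatrix, title: str = "landgen export") -> str:
    width = 3 if gm.calls.max(initial=0) > 99 else 2
    out = [title]
    out.extend(gm.loci)
    fmt = f"%0{width}d%0{width}d"
    for pop in gm.pop_labels:
        out.append("Pop")
        for i in gm.individuals_of(pop):
            toks = [fmt % (a, b) for a, b in gm.calls[i]]
            out.append(f"{pop}:{gm.individuals[i]} ,  " + " ".join(toks))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# long CSV
# ---------------------------------------------------------------------------

_CSV_HEADER = ["individual", "population", "locus", "a1", "a2"]


def _read_csv_long(text: str) -> GenotypeMatrix:
    rows = list(csv.reader(io.StringIO(text)))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise ParseError("line 1: empty CSV file")
    header = [c.strip().lower() for c in rows[0]]
    if header != _CSV_HEADER:
        raise ParseError(f"line 1: expected header {','.join(_CSV_HEADER)}")
    individuals: list[str] = []
    populations: dict[str, str] = {}
    loci: list[str] = []
    data: dict[tuple[str, str], tuple[int, int]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 5:
            raise ParseError(f"line {lineno}: expected 5 fields, got {len(row)}")
        ind, pop, locus, a1, a2 = (c.strip() for c in row)
        try:
            pair = (int(a1 or 0), int(a2 or 0))
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer allele in {row}") from None
        if ind in populations and populations[ind] != pop:
            raise ValidationError(
                f"line {lineno}: individual {ind!r} assigned to two populations "
                f"({populations[ind]!r} and {pop!r})"
            )
        if ind not in populations:
            populations[ind] = pop
            individuals.append(ind)
        if locus not in loci:
            loci.append(locus)
        data[(ind, locus)] = pair
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    for (ind, locus), pair in data.items():
        calls[individuals.index(ind), loci.index(locus)] = pair
    return GenotypeMatrix(individuals, populations, loci, calls)


def _write_csv_long(gm: GenotypeMatrix) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_CSV_HEADER)
    for i, ind in enumerate(gm.individuals):
        for j, locus in enumerate(gm.loci):
            a, b = gm.calls[i, j]
            w.writerow([ind, gm.populations[ind], locus, int(a), int(b)])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# public genotype API
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "genepop",
                   exclude_loci: list[str] | None = None) -> GenotypeMatrix:
    """Read and validate a genotype file.

    Parameters
    ----------
    path : file to read.
    format : ``"genepop"`` or ``"csv"``.
    exclude_loci : locus names dropped after parsing (e.g. markers discarded
        for excess missing data or Hardy-Weinberg departures).
    """
    path = Path(path)
    if not path.exists():
        raise GenioError(f"no such file: {path}")
    text = path.read_text()
    if format == "genepop":
        gm = _read_genepop(text)
    elif format == "csv":
        gm = _read_csv_long(text)
    else:
        raise GenioError(f"unknown genotype format {format!r}")
    if exclude_loci:
        missing = set(exclude_loci) - set(gm.loci)
        if missing:
            raise ValidationError(f"exclude_loci not in file: {sorted(missing)}")
        gm = gm.drop_loci(list(exclude_loci))
    return gm


def write_genotypes(gm: GenotypeMatrix, path: str | Path,
                    format: str = "genepop") -> None:
    path = Path(path)
    if format == "genepop":
        path.write_text(_write_genepop(gm))
    elif format == "csv":
        path.write_text(_write_csv_long(gm))
    else:
        raise GenioError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------

def read_sites(path: str | Path, pop_min_n: int = 10,
               require_projected: bool = True) -> pd.DataFrame:
    """Read a sites CSV (``site,name,area,n,x,y``).

    Adds a ``role`` column: ``"population"`` where N > *pop_min_n*, else
    ``"locality"`` (sites with few genotypes are kept for structure analyses
    but excluded from pairwise differentiation).
    """
    df = pd.read_csv(path)
    expected = ["site", "name", "area", "n", "x", "y"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected header {','.join(expected)}")
    if df["site"].duplicated().any():
        dups = df.loc[df["site"].duplicated(), "site"].tolist()
        raise ValidationError(f"duplicate site IDs: {dups}")
    if require_projected:
        _check_projected({r.site: (r.x, r.y) for r in df.itertuples()})
    df["role"] = np.where(df["n"] > pop_min_n, "population", "locality")
    return df


def write_sites(df: pd.DataFrame, path: str | Path) -> None:
    df[["site", "name", "area", "n", "x", "y"]].to_csv(path, index=False)


def site_coords(df: pd.DataFrame, role: str | None = "population") -> dict:
    sub = df if role is None else df[df["role"] == role]
    return {r.site: (float(r.x), float(r.y)) for r in sub.itertuples()}


# ---------------------------------------------------------------------------
# rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

@dataclass
class ClassRaster:
    """Categorical raster: integer class codes on a regular grid.

    ``data`` is (nrows, ncols) int; cells where ``mask`` is False are nodata
    and never enter pixel graphs.  ``xll, yll`` are the coordinates of the
    lower-left corner (ESRI convention); ``origin`` exposes the upper-left.
    """

    data: np.ndarray
    mask: np.ndarray
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape or self.data.ndim != 2:
            raise GenioError("raster data and mask must be 2-D and congruent")
        if self.cellsize <= 0:
            raise GenioError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def origin(self) -> tuple[float, float]:
        """(x of left edge, y of top edge)."""
        return self.xll, self.yll + self.shape[0] * self.cellsize

    def classes(self) -> np.ndarray:
        return np.unique(self.data[self.mask])

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.shape[0]
        return (self.xll + (col + 0.5) * self.cellsize,
                self.yll + (nrows - 1 - row + 0.5) * self.cellsize)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.xll) / self.cellsize))
        row = self.shape[0] - 1 - int(np.floor((y - self.yll) / self.cellsize))
        return row, col


def read_class_raster(path: str | Path) -> ClassRaster:
    """Read an ESRI ASCII grid with integer class codes."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raise GenioError(
            "GeoTIFF input is not supported; convert the layer to an ESRI "
            "ASCII grid (.asc)"
        )
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ParseError(f"{path}: missing raster header field {key!r}")
    if not {"xllcorner", "xllcenter"} & header.keys():
        raise ParseError(f"{path}: missing georeferencing (xllcorner/yllcorner)")
    cell = header["cellsize"]
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cell / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cell / 2)
    nodata = int(header.get("nodata_value", -9999))
    raw = np.loadtxt(io.StringIO("\n".join(lines[body_start:])), ndmin=2)
    if raw.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ParseError(
            f"{path}: body shape {raw.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    if not np.all(raw == np.round(raw)):
        raise GenioError(f"{path}: raster band is not integer-valued")
    data = raw.astype(np.int64)
    mask = data != nodata
    return ClassRaster(data=data, mask=mask, cellsize=cell, xll=xll, yll=yll,
                       nodata=nodata)


def write_class_raster(raster: ClassRaster, path: str | Path) -> None:
    data = raster.data.copy()
    data[~raster.mask] = raster.nodata
    nrows, ncols = raster.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {raster.xll:.6f}\nyllcorner {raster.yll:.6f}\n"
        f"cellsize {raster.cellsize:.6f}\nNODATA_value {raster.nodata}\n"
    )
    body = "\n".join(" ".join(str(v) for v in row) for row in data)
    Path(path).write_text(header + body + "\n")


def write_float_raster(values: np.ndarray, like: ClassRaster,
                       path: str | Path, ndigits: int = 6) -> None:
    """Write a float surface (e.g. conductance) on the grid of *like*."""
    nrows, ncols = like.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {like.xll:.6f}\nyllcorner {like.yll:.6f}\n"
        f"cellsize {like.cellsize:.6f}\nNODATA_value {like.nodata}\n"
    )
    rows = []
    for r in range(nrows):
        toks = []
        for c in range(ncols):
            if like.mask[r, c]:
                toks.append(f"{values[r, c]:.{ndigits}g}")
            else:
                toks.append(str(like.nodata))
        rows.append(" ".join(toks))
    Path(path).write_text(header + "\n".join(rows) + "\n")
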