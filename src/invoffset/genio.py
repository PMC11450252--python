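"""Genotype, metadata, environment-table and raster input/output.

The pipeline's substrate is a samples x loci allele-dosage matrix read from a
VCF of biallelic SNPs (dosage = ALT-allele count, 0/1/2, NaN for missing),
together with a per-sample metadata table, per-population environmental
tables, and gridded environmental rasters stored as ESRI ASCII grids (one
grid per variable, shared geotransform).

Filtering mirrors sequential VCFtools-style calls on genotypes: minor-allele
count, per-site missingness, per-individual missingness, then one SNP per
locus.  Depth-based filters belong upstream of the genotype matrix and are
out of scope here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

STATUSES = ("native", "introduced", "farmed")

#: Default bioclimatic variable names (native-range climate predictors).
ENV_VARIABLES = ("AnnMeanTemp", "MinTemp", "MaxTemp", "TempSeason", "AnnPrec")


class VcfFormatError(ValueError):
    """Raised for malformed or unsupported VCF content."""


# --------------------------------------------------------------------------
# core containers
# --------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix with locus and sample annotation.

    ``dosages`` is float64 with values in {0, 1, 2} and NaN for missing
    genotypes.  ``locus_ids`` are unique per-SNP identifiers of the form
    ``"<locus_tag>_<snp_column>"`` (reduced-representation convention: one
    assembled locus may carry several SNP columns).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    chrom: list[str]
    pos: np.ndarray          # 1-based coordinates
    ref_alt: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.pos = np.asarray(self.pos, dtype=int)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.locus_ids) != m:
            raise ValueError("dosage dimensions do not match sample/locus ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids not unique")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus_ids not unique")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("non-missing dosages must be in {0,1,2}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def locus_tags(self) -> list[str]:
        """Locus tag (assembled-locus identifier) per SNP column."""
        return [_locus_tag(lid) for lid in self.locus_ids]

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[idx, :],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
        )

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.atleast_1d(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            locus_ids=[self.locus_ids[i] for i in idx],
            chrom=[self.chrom[i] for i in idx],
            pos=self.pos[idx],
            ref_alt=[self.ref_alt[i] for i in idx],
        )


def _locus_tag(locus_id: str) -> str:
    """STACKS-style ``<locus>_<column>`` -> ``<locus>``; otherwise the id."""
    m = re.match(r"^(.*)_(\d+)$", locus_id)
    return m.group(1) if m else locus_id


@dataclass
class SampleMetadata:
    """Per-sample table: sample_id, population_id, status, lon, lat."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "population_id", "status", "lon", "lat")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        bad = set(self.table["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")
        if not np.isfinite(self.table[["lon", "lat"]].to_numpy()).all():
            raise ValueError("non-finite coordinates in metadata")
        self.table = self.table.reset_index(drop=True)

    def validate_against(self, g: GenotypeMatrix) -> None:
        """Every genotyped sample must have exactly one metadata row."""
        counts = self.table["sample_id"].value_counts()
        missing = [s for s in g.sample_ids if s not in counts.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}...")

    def populations(self, g: GenotypeMatrix) -> pd.Series:
        """population_id aligned to ``g.sample_ids`` order."""
        lookup = self.table.set_index("sample_id")["population_id"]
        return lookup.reindex(g.sample_ids)

    def population_table(self) -> pd.DataFrame:
        """One row per population: status and mean coordinates."""
        return (
            self.table.groupby("population_id", sort=True)
            .agg(status=("status", "first"), lon=("lon", "mean"), lat=("lat", "mean"))
            .reset_index()
        )


@dataclass
class FilterConfig:
    """Genotype-level filters applied in a fixed order.

    min_mac: minimum minor-allele count per site (counted on non-missing
    alleles; minor allele is the less frequent of REF/ALT at the site).
    max_site_missing: remove sites genotyped in fewer than
    ``1 - max_site_missing`` of individuals.  max_indiv_missing: remove
    individuals missing more than this fraction of the remaining loci.
    one_snp_per_locus keeps the first SNP column per locus tag.
    """

    min_mac: int = 2
    max_site_missing: float = 0.2
    max_indiv_missing: float = 0.5
    one_snp_per_locus: bool = True

    def __post_init__(self) -> None:
        if self.min_mac < 0:
            raise ValueError("min_mac must be >= 0")
        for f in (self.max_site_missing, self.max_indiv_missing):
            if not 0.0 <= f <= 1.0:
                raise ValueError("missingness fractions must be in [0,1]")


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a dosage matrix.

    Dosage is the ALT-allele count per genotype; ``./.`` and half-calls
    become missing.  Multi-allelic records are rejected.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    ref_alt: list[tuple[str, str]] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise VcfFormatError(
                f"non-biallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); split or drop it upstream"
            )
        d = np.full(len(samples), np.nan)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:      # ./., half-calls -> missing
                continue
            d[i] = a + b
        lid = rec.ID if rec.ID not in (None, ".", "") else f"{rec.CHROM}_{rec.POS}"
        cols.append(d)
        locus_ids.append(lid)
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref_alt.append((rec.REF, rec.ALT[0]))
    vcf.close()
    if not cols:
        raise VcfFormatError(f"no records in {path}")
    g = GenotypeMatrix(
        dosages=np.column_stack(cols),
        sample_ids=samples,
        locus_ids=locus_ids,
        chrom=chrom,
        pos=np.array(pos),
        ref_alt=ref_alt,
    )
    logger.info("read %d samples x %d SNPs from %s", g.n_samples, g.n_loci, path)
    return g


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a minimal sites+GT VCF 4.2 file."""
    dos_to_gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j in range(g.n_loci):
            ref, alt = g.ref_alt[j]
            gts = "\t".join(
                "./." if np.isnan(d) else dos_to_gt[d] for d in g.dosages[:, j]
            )
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{g.locus_ids[j]}\t{ref}\t{alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# --------------------------------------------------------------------------
# filters
# --------------------------------------------------------------------------

def minor_allele_counts(dosages: np.ndarray) -> np.ndarray:
    """Per-site minor allele count over non-missing alleles."""
    alt = np.nansum(dosages, axis=0)
    n_alleles = 2 * np.sum(~np.isnan(dosages), axis=0)
    return np.minimum(alt, n_alleles - alt)


def apply_filters(g: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Apply genotype filters in the fixed documented order.

    (1) site MAC >= min_mac; (2) site missingness <= max_site_missing;
    (3) individual missingness <= max_indiv_missing (computed after the site
    filters, mirroring sequential filtering runs); (4) first SNP per locus
    tag.  Returns a new matrix; the input is never mutated.
    """
    mac = minor_allele_counts(g.dosages)
    keep = mac >= cfg.min_mac
    g2 = g.take_loci(np.flatnonzero(keep))
    logger.info("MAC filter: %d -> %d loci", g.n_loci, g2.n_loci)

    if g2.n_loci:
        site_miss = np.mean(np.isnan(g2.dosages), axis=0)
        g2 = g2.take_loci(np.flatnonzero(site_miss <= cfg.max_site_missing))
    if g2.n_loci:
        indiv_miss = np.mean(np.isnan(g2.dosages), axis=1)
        g2 = g2.take_samples(np.flatnonzero(indiv_miss <= cfg.max_indiv_missing))

    if cfg.one_snp_per_locus and g2.n_loci:
        seen: set[str] = set()
        keep_idx = []
        for j, tag in enumerate(g2.locus_tags()):
            if tag not in seen:
                seen.add(tag)
                keep_idx.append(j)
        g2 = g2.take_loci(np.array(keep_idx, dtype=int))

    if g2.n_loci == 0:
        logger.warning("all loci removed by filters")
    logger.info("filters retained %d samples x %d loci", g2.n_samples, g2.n_loci)
    return g2


# --------------------------------------------------------------------------
# metadata / environment tables
# --------------------------------------------------------------------------

def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t")
    logger.info("read %d metadata rows from %s", len(df), path)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Per-population environmental table, indexed by population_id."""
    df = pd.read_csv(path, sep="\t")
    if "population_id" not in df.columns:
        raise ValueError("env table requires a population_id column")
    df = df.set_index("population_id")
    logger.info("read env table: %d sites x %d variables", *df.shape)
    return df


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t", index=True, index_label="population_id")


# --------------------------------------------------------------------------
# rasters (ESRI ASCII grid dialect)
# --------------------------------------------------------------------------

@dataclass
class EnvRaster:
    """Named stack of 2-D grids sharing one geotransform.

    Grids are float arrays with NaN for nodata; row 0 is the northernmost
    row (ASCII-grid convention).  ``xll``/``yll`` are the lower-left corner
    coordinates and ``cellsize`` the square pixel width in degrees.
    """

    grids: dict[str, np.ndarray]
    xll: float
    yll: float
    cellsize: float

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.grids.values()}
        if len(shapes) > 1:
            raise ValueError(f"raster grids have mismatched shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.grids.values())).shape

    @property
    def variables(self) -> list[str]:
        return list(self.grids)

    def pixel_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the pixel containing the point; clipped to grid."""
        nrows, ncols = self.shape
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cellsize))
        row = nrows - 1 - row_from_bottom
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({lon}, {lat}) off raster")
        return row, col

    def extract(self, lon: float, lat: float) -> dict[str, float]:
        """Environmental values at the pixel containing (lon, lat)."""
        r, c = self.pixel_of(lon, lat)
        return {name: float(grid[r, c]) for name, grid in self.grids.items()}


_NODATA = -9999.0


def write_ascii_grid(grid: np.ndarray, xll: float, yll: float, cellsize: float,
                     path: str | Path) -> None:
    nrows, ncols = grid.shape
    out = np.where(np.isnan(grid), _NODATA, grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {xll}\nyllcorner {yll}\n")
        fh.write(f"cellsize {cellsize}\nNODATA_value {_NODATA}\n")
        for row in out:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    grid = np.loadtxt(lines[6:])
    grid = np.atleast_2d(grid)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {grid.shape} disagrees with header")
    nodata = header.get("nodata_value", _NODATA)
    grid = np.where(grid == nodata, np.nan, grid)
    return grid, header["xllcorner"], header["yllcorner"], header["cellsize"]


def read_raster_stack(paths: dict[str, str | Path]) -> EnvRaster:
    """Read one ASCII grid per variable into a stacked EnvRaster."""
    grids: dict[str, np.ndarray] = {}
    geo: tuple[float, float, float] | None = None
    for name, p in paths.items():
        grid, xll, yll, cs = read_ascii_grid(p)
        if geo is None:
            geo = (xll, yll, cs)
        elif geo != (xll, yll, cs):
            raise ValueError(f"raster {name} has a different geotransform")
        grids[name] = grid
    if geo is None:
        raise ValueError("no raster paths given")
    logger.info("read raster stack: %d variables, shape %s",
                len(grids), next(iter(grids.values())).shape)
    return EnvRaster(grids, *geo)


def write_raster_stack(raster: EnvRaster, outdir: str | Path,
                       prefix: str = "env") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, grid in raster.grids.items():
        p = outdir / f"{prefix}_{name}.asc"
        write_ascii_grid(grid, raster.xll, raster.yll, raster.cellsize, p)
        paths[name] = p
    return paths
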