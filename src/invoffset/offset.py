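"""Genotype-environment index extrapolation and genomic offset.

The index projects a pixel's standardized climate onto the
environmental-variable scores of the first axis of the adaptively enriched
RDA: index(pixel) = sum_j score_j * (env_j - mean_j) / sd_j, with means and
sds taken over the native range (the ordination was fit on native data, so
the index stays comparable between maps).  A pixel matching the native-mean
climate scores exactly 0, and the index is linear in each standardized
variable.

The genomic offset of an introduced population is the absolute index
difference between the pixel where it was introduced and the pixel of its
most closely related native population (argmin pairwise Fst).  A small
offset means the source genotype already occurs under a similar climate; a
large one flags an adaptive mismatch.  Offsets are ranked into
Low/Medium/High by empirical tertiles (or user-supplied fixed breaks).

A reference table of published offsets for 40 introduced tench populations
ships with the package for desk checks (``load_reference_offsets``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .gea import Standardization
from .genio import EnvRaster, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class AdaptiveIndexRaster:
    """Genotype-environment index grid sharing the EnvRaster geotransform."""

    grid: np.ndarray
    xll: float
    yll: float
    cellsize: float
    axis: str = "RDA1"

    def at(self, lon: float, lat: float) -> float:
        r = EnvRaster({"index": self.grid}, self.xll, self.yll, self.cellsize)
        return r.extract(lon, lat)["index"]


def adaptive_index(env_scores: pd.Series, raster: EnvRaster,
                   standardization: Standardization,
                   axis: str = "RDA1") -> AdaptiveIndexRaster:
    """Extrapolate axis scores over a climate raster.

    ``env_scores`` holds one score per environmental variable (the axis-1
    column of the enriched RDA's variable scores); every scored variable
    must be present in the raster stack.  Nodata pixels propagate.
    """
    missing = [v for v in env_scores.index if v not in raster.grids]
    if missing:
        raise ValueError(f"variables missing from raster: {missing}")
    idx = np.zeros(raster.shape)
    for var, score in env_scores.items():
        z = (raster.grids[var] - standardization.mean[var]) \
            / standardization.sd[var]
        idx = idx + score * z
    return AdaptiveIndexRaster(grid=idx, xll=raster.xll, yll=raster.yll,
                               cellsize=raster.cellsize, axis=axis)


def nearest_native_source(fst: pd.DataFrame,
                          meta: SampleMetadata) -> dict[str, str]:
    """Map each introduced population to the native population with the
    smallest pairwise Fst; ties break to the lexicographically first
    native population id (logged)."""
    pops = meta.population_table()
    natives = sorted(pops.loc[pops["status"] == "native", "population_id"])
    introduced = sorted(pops.loc[pops["status"] == "introduced",
                                 "population_id"])
    if not natives:
        raise ValueError("no native populations in metadata")
    mapping: dict[str, str] = {}
    for pop in introduced:
        row = fst.loc[pop, natives]
        if row.isna().all():
            raise ValueError(f"no defined Fst between {pop} and any native "
                             "population")
        best = row.min()
        winners = sorted(row.index[row == best])
        if len(winners) > 1:
            logger.warning("Fst tie for %s among %s; choosing %s", pop,
                           winners, winners[0])
        mapping[pop] = winners[0]
    return mapping


def genetic_offset(idx: AdaptiveIndexRaster, mapping: dict[str, str],
                   meta: SampleMetadata) -> pd.DataFrame:
    """Offset table: |index(introduced pixel) - index(source pixel)| per
    introduced population, with the signed difference retained."""
    pops = meta.population_table().set_index("population_id")
    rows = []
    for intro, src in sorted(mapping.items()):
        vi = idx.at(pops.loc[intro, "lon"], pops.loc[intro, "lat"])
        vs = idx.at(pops.loc[src, "lon"], pops.loc[src, "lat"])
        if np.isnan(vi) or np.isnan(vs):
            raise ValueError(f"nodata index pixel for {intro} or {src}")
        rows.append((intro, src, abs(vi - vs), vi - vs))
    return pd.DataFrame(
        rows, columns=["introduced_population", "source_population",
                       "offset", "signed_offset"],
    ).set_index("introduced_population")


def classify_offsets(offsets: pd.Series, mode: str = "quantile",
                     breaks: tuple[float, float] | None = None) -> pd.Series:
    """Label offsets Low/Medium/High.

    ``quantile`` mode uses empirical tertiles of the offset vector (Low =
    lowest third); ``fixed`` mode uses user-supplied increasing breakpoints
    (lo, hi).  Values tied with a breakpoint fall into the lower class.
    """
    offsets = pd.Series(offsets, dtype=float)
    if mode == "quantile":
        if len(offsets) < 3:
            raise ValueError("quantile mode needs >= 3 offsets")
        lo, hi = np.quantile(offsets, [1 / 3, 2 / 3])
        if lo == hi:
            logger.warning("degenerate offset distribution; all Low")
    elif mode == "fixed":
        if breaks is None or not breaks[0] < breaks[1]:
            raise ValueError("fixed mode needs increasing (lo, hi) breaks")
        lo, hi = breaks
    else:
        raise ValueError(f"unknown classification mode: {mode}")
    labels = pd.Series("Medium", index=offsets.index, name="class")
    labels[offsets <= lo] = "Low"
    labels[offsets > hi] = "High"
    return labels


def count_below(offsets, threshold: float) -> int:
    """Number of offsets strictly below the threshold."""
    if not np.isfinite(threshold) and not np.isposinf(threshold):
        raise ValueError("threshold must be finite or +inf")
    return int(np.sum(np.asarray(offsets, dtype=float) < threshold))


def load_reference_offsets() -> pd.DataFrame:
    """The packaged reference offsets for 40 introduced tench populations
    (introduced population, Fst-nearest native source, offset, class)."""
    with resources.files("invoffset.data").joinpath(
            "tench_introduced_offsets.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
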