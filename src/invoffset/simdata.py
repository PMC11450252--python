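"""Synthetic genotype/environment data with the structure the analysis assumes.

The generator emulates a species whose native range was recolonized from two
glacial refugia: two ancestral clusters diverged under drift
(Balding-Nichols model with divergence parameter F), native populations sit
on a longitudinal admixture cline between them (admixture proportion q_W to
the western cluster), a subset of "adaptive" loci track a focal bioclimatic
variable on the logit scale, and introduced populations are founded by small
samples drawn from a named native source.  Farmed populations are admixed
stocks placed at arbitrary locations.

Every downstream stage (diversity, ancestry, Fst, genotype-environment
association, offset) can therefore be tested against recorded ground truth.
Randomness derives from a single seed through a documented stream-splitting
scheme so stages can be re-simulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import ENV_VARIABLES, EnvRaster, GenotypeMatrix, SampleMetadata

FOCAL_VARIABLE = "MinTemp"


@dataclass
class SimConfig:
    """Study conditions for the synthetic range.

    Defaults mirror the sampled design the pipeline targets: 36 native,
    40 introduced and 19 farmed populations, ~8 samples per population,
    thousands of biallelic SNPs with ~6% missing genotypes, moderate
    refugial divergence, and introductions founded by 10 diploids.
    """

    n_native_pops: int = 36
    n_introduced_pops: int = 40
    n_farmed_pops: int = 19
    samples_per_pop: int = 8
    n_loci: int = 2000
    n_adaptive_loci: int = 60
    fst_divergence: float = 0.15
    env_effect: float = 1.0
    founder_size: int = 10
    missing_rate: float = 0.06
    raster_shape: tuple[int, int] = (50, 50)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_native_pops", "n_introduced_pops", "n_farmed_pops",
                     "samples_per_pop", "n_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.fst_divergence < 1.0:
            raise ValueError("fst_divergence must be in (0,1)")
        if self.founder_size < 1:
            raise ValueError("founder_size must be >= 1")
        if self.n_adaptive_loci > self.n_loci:
            raise ValueError("more adaptive loci than loci")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    true_q: pd.Series                 # per-sample ancestry to the W cluster
    pop_q: pd.Series                  # per-population ancestry
    adaptive_locus_ids: list[str]
    source_of: dict[str, str]         # introduced pop -> native source pop
    pop_freqs: pd.DataFrame           # population x locus expected frequencies
    focal_variable: str = FOCAL_VARIABLE
    adaptive_effects: pd.Series = field(default_factory=pd.Series)


def expected_founder_retention(founder_size: int) -> float:
    """Expected fraction of source heterozygosity retained after a founder
    event of ``founder_size`` diploids: 1 - 1/(2N)."""
    if founder_size < 1:
        raise ValueError("founder_size must be >= 1")
    return 1.0 - 1.0 / (2.0 * founder_size)


def founder_retention_simulation(founder_size: int, n_loci: int = 500,
                                 n_reps: int = 200, maf_min: float = 0.05,
                                 seed: int = 0) -> float:
    """Mean simulated He retention over replicate founder events.

    Source allele frequencies are uniform with minor-allele frequency above
    ``maf_min``; each replicate draws ``2*founder_size`` gene copies per
    locus and compares post-founding expected heterozygosity 2p(1-p) with
    the source value.  Returns the mean over replicates of the per-replicate
    He ratio (introduced / source).
    """
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_reps)
    for r in range(n_reps):
        p = rng.uniform(maf_min, 1.0 - maf_min, size=n_loci)
        x = rng.binomial(2 * founder_size, p)
        pf = x / (2.0 * founder_size)
        ratios[r] = np.mean(2 * pf * (1 - pf)) / np.mean(2 * p * (1 - p))
    return float(ratios.mean())


def _balding_nichols(rng: np.random.Generator, p0: np.ndarray,
                     F: float) -> np.ndarray:
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    return rng.beta(a, b)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_raster(cfg: SimConfig, rng: np.random.Generator) -> EnvRaster:
    """Smooth synthetic bioclim gradients on a small grid.

    Longitude spans 10 degrees, latitude 10 degrees.  The focal variable
    (annual mean temperature) increases eastward so it is collinear with the
    refugial cline, as in a real postglacial range; the remaining variables
    mix longitude, latitude and a sinusoid so the stack is correlated but
    not degenerate.
    """
    nrows, ncols = cfg.raster_shape
    xll, yll, cs = 0.0, 40.0, 10.0 / ncols
    lon = xll + (np.arange(ncols) + 0.5) * cs
    lat_desc = yll + 10.0 - (np.arange(nrows) + 0.5) * (10.0 / nrows)
    LON, LAT = np.meshgrid(lon, lat_desc)
    u = (LON - xll) / 10.0              # 0 (west) .. 1 (east)
    v = (LAT - yll) / 10.0
    # Distinct spatial structures keep pairwise correlations below the
    # |r| < 0.7 screen the association stage enforces.  Annual mean
    # temperature runs along the longitudinal expansion axis, so climate is
    # partially confounded with the refugial cline (as in a real postglacial
    # range); the focal selective driver, winter minimum temperature, is
    # latitudinal and therefore identifiable against that cline.
    grids = {
        "AnnMeanTemp": 6.0 + 6.0 * u + 1.2 * np.cos(2 * np.pi * v),
        "MinTemp": -4.0 - 6.0 * v,
        "MaxTemp": 22.0 + 120.0 * (v - 0.5) ** 2 - 1.5 * u,
        "TempSeason": 15.0 + 12.0 * (u - 0.5) ** 2 + 2.0 * v,
        "AnnPrec": 900.0 + 400.0 * (u - 0.5) * (v - 0.5),
    }
    return EnvRaster(grids, xll=xll, yll=yll, cellsize=cs)


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, SampleMetadata,
                                              pd.DataFrame, EnvRaster, SimTruth]:
    """Generate genotypes, metadata, environment table, raster and truth.

    Neutral loci: ancestral frequency p0 ~ U(0.05, 0.95); cluster
    frequencies from Balding-Nichols(p0, F); population frequency is the
    q_W-weighted mixture.  Adaptive loci get an additional logit-scale shift
    of ``env_effect * sign_l * z`` where z is the focal variable
    standardized over native populations and sign_l is a random per-locus
    direction.  Introduced populations resample their source through
    ``2*founder_size`` gene copies.  Fully reproducible from cfg.seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_freq, r_geno, r_place, r_intro, r_miss = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    raster = make_raster(cfg, r_place)
    nrows, ncols = raster.shape

    # --- native populations on a west-east cline ---------------------------
    n_nat = cfg.n_native_pops
    native_ids = [f"N{i:02d}" for i in range(1, n_nat + 1)]
    # west (q_W=1) to east, with jitter so the cline is monotone in
    # longitude but not an exact affine function of it
    q_w = np.clip(np.linspace(1.0, 0.0, n_nat)
                  + r_place.normal(0.0, 0.04, size=n_nat), 0.0, 1.0)
    lon_frac = np.linspace(0.03, 0.97, n_nat)     # matching longitudes
    native_lon = raster.xll + lon_frac * 10.0
    native_lat = raster.yll + r_place.uniform(0.5, 9.5, size=n_nat)

    # --- environment -------------------------------------------------------
    # population-site values are the raster climatology plus a small local
    # (microclimate) deviation, so site climate is correlated with, but not
    # an exact function of, the coordinates
    grid_sd = {k: float(np.nanstd(v)) for k, v in raster.grids.items()}

    def env_at(lon: float, lat: float) -> dict[str, float]:
        vals = raster.extract(lon, lat)
        return {k: v + r_place.normal(0.0, 0.05 * grid_sd[k])
                for k, v in vals.items()}

    env_rows = {pid: env_at(lo, la)
                for pid, lo, la in zip(native_ids, native_lon, native_lat)}

    # --- allele frequencies ------------------------------------------------
    L = cfg.n_loci
    p0 = r_freq.uniform(0.05, 0.95, size=L)
    p_e = _balding_nichols(r_freq, p0, cfg.fst_divergence)
    p_w = _balding_nichols(r_freq, p0, cfg.fst_divergence)
    pop_p = np.clip(
        q_w[:, None] * p_w[None, :] + (1 - q_w)[:, None] * p_e[None, :],
        1e-4, 1 - 1e-4,
    )

    adaptive_idx = np.sort(r_freq.choice(L, size=cfg.n_adaptive_loci,
                                         replace=False))
    signs = r_freq.choice([-1.0, 1.0], size=cfg.n_adaptive_loci)
    focal = np.array([env_rows[p][FOCAL_VARIABLE] for p in native_ids])
    z = (focal - focal.mean()) / focal.std()
    shift = cfg.env_effect * z[:, None] * signs[None, :]
    pop_p[:, adaptive_idx] = np.clip(
        _expit(_logit(pop_p[:, adaptive_idx]) + shift), 1e-4, 1 - 1e-4)

    locus_ids = [f"L{l}_1" for l in range(L)]

    # --- introduced populations via founder events -------------------------
    n_int = cfg.n_introduced_pops
    intro_ids = [f"I{i:02d}" for i in range(1, n_int + 1)]
    source_of: dict[str, str] = {}
    intro_p = np.empty((n_int, L))
    for i, pid in enumerate(intro_ids):
        src = int(r_intro.integers(n_nat))
        source_of[pid] = native_ids[src]
        x = r_intro.binomial(2 * cfg.founder_size, pop_p[src])
        intro_p[i] = np.clip(x / (2.0 * cfg.founder_size), 0.0, 1.0)
    intro_lon = raster.xll + r_place.uniform(0.2, 9.8, size=n_int)
    intro_lat = raster.yll + r_place.uniform(0.2, 9.8, size=n_int)
    for pid, lo, la in zip(intro_ids, intro_lon, intro_lat):
        env_rows[pid] = env_at(lo, la)

    # --- farmed stocks: admixed, arbitrary locations -----------------------
    n_farm = cfg.n_farmed_pops
    farm_ids = [f"F{i:02d}" for i in range(1, n_farm + 1)]
    farm_q = r_intro.uniform(0.0, 1.0, size=n_farm)
    farm_p = np.clip(farm_q[:, None] * p_w + (1 - farm_q)[:, None] * p_e,
                     1e-4, 1 - 1e-4)
    farm_lon = raster.xll + r_place.uniform(0.2, 9.8, size=n_farm)
    farm_lat = raster.yll + r_place.uniform(0.2, 9.8, size=n_farm)
    for pid, lo, la in zip(farm_ids, farm_lon, farm_lat):
        env_rows[pid] = env_at(lo, la)

    # --- genotypes ---------------------------------------------------------
    all_ids = native_ids + intro_ids + farm_ids
    all_p = np.vstack([pop_p, intro_p, farm_p])
    all_q = np.concatenate([q_w, np.array([q_w[native_ids.index(source_of[p])]
                                           for p in intro_ids]), farm_q])
    all_lon = np.concatenate([native_lon, intro_lon, farm_lon])
    all_lat = np.concatenate([native_lat, intro_lat, farm_lat])
    statuses = (["native"] * n_nat + ["introduced"] * n_int
                + ["farmed"] * n_farm)

    rows, sample_ids, meta_rows = [], [], []
    truth_q = []
    for pid, p, q, st, lo, la in zip(all_ids, all_p, all_q, statuses,
                                     all_lon, all_lat):
        d = r_geno.binomial(2, p, size=(cfg.samples_per_pop, L)).astype(float)
        rows.append(d)
        for s in range(cfg.samples_per_pop):
            sid = f"{pid}_s{s:02d}"
            sample_ids.append(sid)
            meta_rows.append((sid, pid, st, lo, la))
            truth_q.append(q)
    dosages = np.vstack(rows)
    if cfg.missing_rate > 0:
        mask = r_miss.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    g = GenotypeMatrix(
        dosages=dosages,
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        chrom=["1"] * L,
        pos=np.arange(1, L + 1) * 100,
        ref_alt=[("A", "G")] * L,
    )
    meta = SampleMetadata(pd.DataFrame(
        meta_rows, columns=["sample_id", "population_id", "status", "lon", "lat"]))
    env = pd.DataFrame.from_dict(env_rows, orient="index")[list(ENV_VARIABLES)]
    env.index.name = "population_id"

    truth = SimTruth(
        true_q=pd.Series(truth_q, index=sample_ids, name="q_W"),
        pop_q=pd.Series(all_q, index=all_ids, name="q_W"),
        adaptive_locus_ids=[locus_ids[j] for j in adaptive_idx],
        source_of=source_of,
        pop_freqs=pd.DataFrame(all_p, index=all_ids, columns=locus_ids),
        adaptive_effects=pd.Series(cfg.env_effect * signs,
                                   index=[locus_ids[j] for j in adaptive_idx]),
    )
    return g, meta, env, raster, truth
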