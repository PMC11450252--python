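"""End-to-end orchestration: filter -> diversity -> structure ->
differentiation -> genotype-environment association -> offset.

A run consumes either file inputs (VCF + metadata + env table + rasters)
or a simulate block, executes the stages in dependency order, writes each
stage's outputs under the run directory and records a manifest (config,
seeds, input hashes, outputs) so deterministic artifacts can be audited.

Note the one ordering subtlety: diversity *metrics* only need genotypes,
but the diversity *models* regress on ancestry, so the model fit happens
after the structure stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differentiation, gea, genio, offset, popdiv, simdata, structure

logger = logging.getLogger(__name__)

STAGES = ("filter", "diversity", "structure", "fst", "gea", "offset")


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of ``inputs``/``simulate`` is active."""

    outdir: str = "invoffset_run"
    seed: int = 0
    inputs: dict | None = None          # vcf, metadata, env_table, rasters
    simulate: dict = field(default_factory=dict)   # SimConfig overrides
    filter: dict = field(default_factory=dict)     # FilterConfig fields
    structure: dict = field(default_factory=dict)  # K, cv_K_list, mask_fraction, n_folds
    gea: dict = field(default_factory=dict)        # n_latent, sd, permutations, q_threshold, mode
    offset: dict = field(default_factory=dict)     # mode, breaks
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if self.inputs is not None and self.simulate:
            raise ValueError("give either file inputs or a simulate block")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    if cfg.inputs is not None:
        paths = cfg.inputs
        for key in ("vcf", "metadata", "env_table"):
            if key not in paths:
                raise FileNotFoundError(f"config inputs missing '{key}'")
            if not Path(paths[key]).exists():
                raise FileNotFoundError(f"input file not found: {paths[key]}")
        g = genio.read_vcf(paths["vcf"])
        meta = genio.read_metadata(paths["metadata"])
        env = genio.read_env_table(paths["env_table"])
        raster = genio.read_raster_stack(
            {k: v for k, v in paths.get("rasters", {}).items()})
        truth = None
    else:
        sim_cfg = simdata.SimConfig(**{"seed": cfg.seed, **cfg.simulate})
        g, meta, env, raster, truth = simdata.simulate_dataset(sim_cfg)
    meta.validate_against(g)
    return g, meta, env, raster, truth


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {**asdict(cfg), "stages": list(cfg.stages)},
                      "outputs": {}, "inputs": {}}

    g, meta, env, raster, truth = _load_inputs(cfg)
    if cfg.inputs:
        manifest["inputs"] = {k: _sha256(Path(v))
                              for k, v in cfg.inputs.items()
                              if isinstance(v, str) and Path(v).exists()}
    groups = meta.populations(g)
    pops = meta.population_table().set_index("population_id")

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    # ---- filter -----------------------------------------------------------
    if "filter" in cfg.stages:
        fcfg = genio.FilterConfig(**cfg.filter)
        g = genio.apply_filters(g, fcfg)
        groups = meta.populations(g)
        emit("filtered.vcf", lambda p: genio.write_vcf(g, p))

    # ---- structure --------------------------------------------------------
    qw_pop = None
    if "structure" in cfg.stages:
        scfg = cfg.structure
        K = int(scfg.get("K", 2))
        anc = structure.estimate_ancestry(g, K=K, seed=cfg.seed,
                                          max_iter=int(scfg.get("max_iter", 300)))
        emit("ancestry.Q", lambda p: structure.write_q_matrix(anc, p))
        emit("ancestry.P", lambda p: structure.write_p_matrix(anc, p))
        if scfg.get("cv_K_list"):
            cv = structure.cross_validate_K(
                g, scfg["cv_K_list"],
                mask_fraction=float(scfg.get("mask_fraction", 0.1)),
                n_folds=int(scfg.get("n_folds", 3)), seed=cfg.seed)
            emit("cv_errors.tsv", lambda p: pd.Series(cv.errors).rename_axis(
                "K").to_frame("masked_mse").to_csv(p, sep="\t"))
        scores, expl = structure.pca_genotypes(g, n_axes=4)
        emit("pca_scores.tsv", lambda p: pd.DataFrame(
            scores, index=g.sample_ids,
            columns=[f"PC{i+1}" for i in range(scores.shape[1])]
        ).to_csv(p, sep="\t"))
        # per-population mean ancestry to the first cluster
        q1 = pd.Series(anc.Q[:, 0], index=g.sample_ids)
        qw_pop = q1.groupby(groups).mean()
        manifest["structure"] = {"K": K, "loglik": anc.loglik,
                                 "converged": anc.converged}

    # ---- diversity --------------------------------------------------------
    if "diversity" in cfg.stages:
        div = popdiv.diversity_metrics(g, groups)
        emit("diversity.tsv", lambda p: div.to_csv(p, sep="\t"))
        if qw_pop is not None:
            fits = popdiv.fit_diversity_models(
                div, qw_pop.reindex(div.index),
                pops["status"].reindex(div.index))
            summary = pd.DataFrame({
                m: {"status_stat": f.status_stat, "status_p": f.status_p,
                    "ancestry_stat": f.ancestry_stat,
                    "ancestry_p": f.ancestry_p}
                for m, f in fits.items()}).T
            emit("diversity_models.tsv", lambda p: summary.to_csv(p, sep="\t"))

    # ---- differentiation --------------------------------------------------
    fst = None
    if "fst" in cfg.stages:
        fst = differentiation.pairwise_fst(g, groups)
        betas = differentiation.population_specific_fst(g, groups)
        emit("pairwise_fst.tsv", lambda p: fst.to_csv(p, sep="\t"))
        emit("beta_fst.tsv", lambda p: betas.to_csv(p, sep="\t"))
        if fst.shape[0] >= 3:
            tree = differentiation.nj_tree(fst, impute_mean=True)
            emit("nj_tree.nwk",
                 lambda p: Path(p).write_text(tree.to_newick()))
            mds = differentiation.classical_mds(fst.fillna(fst.mean().mean()))
            emit("mds_scores.tsv", lambda p: mds.to_csv(p, sep="\t"))

    # ---- genotype-environment association ---------------------------------
    enriched = None
    std = None
    if "gea" in cfg.stages:
        gcfg = cfg.gea
        native = pops.index[pops["status"] == "native"]
        env_native = env.loc[[p for p in env.index if p in set(native)]]
        env_std, std = gea.standardize_env(env_native)
        # individual-level scan on native samples
        nat_rows = np.array([i for i, s in enumerate(g.sample_ids)
                             if groups[s] in set(native)])
        g_nat = g.take_samples(nat_rows)
        env_per_sample = env_std.loc[
            [groups[s] for s in g_nat.sample_ids]].reset_index(drop=True)
        scan = gea.lfmm_scan(g_nat, env_per_sample,
                             n_latent=int(gcfg.get("n_latent", 2)),
                             seed=cfg.seed)
        emit("lfmm_q.tsv", lambda p: scan.q.to_csv(p, sep="\t"))
        # population-level pRDA
        freqs = popdiv.allele_frequencies(g_nat, groups.loc[g_nat.sample_ids])
        freqs = freqs.reindex(env_std.index)
        if qw_pop is None:      # gea without the structure stage: fit here
            anc = structure.estimate_ancestry(g, K=2, seed=cfg.seed,
                                              max_iter=300)
            q1 = pd.Series(anc.Q[:, 0], index=g.sample_ids)
            qw_pop = q1.groupby(groups).mean()
        cond = pops.loc[env_std.index, ["lon", "lat"]].copy()
        cond["qW"] = qw_pop.reindex(env_std.index)
        part = gea.variance_partition(
            freqs, env_std, pops.loc[env_std.index, ["lon", "lat"]],
            cond[["qW"]])
        emit("variance_partition.tsv",
             lambda p: part.as_table().to_csv(p, sep="\t"))
        pr = gea.prda(freqs, env_std, cond,
                      n_permutations=int(gcfg.get("permutations", 199)),
                      seed=cfg.seed)
        rda_out = gea.rda_outliers(pr, axis=1, sd=float(gcfg.get("sd", 2.5)))
        lfmm_out = scan.candidates(float(gcfg.get("q_threshold", 0.1)))
        cands = gea.combine_candidates(lfmm_out, rda_out)
        chosen = (cands.shared if gcfg.get("mode") == "intersection"
                  else cands.combined)
        manifest["gea"] = {
            "n_lfmm": len(cands.lfmm_loci), "n_rda": len(cands.rda_loci),
            "n_shared": len(cands.shared), "n_combined": len(cands.combined),
            "prda_p": pr.perm_p,
        }
        if chosen:
            enriched = gea.enriched_rda(freqs, env_std, chosen)
            sv = gea.strongest_variable(freqs, env_std, chosen)
            emit("candidates.tsv", lambda p: sv.rename_axis("locus_id")
                 .to_frame().to_csv(p, sep="\t"))
        else:
            logger.warning("no candidate loci; offset stage will be skipped")

    # ---- offset -----------------------------------------------------------
    if "offset" in cfg.stages and enriched is not None and fst is not None:
        ocfg = cfg.offset
        idx = offset.adaptive_index(enriched.env_scores["RDA1"], raster, std)
        emit("adaptive_index.asc", lambda p: genio.write_ascii_grid(
            idx.grid, idx.xll, idx.yll, idx.cellsize, p))
        mapping = offset.nearest_native_source(fst, meta)
        table = offset.genetic_offset(idx, mapping, meta)
        table["class"] = offset.classify_offsets(
            table["offset"], mode=ocfg.get("mode", "quantile"),
            breaks=tuple(ocfg["breaks"]) if ocfg.get("breaks") else None)
        emit("offsets.tsv", lambda p: table.to_csv(p, sep="\t"))
        manifest["offset"] = {"n_introduced": len(table),
                              "median_offset": float(table["offset"].median())}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
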