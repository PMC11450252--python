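"""Genotype-environment association: latent-factor scan, pRDA, partitioning."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invoffset import gea, popdiv, simdata


def _native_pieces(cfg):
    g, meta, env, raster, truth = simdata.simulate_dataset(cfg)
    groups = meta.populations(g)
    native = [p for p in env.index if p.startswith("N")]
    rows = np.array([i for i, s in enumerate(g.sample_ids)
                     if groups[s] in set(native)])
    g_nat = g.take_samples(rows)
    env_std, std = gea.standardize_env(env.loc[native])
    freqs = popdiv.allele_frequencies(
        g_nat, groups.loc[g_nat.sample_ids]).reindex(env_std.index)
    pops = meta.population_table().set_index("population_id")
    return g_nat, groups, env_std, std, freqs, pops, truth


class TestStandardization:
    def test_standardized_columns_centred_scaled(self, small_sim):
        _, _, env, _, _ = small_sim
        native = [p for p in env.index if p.startswith("N")]
        z, std = gea.standardize_env(env.loc[native])
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-10)

    def test_constant_variable_rejected(self):
        env = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            gea.standardize_env(env)


class TestLfmmScan:
    def test_zero_latent_equals_plain_ols(self, rng):
        n, L = 80, 30
        Y = rng.binomial(2, 0.5, size=(n, L)).astype(float)
        env = pd.DataFrame({"x": rng.normal(size=n)})
        scan = gea.lfmm_scan(Y, env, n_latent=0)
        import statsmodels.api as sm
        j = 7
        ols = sm.OLS(Y[:, j] - Y[:, j].mean(),
                     sm.add_constant(env["x"])).fit()
        raw_z = scan.z.iloc[j, 0] * np.sqrt(scan.gif.iloc[0])
        assert raw_z == pytest.approx(ols.tvalues["x"], rel=1e-10)

    def test_null_pvalues_uniform(self):
        cfg = simdata.SimConfig(n_native_pops=40, n_introduced_pops=1,
                                n_farmed_pops=1, samples_per_pop=10,
                                n_loci=5000, n_adaptive_loci=1,
                                env_effect=0.0, seed=7, missing_rate=0.0)
        g_nat, groups, env_std, *_ = _native_pieces(cfg)
        envps = env_std.loc[[groups[s] for s in g_nat.sample_ids]]
        # permute environment rows against genotypes
        envp = envps.sample(frac=1.0, random_state=3).reset_index(drop=True)
        scan = gea.lfmm_scan(g_nat, envp, n_latent=2)
        mac = np.nansum(g_nat.dosages, axis=0)
        nn = 2 * np.sum(~np.isnan(g_nat.dosages), axis=0)
        poly = np.minimum(mac, nn - mac) >= 2
        for var in scan.p.columns:
            assert stats.kstest(scan.p[var][poly], "uniform").pvalue > 0.01

    def test_planted_loci_detected(self):
        powers, fdps = [], []
        for rep in range(3):
            cfg = simdata.SimConfig(n_native_pops=60, n_introduced_pops=1,
                                    n_farmed_pops=1, samples_per_pop=15,
                                    n_loci=1000, n_adaptive_loci=20,
                                    env_effect=1.0, seed=300 + rep)
            g_nat, groups, env_std, *_ , truth = _native_pieces(cfg)
            envps = env_std.loc[[groups[s] for s in g_nat.sample_ids]]
            scan = gea.lfmm_scan(g_nat, envps, n_latent=2)
            cand = scan.candidates(0.1)
            A = set(truth.adaptive_locus_ids)
            powers.append(len(cand & A) / len(A))
            fdps.append(len(cand - A) / max(len(cand), 1))
        assert np.mean(powers) >= 0.8
        assert np.mean(fdps) <= 0.2

    def test_excessive_latent_rank_rejected(self, rng):
        Y = rng.binomial(2, 0.5, size=(5, 8)).astype(float)
        with pytest.raises(ValueError):
            gea.lfmm_scan(Y, pd.DataFrame({"x": np.zeros(5) + rng.normal(size=5)}),
                          n_latent=5)

    def test_bh_adjustment_matches_step_up_oracle(self, rng):
        p = rng.uniform(size=200)
        from statsmodels.stats.multitest import multipletests
        got = multipletests(p, method="fdr_bh")[1]
        # direct sort-based step-up oracle
        order = np.argsort(p)
        m = len(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        want = np.empty(m)
        want[order] = np.minimum(q, 1.0)
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestRda:
    def test_self_conditioning_zero_inertia(self, rng):
        Y = pd.DataFrame(rng.normal(size=(10, 6)))
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        r = gea.rda(Y, X, condition=X, n_permutations=0)
        assert r.constrained_inertia == 0.0

    def test_partially_collinear_predictor_rejected(self, rng):
        Y = pd.DataFrame(rng.normal(size=(10, 6)))
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="collinear"):
            gea.rda(Y, X, condition=X[["a"]], n_permutations=0)

    def test_single_predictor_equals_regression_r2(self, rng):
        Y = pd.DataFrame(rng.normal(size=(6, 10)))
        X = pd.DataFrame({"x": rng.normal(size=6)})
        r = gea.rda(Y, X, n_permutations=0)
        Yc = Y - Y.mean()
        x = X["x"] - X["x"].mean()
        fitted = np.outer(x, (Yc.T @ x) / (x @ x))
        want = np.sum(fitted ** 2) / np.sum(Yc.to_numpy() ** 2)
        assert r.r_squared == pytest.approx(want, abs=1e-10)

    def test_matches_vegan_on_random_matrix(self, tmp_path, rng):
        Y = pd.DataFrame(rng.normal(size=(12, 8)))
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=["x1", "x2", "x3"])
        Z = pd.DataFrame(rng.normal(size=(12, 2)), columns=["z1", "z2"])
        Y.to_csv(tmp_path / "Y.csv", index=False)
        X.to_csv(tmp_path / "X.csv", index=False)
        Z.to_csv(tmp_path / "Z.csv", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- read.csv("{tmp_path}/Y.csv")
            X <- read.csv("{tmp_path}/X.csv")
            Z <- read.csv("{tmp_path}/Z.csv")
            d <- cbind(X, Z)
            m <- rda(Y ~ x1 + x2 + x3 + Condition(z1) + Condition(z2), data=d)
            write.csv(data.frame(eig=eigenvals(m, model="constrained")),
                      "{tmp_path}/eig.csv", row.names=FALSE)
        """)
        (tmp_path / "chk.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "chk.R")], check=True,
                       capture_output=True)
        want = pd.read_csv(tmp_path / "eig.csv")["eig"].to_numpy()
        r = gea.prda(Y, X, Z, n_permutations=0)
        np.testing.assert_allclose(r.eigvals, want, rtol=1e-6)

    def test_permutation_p_detects_real_association(self, rng):
        x = rng.normal(size=20)
        Y = pd.DataFrame(np.outer(x, rng.normal(size=15))
                         + 0.3 * rng.normal(size=(20, 15)))
        r = gea.rda(Y, pd.DataFrame({"x": x}), n_permutations=199, seed=0)
        assert r.perm_p < 0.01

    def test_axis_inertias_non_increasing(self, small_sim):
        g, meta, env, raster, truth = small_sim
        groups = meta.populations(g)
        native = [p for p in env.index if p.startswith("N")]
        env_std, _ = gea.standardize_env(env.loc[native])
        rows = np.array([i for i, s in enumerate(g.sample_ids)
                         if groups[s] in set(native)])
        freqs = popdiv.allele_frequencies(
            g.take_samples(rows),
            groups.iloc[rows]).reindex(env_std.index)
        r = gea.rda(freqs, env_std, n_permutations=0)
        assert np.all(np.diff(r.eigvals) <= 1e-12)
        assert r.constrained_inertia <= r.total_inertia + 1e-12


class TestVariancePartition:
    def test_bookkeeping_from_published_style_inertias(self):
        part = gea.VariancePartition.from_inertias(
            total=1100.3, full=863.6, climate=61.2, geography=43.4,
            demography=339.3)
        assert part.unexplained == pytest.approx(236.7, abs=1e-9)
        assert round(part.full / part.total, 3) == 0.785
        assert round(part.climate / part.total, 3) == 0.056
        assert round(part.demography / part.total, 3) == 0.308

    def test_orthogonal_blocks_no_confounding(self, rng):
        n = 40
        a = rng.normal(size=(n, 2))
        q, _ = np.linalg.qr(rng.normal(size=(n, 6)))
        blocks = [pd.DataFrame(q[:, :2], columns=["c1", "c2"]),
                  pd.DataFrame(q[:, 2:4], columns=["g1", "g2"]),
                  pd.DataFrame(q[:, 4:6], columns=["d1", "d2"])]
        Y = pd.DataFrame(q @ rng.normal(size=(6, 30))
                         + 0.5 * rng.normal(size=(n, 30)))
        part = gea.variance_partition(Y, *blocks)
        assert abs(part.confounded) / part.total < 0.02

    def test_structure_only_data_gives_no_unique_climate_signal(self):
        # bias-corrected unique climate fraction stays near zero when only
        # neutral structure drives allele frequencies
        fracs = []
        for rep in range(8):
            cfg = simdata.SimConfig(
                n_native_pops=24, n_introduced_pops=1, n_farmed_pops=1,
                samples_per_pop=8, n_loci=500, n_adaptive_loci=1,
                env_effect=0.0, seed=600 + rep)
            g_nat, groups, env_std, std, freqs, pops, truth = \
                _native_pieces(cfg)
            native = list(env_std.index)
            part = gea.variance_partition(
                freqs, env_std, pops.loc[native, ["lon", "lat"]],
                truth.pop_q.loc[native].to_frame("qW"))
            fracs.append(part.adjusted["climate"])
        assert max(fracs) <= 0.02

    def test_proportions_sum_to_one(self, small_sim):
        g, meta, env, raster, truth = small_sim
        groups = meta.populations(g)
        native = [p for p in env.index if p.startswith("N")]
        env_std, _ = gea.standardize_env(env.loc[native])
        rows = np.array([i for i, s in enumerate(g.sample_ids)
                         if groups[s] in set(native)])
        freqs = popdiv.allele_frequencies(
            g.take_samples(rows), groups.iloc[rows]).reindex(env_std.index)
        pops = meta.population_table().set_index("population_id")
        part = gea.variance_partition(
            freqs, env_std, pops.loc[native, ["lon", "lat"]],
            truth.pop_q.loc[native].to_frame("qW"))
        tab = part.as_table()
        comp = tab.loc[["full_model", "unexplained"], "proportion_of_total"]
        assert comp.sum() == pytest.approx(1.0, abs=1e-10)
        uniq = tab.loc[["climate_unique", "geography_unique",
                        "demography_unique", "confounded"], "inertia"].sum()
        assert uniq == pytest.approx(part.full, abs=1e-9)


class TestOutliersAndCandidates:
    def test_gaussian_loadings_tail_fraction(self, rng):
        load = pd.DataFrame({"RDA1": rng.normal(size=10_000)})
        r = gea.RdaResult(loadings=load, env_scores=pd.DataFrame(),
                          site_scores=pd.DataFrame(), eigvals=np.array([1.0]),
                          total_inertia=1.0, perm_p=None)
        frac = len(gea.rda_outliers(r, 1, 2.5)) / 10_000
        assert frac == pytest.approx(2 * stats.norm.sf(2.5), abs=0.003)

    def test_infinite_threshold_empty(self, rng):
        load = pd.DataFrame({"RDA1": rng.normal(size=100)})
        r = gea.RdaResult(loadings=load, env_scores=pd.DataFrame(),
                          site_scores=pd.DataFrame(), eigvals=np.array([1.0]),
                          total_inertia=1.0, perm_p=None)
        assert gea.rda_outliers(r, 1, np.inf) == set()

    def test_candidate_set_algebra(self):
        cs = gea.combine_candidates({"a", "b", "c"}, {"b", "c", "d"})
        assert cs.shared == {"b", "c"}
        assert cs.combined == {"a", "b", "c", "d"}
        disjoint = gea.combine_candidates({"a"}, {"b"})
        assert len(disjoint.combined) == 2 and not disjoint.shared
        same = gea.combine_candidates({"a"}, {"a"})
        assert same.combined == same.shared == {"a"}

    def test_strongest_variable_argmax_and_tiebreak(self, rng):
        x = rng.normal(size=30)
        freqs = pd.DataFrame({"L1": x + 0.1 * rng.normal(size=30),
                              "L2": rng.normal(size=30)})
        env = pd.DataFrame({"A": rng.normal(size=30), "B": x})
        got = gea.strongest_variable(freqs, env, ["L1"])
        assert got["L1"] == "B"
        # exact tie: duplicated variable -> first in canonical order wins
        env2 = pd.DataFrame({"A": x, "B": x})
        assert gea.strongest_variable(freqs, env2, ["L1"])["L1"] == "A"

    def test_enriched_rda_on_all_loci_equals_plain(self, rng):
        Y = pd.DataFrame(rng.normal(size=(10, 6)),
                         columns=[f"L{j}" for j in range(6)])
        X = pd.DataFrame({"x": rng.normal(size=10)})
        plain = gea.rda(Y, X, n_permutations=0)
        enr = gea.enriched_rda(Y, X, set(Y.columns))
        np.testing.assert_allclose(enr.eigvals, plain.eigvals, atol=1e-12)

    def test_empty_candidates_rejected(self, rng):
        Y = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            gea.enriched_rda(Y, pd.DataFrame({"x": rng.normal(size=5)}), set())
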