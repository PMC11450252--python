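"""Genotype-environment index, nearest-source mapping, genomic offset."""

import numpy as np
import pandas as pd
import pytest

from invoffset import gea, offset, popdiv, simdata
from invoffset.genio import EnvRaster, SampleMetadata
from invoffset.offset import (AdaptiveIndexRaster, adaptive_index,
                              classify_offsets, count_below, genetic_offset,
                              load_reference_offsets, nearest_native_source)


def _std(means, sds):
    return gea.Standardization(mean=pd.Series(means), sd=pd.Series(sds))


def _meta(rows):
    return SampleMetadata(pd.DataFrame(
        rows, columns=["sample_id", "population_id", "status", "lon", "lat"]))


class TestAdaptiveIndex:
    def test_native_mean_pixel_scores_zero(self):
        r = EnvRaster({"a": np.full((4, 4), 3.0), "b": np.full((4, 4), 7.0)},
                      0.0, 0.0, 1.0)
        idx = adaptive_index(pd.Series({"a": 1.3, "b": -0.4}), r,
                             _std({"a": 3.0, "b": 7.0}, {"a": 1.0, "b": 2.0}))
        np.testing.assert_allclose(idx.grid, 0.0)

    def test_single_variable_one_term_sum(self):
        r = EnvRaster({"a": np.array([[2.5]])}, 0.0, 0.0, 1.0)
        idx = adaptive_index(pd.Series({"a": 2.0}), r,
                             _std({"a": 1.0}, {"a": 1.0}))
        assert idx.grid[0, 0] == pytest.approx(3.0)   # 2.0 * 1.5

    def test_matches_per_pixel_loop(self, small_sim):
        *_, raster, _ = small_sim
        scores = pd.Series({v: s for v, s in zip(raster.variables,
                                                 [0.8, -0.5, 0.3, 0.1, -0.9])})
        means = {v: float(np.nanmean(raster.grids[v]))
                 for v in raster.variables}
        sds = {v: float(np.nanstd(raster.grids[v], ddof=1))
               for v in raster.variables}
        std = _std(means, sds)
        idx = adaptive_index(scores, raster, std)
        nrows, ncols = raster.shape
        for r in range(0, nrows, 7):
            for c in range(0, ncols, 7):
                want = sum(scores[v] * (raster.grids[v][r, c] - means[v])
                           / sds[v] for v in raster.variables)
                assert idx.grid[r, c] == pytest.approx(want, abs=1e-12)

    def test_linearity_in_standardized_env(self):
        g = np.linspace(0, 1, 16).reshape(4, 4)
        std = _std({"a": 0.0}, {"a": 1.0})
        one = adaptive_index(pd.Series({"a": 2.0}), EnvRaster({"a": g}, 0, 0, 1), std)
        three = adaptive_index(pd.Series({"a": 2.0}),
                               EnvRaster({"a": 3 * g}, 0, 0, 1), std)
        np.testing.assert_allclose(three.grid, 3 * one.grid, atol=1e-12)

    def test_missing_variable_rejected(self):
        r = EnvRaster({"a": np.zeros((2, 2))}, 0, 0, 1.0)
        with pytest.raises(ValueError, match="missing from raster"):
            adaptive_index(pd.Series({"a": 1.0, "b": 1.0}), r,
                           _std({"a": 0, "b": 0}, {"a": 1, "b": 1}))

    def test_nodata_propagates(self):
        g = np.zeros((2, 2))
        g[0, 1] = np.nan
        idx = adaptive_index(pd.Series({"a": 1.0}),
                             EnvRaster({"a": g}, 0, 0, 1.0),
                             _std({"a": 0.0}, {"a": 1.0}))
        assert np.isnan(idx.grid[0, 1]) and idx.grid[0, 0] == 0.0


class TestNearestSource:
    def test_single_native_catches_all(self):
        fst = pd.DataFrame([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]],
                           index=["N1", "I1", "I2"],
                           columns=["N1", "I1", "I2"], dtype=float)
        meta = _meta([("a", "N1", "native", 0, 0),
                      ("b", "I1", "introduced", 1, 1),
                      ("c", "I2", "introduced", 2, 2)])
        assert nearest_native_source(fst, meta) == {"I1": "N1", "I2": "N1"}

    def test_tie_breaks_lexicographically(self):
        fst = pd.DataFrame(np.array([[0, 0, .2], [0, 0, .2], [.2, .2, 0]]),
                           index=["NA", "NB", "I1"],
                           columns=["NA", "NB", "I1"], dtype=float)
        meta = _meta([("a", "NA", "native", 0, 0),
                      ("b", "NB", "native", 1, 0),
                      ("c", "I1", "introduced", 2, 2)])
        assert nearest_native_source(fst, meta)["I1"] == "NA"

    def test_simulated_sources_recovered(self):
        correct = total = 0
        for rep in range(4):
            cfg = simdata.SimConfig(
                n_native_pops=8, n_introduced_pops=5, n_farmed_pops=1,
                samples_per_pop=15, n_loci=2000, founder_size=50,
                seed=400 + rep)
            g, meta, env, raster, truth = simdata.simulate_dataset(cfg)
            from invoffset.differentiation import pairwise_fst
            fst = pairwise_fst(g, meta.populations(g))
            mapping = nearest_native_source(fst, meta)
            for p, src in mapping.items():
                correct += src == truth.source_of[p]
                total += 1
        assert correct / total >= 0.9


class TestGeneticOffset:
    def _index(self):
        grid = np.tile(np.arange(5, dtype=float), (5, 1))   # index = col
        return AdaptiveIndexRaster(grid, 0.0, 0.0, 1.0)

    def test_identical_env_zero_offset(self):
        idx = self._index()
        meta = _meta([("a", "N1", "native", 2.5, 2.5),
                      ("b", "I1", "introduced", 2.5, 4.5)])  # same column
        tab = genetic_offset(idx, {"I1": "N1"}, meta)
        assert tab.loc["I1", "offset"] == 0.0

    def test_offset_is_absolute_column_difference(self):
        idx = self._index()
        meta = _meta([("a", "N1", "native", 0.5, 0.5),
                      ("b", "I1", "introduced", 3.5, 0.5)])
        tab = genetic_offset(idx, {"I1": "N1"}, meta)
        assert tab.loc["I1", "offset"] == 3.0
        assert tab.loc["I1", "signed_offset"] == 3.0

    def test_invariant_under_axis_sign_flip(self):
        idx = self._index()
        flipped = AdaptiveIndexRaster(-idx.grid, 0.0, 0.0, 1.0)
        meta = _meta([("a", "N1", "native", 0.5, 0.5),
                      ("b", "I1", "introduced", 3.5, 0.5)])
        a = genetic_offset(idx, {"I1": "N1"}, meta)["offset"]
        b = genetic_offset(flipped, {"I1": "N1"}, meta)["offset"]
        pd.testing.assert_series_equal(a, b)

    def test_env_displaced_introductions_get_larger_offsets(self):
        # end-to-end: offsets grow with the introduced pixel's climatic
        # displacement from the source pixel
        from scipy import stats as sstats
        low, high = [], []
        for rep in range(6):
            cfg = simdata.SimConfig(
                n_native_pops=24, n_introduced_pops=10, n_farmed_pops=1,
                samples_per_pop=10, n_loci=600, n_adaptive_loci=30,
                env_effect=1.0, seed=900 + rep)
            g, meta, env, raster, truth = simdata.simulate_dataset(cfg)
            groups = meta.populations(g)
            native = [p for p in env.index if p.startswith("N")]
            rows = np.array([i for i, s in enumerate(g.sample_ids)
                             if groups[s] in set(native)])
            g_nat = g.take_samples(rows)
            env_std, std = gea.standardize_env(env.loc[native])
            freqs = popdiv.allele_frequencies(
                g_nat, groups.loc[g_nat.sample_ids]).reindex(env_std.index)
            enr = gea.enriched_rda(freqs, env_std,
                                   set(truth.adaptive_locus_ids))
            idx = adaptive_index(enr.env_scores["RDA1"], raster, std)
            pops = meta.population_table().set_index("population_id")
            tab = genetic_offset(idx, dict(truth.source_of), meta)
            disp = {}
            for p in tab.index:
                ei = raster.extract(pops.loc[p, "lon"],
                                    pops.loc[p, "lat"])[truth.focal_variable]
                es = raster.extract(
                    pops.loc[truth.source_of[p], "lon"],
                    pops.loc[truth.source_of[p], "lat"])[truth.focal_variable]
                disp[p] = abs(ei - es)
            med = np.median(list(disp.values()))
            for p in tab.index:
                (low if disp[p] <= med else high).append(tab.loc[p, "offset"])
        p = sstats.mannwhitneyu(high, low, alternative="greater").pvalue
        assert p < 0.01


class TestClassification:
    def test_tertiles_of_one_to_nine(self):
        labels = classify_offsets(pd.Series(np.arange(1.0, 10.0)))
        assert labels.value_counts().to_dict() == {"Low": 3, "Medium": 3,
                                                   "High": 3}

    def test_fixed_breaks_match_direct_binning(self):
        v = pd.Series([0.5, 3.0, 3.143, 4.0, 5.9, 6.2])
        labels = classify_offsets(v, mode="fixed", breaks=(3.143, 5.817))
        want = ["Low" if x <= 3.143 else "Medium" if x <= 5.817 else "High"
                for x in v]
        assert labels.tolist() == want

    def test_degenerate_all_equal_all_low(self):
        labels = classify_offsets(pd.Series([2.0] * 6))
        assert (labels == "Low").all()

    def test_invalid_breaks_rejected(self):
        with pytest.raises(ValueError):
            classify_offsets(pd.Series([1.0, 2.0, 3.0]), mode="fixed",
                             breaks=(5.0, 1.0))


class TestCountBelowAndReference:
    def test_reference_table_shape_and_classes(self):
        ref = load_reference_offsets()
        assert len(ref) == 40
        assert set(ref["relative_difference"]) == {"Low", "Medium", "High"}
        assert (ref["offset"] >= 0).all()

    def test_count_below_trivials(self):
        ref = load_reference_offsets()
        assert count_below(ref["offset"], 0.0) == 0
        assert count_below(ref["offset"], np.inf) == 40
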