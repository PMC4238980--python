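import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sysgen.cross_qtl import (ScanResult, kruskal_wallis_lod,
                              merge_qtl_regions, permutation_threshold,
                              regions_to_frame, scan_binary,
                              scan_nonparametric, support_interval_2lod,
                              QTLRegion)
from sysgen.io_formats import GeneticMap, GenotypeMatrix
from sysgen.synthdata import CrossSpec, QTLEffect, simulate_f2_genotypes


def _series(vals, geno, name="t"):
    return pd.Series(np.asarray(vals, dtype=float), index=geno.samples, name=name)


def _geno_from_column(col):
    col = np.asarray(col, dtype=float)
    gmap = GeneticMap(pd.DataFrame(
        [{"marker_id": "m1", "chrom": "1", "pos_cM": 0.0, "pos_bp": 100}]
    ))
    geno = GenotypeMatrix([f"s{i}" for i in range(len(col))], ["m1"], col[:, None])
    return geno, gmap


class TestNonparametricScan:
    def test_constant_trait_gives_zero_lod(self, small_geno, small_map):
        scan = scan_nonparametric(small_geno, small_map,
                                  _series(np.ones(80), small_geno))
        assert np.allclose(scan.table["lod"], 0.0)

    def test_hand_computed_kruskal_wallis(self):
        # groups {1,2},{3,4},{5,6}: H = 12/(6*7) * sum n_i (Rbar_i - Rbar)^2
        #   = 4.5714..., LOD = H / (2 ln 10) = 0.99267
        geno, gmap = _geno_from_column([0, 0, 1, 1, 2, 2])
        scan = scan_nonparametric(geno, gmap, _series([1, 2, 3, 4, 5, 6], geno))
        assert scan.table["lod"][0] == pytest.approx(4.571428571 / (2 * np.log(10)),
                                                     abs=1e-9)
        assert scan.table["lod"][0] == pytest.approx(0.992673, abs=1e-5)

    def test_invariant_under_monotone_transform(self, small_geno, small_map):
        rng = np.random.default_rng(0)
        y = rng.normal(size=80)
        s1 = scan_nonparametric(small_geno, small_map, _series(y, small_geno))
        s2 = scan_nonparametric(small_geno, small_map,
                                _series(np.exp(3 * y) + 5, small_geno))
        assert np.allclose(s1.table["lod"], s2.table["lod"])

    def test_missing_genotypes_fall_back_to_per_marker_ranks(self, small_map):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(40, 10)).astype(float)
        codes[::7, 0] = np.nan
        geno = GenotypeMatrix([f"s{i}" for i in range(40)],
                              small_map.marker_ids, codes)
        y = rng.normal(size=40)
        scan = scan_nonparametric(geno, small_map, _series(y, geno))
        ok = ~np.isnan(codes[:, 0])
        groups = [y[ok][codes[ok, 0] == g] for g in (0, 1, 2)]
        expected = kruskal_wallis_lod(stats.kruskal(*groups).statistic)
        assert scan.table["lod"][0] == pytest.approx(expected, abs=1e-12)


class TestBinaryScan:
    def test_saturated_toy_matches_closed_form_likelihood(self):
        # 12 samples, 4 per genotype group, successes 1/2/3: the two-indicator
        # logistic model is saturated per group, so its maximized likelihood
        # equals the closed-form binomial one
        geno, gmap = _geno_from_column(np.repeat([0.0, 1.0, 2.0], 4))
        y = [1, 0, 0, 0, 1, 1, 0, 0, 1, 1, 1, 0]

        def bin_ll(k, n):
            p = k / n
            return k * np.log(p) + (n - k) * np.log(1 - p)

        oracle = (bin_ll(1, 4) + bin_ll(2, 4) + bin_ll(3, 4) - bin_ll(6, 12)) \
            / np.log(10)
        scan = scan_binary(geno, gmap, _series(y, geno))
        assert scan.table["lod"][0] == pytest.approx(oracle, abs=1e-8)

    def test_uninformative_covariate_leaves_lod_unchanged(self):
        geno, gmap = _geno_from_column(np.repeat([0.0, 1.0, 2.0], 4))
        y = _series([1, 0, 0, 0, 1, 1, 0, 0, 1, 1, 1, 0], geno)
        base = scan_binary(geno, gmap, y)
        cov = pd.DataFrame({"noise": np.zeros(12)}, index=geno.samples)
        with_cov = scan_binary(geno, gmap, y, cov)
        assert with_cov.table["lod"][0] == pytest.approx(base.table["lod"][0],
                                                         abs=1e-6)

    def test_null_binary_lods_near_zero(self, small_map):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=(400, 10)).astype(float)
        geno = GenotypeMatrix([f"s{i}" for i in range(400)],
                              small_map.marker_ids, codes)
        y = _series(rng.integers(0, 2, 400), geno)
        scan = scan_binary(geno, small_map, y)
        assert np.median(scan.table["lod"]) < 0.5

    def test_separation_flagged(self):
        geno, gmap = _geno_from_column(np.repeat([0.0, 1.0, 2.0], 4))
        y = _series([0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1], geno)
        scan = scan_binary(geno, gmap, y)
        assert scan.table["flag"][0] == "separation"
        assert np.isfinite(scan.table["lod"][0])


class TestPermutationThreshold:
    @pytest.fixture()
    def geno_and_trait(self, small_map):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(60, 10)).astype(float)
        geno = GenotypeMatrix([f"s{i}" for i in range(60)],
                              small_map.marker_ids, codes)
        y = pd.Series(rng.normal(size=60), index=geno.samples, name="t")
        return geno, y

    def test_alpha_one_gives_min_of_maxima(self, small_map, geno_and_trait):
        geno, y = geno_and_trait
        perm = permutation_threshold(geno, small_map, y, None, "nonparametric",
                                     n_perm=50, alpha=1.0, seed=0)
        assert perm.threshold == pytest.approx(perm.max_lods.min())

    def test_threshold_monotone_in_alpha(self, small_map, geno_and_trait):
        geno, y = geno_and_trait
        thresholds = [
            permutation_threshold(geno, small_map, y, None, "nonparametric",
                                  n_perm=100, alpha=a, seed=0).threshold
            for a in (0.01, 0.05, 0.2, 0.63, 1.0)
        ]
        assert all(t1 >= t2 for t1, t2 in zip(thresholds, thresholds[1:]))

    def test_genome_p_bounded_and_deterministic(self, small_map, geno_and_trait):
        geno, y = geno_and_trait
        p1 = permutation_threshold(geno, small_map, y, None, "nonparametric",
                                   n_perm=99, alpha=0.05, seed=5)
        p2 = permutation_threshold(geno, small_map, y, None, "nonparametric",
                                   n_perm=99, alpha=0.05, seed=5)
        assert np.array_equal(p1.max_lods, p2.max_lods)
        assert p1.genome_p(np.inf) == pytest.approx(1 / 100)
        assert p1.genome_p(-1.0) == pytest.approx(1.0)

    def test_binary_permutation_matches_observed_scale(self, small_map):
        # permuted binary scans should produce max LODs comparable to a null
        # observed scan, not systematically inflated
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(80, 10)).astype(float)
        geno = GenotypeMatrix([f"s{i}" for i in range(80)],
                              small_map.marker_ids, codes)
        y = pd.Series(rng.integers(0, 2, 80).astype(float), index=geno.samples,
                      name="t")
        perm = permutation_threshold(geno, small_map, y, None, "binary",
                                     n_perm=60, alpha=0.05, seed=1)
        scan = scan_binary(geno, small_map, y)
        observed_max = scan.table["lod"].max()
        assert perm.genome_p(observed_max) > 0.01


class TestSupportInterval:
    def _scan_from_lods(self, lods):
        rows = [{"marker_id": f"x{i}", "chrom": "1", "pos_cM": i * 10.0,
                 "pos_bp": (i + 1) * 1_000_000} for i in range(len(lods))]
        gmap = GeneticMap(pd.DataFrame(rows))
        tab = gmap.table.copy()
        tab["lod"] = lods
        tab["flag"] = ""
        return ScanResult(tab, "nonparametric", "t", [], 10), gmap

    def test_hand_example_five_markers(self):
        scan, gmap = self._scan_from_lods([1.0, 3.0, 5.0, 3.5, 2.9])
        region = support_interval_2lod(scan, gmap, "1")
        assert (region.ci_start_bp, region.ci_end_bp) == (2_000_000, 4_000_000)
        assert region.peak_marker == "x2"

    def test_single_marker_chromosome(self):
        scan, gmap = self._scan_from_lods([2.5])
        region = support_interval_2lod(scan, gmap, "1")
        assert region.ci_start_bp == region.ci_end_bp == 1_000_000

    def test_peak_at_chromosome_end_truncates(self):
        scan, gmap = self._scan_from_lods([5.0, 2.0, 1.0])
        region = support_interval_2lod(scan, gmap, "1")
        assert region.ci_start_bp == 1_000_000  # starts at the peak marker
        assert region.ci_end_bp == 1_000_000

    def test_equal_peaks_resolve_leftmost(self):
        scan, gmap = self._scan_from_lods([1.0, 4.0, 4.0, 1.0])
        region = support_interval_2lod(scan, gmap, "1")
        assert region.peak_marker == "x1"

    def test_peak_inside_interval_invariant(self):
        scan, gmap = self._scan_from_lods([0.5, 1.5, 4.2, 3.9, 2.1, 0.3])
        region = support_interval_2lod(scan, gmap, "1")
        peak_bp = int(gmap.table.set_index("marker_id")
                      .loc[region.peak_marker, "pos_bp"])
        assert region.ci_start_bp <= peak_bp <= region.ci_end_bp


def _brute_force_region_count(intervals):
    """Connected components under the share->=1-bp relation (union-find)."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, (c1, s1, e1) in enumerate(intervals):
        for j, (c2, s2, e2) in enumerate(intervals):
            if i < j and c1 == c2 and max(s1, s2) <= min(e1, e2):
                parent[find(i)] = find(j)
    return len({find(i) for i in range(len(intervals))})


class TestMergeRegions:
    def _frame(self, triples):
        return pd.DataFrame([
            {"trait": f"t{i}", "chrom": c, "ci_start_bp": s, "ci_end_bp": e}
            for i, (c, s, e) in enumerate(triples)
        ])

    def test_disjoint_intervals_unchanged(self):
        merged = merge_qtl_regions(self._frame([("1", 10, 20), ("1", 30, 40)]))
        assert len(merged) == 2

    def test_shared_single_bp_merges(self):
        merged = merge_qtl_regions(self._frame([("1", 10, 20), ("1", 20, 40)]))
        assert len(merged) == 1
        assert merged.iloc[0]["start_bp"] == 10 and merged.iloc[0]["end_bp"] == 40

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(["1", "2"]),
                              st.integers(0, 50), st.integers(0, 50)),
                    min_size=1, max_size=8))
    def test_matches_per_bp_union_oracle(self, raw):
        triples = [(c, min(a, b), max(a, b)) for c, a, b in raw]
        merged = merge_qtl_regions(self._frame(triples))
        assert len(merged) == _brute_force_region_count(triples)


class TestPlantedQtlRecovery:
    def test_planted_qtl_is_genome_wide_significant_and_covered(self):
        # strong planted QTL (~20% variance at n=228): detected with the
        # permutation threshold and covered by the 2-LOD interval
        rows = [{"marker_id": f"c{c}_{j}", "chrom": str(c), "pos_cM": j * 10.0,
                 "pos_bp": 1_000_000 + j * 5_000_000}
                for c in (1, 2, 3) for j in range(8)]
        gmap = GeneticMap(pd.DataFrame(rows))
        spec = CrossSpec(map=gmap, n_individuals=228,
                         qtl_effects=[QTLEffect("c2_4", "t", 0.707)])
        hits = 0
        for seed in range(10):
            geno = simulate_f2_genotypes(spec, seed=seed)
            from sysgen.synthdata import simulate_traits
            td = simulate_traits(geno, spec, seed=seed + 100)
            scan = scan_nonparametric(geno, gmap, td.traits["t"])
            perm = permutation_threshold(geno, gmap, td.traits["t"], None,
                                         "nonparametric", n_perm=200,
                                         alpha=0.05, seed=seed)
            sub = scan.table[scan.table["chrom"] == "2"]
            if sub["lod"].max() >= perm.threshold:
                region = support_interval_2lod(scan, gmap, "2")
                truth_bp = 1_000_000 + 4 * 5_000_000
                if region.ci_start_bp <= truth_bp <= region.ci_end_bp:
                    hits += 1
        assert hits >= 9
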