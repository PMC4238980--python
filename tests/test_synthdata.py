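import numpy as np
import pandas as pd
import pytest

from sysgen import synthdata
from sysgen.gwas_case_case import genotype_counts, hwe_exact_p
from sysgen.io_formats import GeneticMap, ValidationError
from sysgen.synthdata import (CisEffect, CrossSpec, ExpressionSpec, GwasSnp,
                              GwasSpec, HumanCohortSpec, QTLEffect, TraitLink,
                              haldane_recomb_fraction, simulate_expression,
                              simulate_f2_genotypes, simulate_gwas_cohort,
                              simulate_human_cohort, simulate_traits)


def _two_marker_map(d_cM: float) -> GeneticMap:
    return GeneticMap(pd.DataFrame([
        {"marker_id": "a", "chrom": "1", "pos_cM": 0.0, "pos_bp": 100},
        {"marker_id": "b", "chrom": "1", "pos_cM": d_cM, "pos_bp": 200},
    ]))


class TestF2Genotypes:
    def test_zero_distance_gives_identical_columns(self):
        spec = CrossSpec(map=_two_marker_map(0.0), n_individuals=500)
        geno = simulate_f2_genotypes(spec, seed=1)
        assert np.array_equal(geno.codes[:, 0], geno.codes[:, 1])

    def test_recombinant_fraction_matches_haldane(self):
        # d = 10 cM -> c = (1 - e^-0.2)/2 = 0.090635
        n = 10_000
        spec = CrossSpec(map=_two_marker_map(10.0), n_individuals=n)
        geno = simulate_f2_genotypes(spec, seed=2)
        c = haldane_recomb_fraction(10.0)
        assert c == pytest.approx(0.0906346, abs=1e-6)
        # dosage is the sum of two gametes, each switching origin w.p. c;
        # per gamete the allele change is 0 w.p. (1-c) and +-1 w.p. c/2 each,
        # so P(dosage changes between markers) = 1 - [(1-c)^2 + c^2/2]
        d0, d1 = geno.codes[:, 0], geno.codes[:, 1]
        switch = np.mean(d0 != d1)
        expect = 1 - ((1 - c) ** 2 + c**2 / 2)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(switch - expect) < 3 * se

    def test_mendelian_f2_ratios(self):
        spec = CrossSpec(map=_two_marker_map(50.0), n_individuals=20_000)
        geno = simulate_f2_genotypes(spec, seed=3)
        freqs = [np.mean(geno.codes[:, 0] == g) for g in (0, 1, 2)]
        assert freqs == pytest.approx([0.25, 0.5, 0.25], abs=0.02)

    def test_determinism(self):
        spec = CrossSpec(map=_two_marker_map(10.0), n_individuals=50)
        g1 = simulate_f2_genotypes(spec, seed=9)
        g2 = simulate_f2_genotypes(spec, seed=9)
        assert np.array_equal(g1.codes, g2.codes)

    def test_unknown_effect_marker_rejected(self):
        with pytest.raises(ValidationError):
            CrossSpec(map=_two_marker_map(1.0),
                      qtl_effects=[QTLEffect("ghost", "t", 1.0)])


class TestTraits:
    def test_null_trait_uncorrelated_with_markers(self):
        spec = CrossSpec(map=_two_marker_map(10.0), n_individuals=10_000,
                         qtl_effects=[QTLEffect("a", "t", 0.0)])
        geno = simulate_f2_genotypes(spec, seed=4)
        td = simulate_traits(geno, spec, seed=5)
        y = td.traits["t"].to_numpy()
        for j in range(2):
            r = np.corrcoef(geno.codes[:, j], y)[0, 1]
            assert abs(r) < 0.1

    def test_additive_group_means(self):
        spec = CrossSpec(map=_two_marker_map(10.0), n_individuals=10_000,
                         qtl_effects=[QTLEffect("a", "t", 1.0)])
        geno = simulate_f2_genotypes(spec, seed=6)
        td = simulate_traits(geno, spec, seed=7)
        y = td.traits["t"].to_numpy()
        dos = geno.codes[:, 0]
        means = [y[dos == g].mean() for g in (0, 1, 2)]
        assert means == pytest.approx([-1.0, 0.0, 1.0], abs=0.08)

    def test_truth_record_lists_planted_effects(self):
        spec = CrossSpec(map=_two_marker_map(10.0), n_individuals=30,
                         qtl_effects=[QTLEffect("a", "t", 0.5, trait_type="continuous")])
        geno = simulate_f2_genotypes(spec, seed=8)
        td = simulate_traits(geno, spec, seed=8)
        assert td.truth.iloc[0]["marker_id"] == "a"
        assert td.truth.iloc[0]["a"] == 0.5


class TestExpression:
    def _spec(self, n_samples=126, **kw):
        ann = pd.DataFrame([
            {"transcript_id": "t1", "chrom": "1", "tss_bp": 150, "ortholog": "T1"},
            {"transcript_id": "t2", "chrom": "1", "tss_bp": 180, "ortholog": "T2"},
        ] + [
            {"transcript_id": f"n{i}", "chrom": "1", "tss_bp": 200 + i,
             "ortholog": None}
            for i in range(48)
        ])
        return ExpressionSpec(annotation=ann, n_samples=n_samples, **kw)

    def test_cis_beta_recovered_by_ols(self):
        gmap = _two_marker_map(10.0)
        cross = CrossSpec(map=gmap, n_individuals=10_000,
                          qtl_effects=[QTLEffect("a", "t", 0.0)])
        geno = simulate_f2_genotypes(cross, seed=10)
        td = simulate_traits(geno, cross, seed=11)
        spec = self._spec(n_samples=10_000,
                          cis_effects=[CisEffect("t1", "a", 0.5)])
        ed = simulate_expression(geno, spec, td, seed=12)
        dos = geno.codes[:, 0]
        y = ed.matrix.loc["t1"].to_numpy()
        beta = np.polyfit(dos, y, 1)[0]
        se = spec.noise_sd / np.sqrt(len(y) * dos.var())
        assert abs(beta - 0.5) < 3 * se

    def test_background_transcripts_fall_below_10th_percentile(self):
        gmap = _two_marker_map(10.0)
        cross = CrossSpec(map=gmap, n_individuals=200)
        geno = simulate_f2_genotypes(cross, seed=13)
        td = simulate_traits(geno, CrossSpec(map=gmap, n_individuals=200,
                                             qtl_effects=[QTLEffect("a", "t", 0.0)]),
                             seed=13)
        spec = self._spec(n_samples=126, background_fraction=0.08)
        ed = simulate_expression(geno, spec, td, seed=14)
        means = ed.matrix.mean(axis=1)
        cut = np.percentile(means, 10)
        for tid in ed.truth["background"]:
            assert means[tid] < cut

    def test_trait_link_hits_target_correlation(self):
        gmap = _two_marker_map(10.0)
        cross = CrossSpec(map=gmap, n_individuals=10_000,
                          qtl_effects=[QTLEffect("a", "t", 0.0)])
        geno = simulate_f2_genotypes(cross, seed=15)
        td = simulate_traits(geno, cross, seed=16)
        spec = self._spec(n_samples=10_000,
                          trait_links=[TraitLink("t1", "t", 0.4)])
        ed = simulate_expression(geno, spec, td, seed=17)
        y = td.traits.loc[ed.samples, "t"].to_numpy()
        r = np.corrcoef(ed.matrix.loc["t1"].to_numpy(), y)[0, 1]
        assert 0.3 < r < 0.5

    def test_cis_window_validation(self):
        gmap = _two_marker_map(10.0)
        ann = pd.DataFrame([{"transcript_id": "far", "chrom": "1",
                             "tss_bp": 5_000_000, "ortholog": None}])
        spec = ExpressionSpec(annotation=ann,
                              cis_effects=[CisEffect("far", "a", 0.5)])
        with pytest.raises(ValidationError):
            spec.validate_cis_windows(gmap)


class TestHumanCohort:
    def test_population_zscores_standardized(self):
        spec = HumanCohortSpec(name="c", genes=["g1", "g2"], n_cases=100)
        data = simulate_human_cohort(spec, seed=20)
        z = (data.expression.sub(data.expression.mean(axis=1), axis=0)
             .div(data.expression.std(axis=1, ddof=0), axis=0))
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_null_hazard_gives_uniform_logrank_p(self):
        # hazard ratio 1: log-rank p over seeds should look U(0,1)
        from scipy import stats as sps
        from sysgen.human_expr import km_logrank
        pvals = []
        for seed in range(200):
            spec = HumanCohortSpec(name="c", genes=["g1"], n_cases=120,
                                   risk_genes=["g1"], hazard_ratio=1.0,
                                   censoring_rate=0.3)
            data = simulate_human_cohort(spec, seed=seed)
            rng = np.random.default_rng(seed + 1000)
            grp = pd.Series(rng.random(len(data.survival)) < 0.5,
                            index=data.survival.index)
            if grp.sum() in (0, len(grp)):
                continue
            km = km_logrank(data.survival["time_months"], data.survival["event"], grp)
            pvals.append(km.p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            HumanCohortSpec(name="c", genes=["g"], hazard_ratio=0.0)
        with pytest.raises(ValidationError):
            HumanCohortSpec(name="c", genes=["g"], censoring_rate=1.0)
        with pytest.raises(ValidationError):
            HumanCohortSpec(name="c", genes=["g"], risk_genes=["ghost"])


class TestGwasCohort:
    def test_genotypes_pass_hwe(self):
        spec = GwasSpec(snps=[GwasSnp("s1", "1", 100, 0.3)], n_subjects=10_000)
        fails = 0
        for seed in range(100):
            data = simulate_gwas_cohort(spec, seed=seed)
            n2, n1, n0 = genotype_counts(data.genotypes["s1"].to_numpy())
            if hwe_exact_p(n2, n1, n0) <= 0.001:
                fails += 1
        assert fails <= 1  # per-SNP level 0.001, 100 seeds

    def test_null_plant_gives_no_association_enrichment(self):
        spec = GwasSpec(snps=[GwasSnp("s1", "1", 100, 0.3)], n_subjects=2_000,
                        planted_log_or={"v": {}},
                        variable_intercepts={"v": 0.0})
        data = simulate_gwas_cohort(spec, seed=5)
        y = data.clinical["v"].to_numpy()
        d = data.genotypes["s1"].to_numpy()
        r = np.corrcoef(d, y)[0, 1]
        assert abs(r) < 0.06

    def test_maf_bounds_enforced(self):
        with pytest.raises(ValidationError):
            GwasSpec(snps=[GwasSnp("s1", "1", 100, 0.7)])
        with pytest.raises(ValidationError):
            GwasSpec(snps=[GwasSnp("s1", "1", 100, 0.3)],
                     planted_log_or={"v": {"ghost": 0.5}})

    def test_determinism(self):
        spec = GwasSpec(snps=[GwasSnp("s1", "1", 100, 0.25)], n_subjects=200,
                        planted_log_or={"v": {"s1": 0.4}})
        d1 = simulate_gwas_cohort(spec, seed=3)
        d2 = simulate_gwas_cohort(spec, seed=3)
        assert d1.genotypes.equals(d2.genotypes)
        assert d1.clinical.equals(d2.clinical)
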