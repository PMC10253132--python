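"""Ground-truth properties of the synthetic F2 generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import binmapqtl as bq
from binmapqtl.linkage import kosambi_inverse, haldane_inverse
from binmapqtl.simulate import ExpressionDesign


def _two_site_map(d_cm):
    return bq.SimMap([bq.SimGroup("X", d_cm, np.array([0.0, d_cm]),
                                  np.array([1, 1_000_000]), 2_000_000)])


class TestMeiosis:
    def test_zero_length_group_never_recombines(self):
        m = bq.SimMap([bq.SimGroup("Z", 0.0, np.array([0.0, 0.0]),
                                   np.array([1, 2]), 10)])
        haps, xovers = bq.simulate_meiosis(m, 500, seed=0)
        assert all(len(x["Z"]) == 0 for x in xovers)
        assert np.all(haps[0] == haps[1])

    def test_crossover_count_mean_matches_map_length(self):
        m = bq.SimMap([bq.SimGroup("X", 100.0, np.linspace(0, 100, 11),
                                   np.arange(1, 12) * 1000, 20_000)])
        _, xovers = bq.simulate_meiosis(m, 10_000, seed=1)
        counts = np.array([len(x["X"]) for x in xovers])
        # Poisson(1.0): mean 1, sd 1 -> SE 0.01
        assert counts.mean() == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("d_cm", [1.0, 5.0, 20.0])
    def test_recombinant_fraction_matches_inverse_map(self, d_cm):
        """Under the default Haldane process the two-site recombinant
        fraction equals the inverse Haldane map of the distance; at small
        distances this coincides with the Kosambi inverse."""
        m = _two_site_map(d_cm)
        haps, _ = bq.simulate_meiosis(m, 40_000, seed=int(d_cm * 7))
        frac = float((haps[0] != haps[1]).mean())
        expected = haldane_inverse(d_cm)
        se = np.sqrt(expected * (1 - expected) / 40_000)
        assert abs(frac - expected) < 3 * se
        if d_cm <= 1.0:
            assert frac == pytest.approx(kosambi_inverse(d_cm), abs=3 * se + 1e-4)

    def test_interference_mode_recombinant_fraction(self):
        """The gamma-renewal mode still yields r ≈ d/100 at short distance."""
        m = _two_site_map(1.0)
        haps, _ = bq.simulate_meiosis(m, 40_000, seed=3, interference_shape=2.63)
        frac = float((haps[0] != haps[1]).mean())
        assert frac == pytest.approx(0.01, abs=0.003)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            bq.SimMap([])


class TestF2:
    def test_single_individual_valid_codes(self):
        m = _two_site_map(10.0)
        t = bq.simulate_f2(m, 1, seed=0)
        assert t.diplotypes.shape == (2, 1)
        assert set(np.unique(t.diplotypes)) <= {0, 1, 2}

    def test_genotype_frequencies_1_2_1(self):
        m = _two_site_map(10.0)
        t = bq.simulate_f2(m, 10_000, seed=2)
        counts = np.bincount(t.diplotypes[0], minlength=3)
        chi2, p = bq.segregation_chi2(counts)
        assert p > 0.001

    def test_zero_distance_sites_identical(self):
        m = bq.SimMap([bq.SimGroup("X", 10.0, np.array([5.0, 5.0, 10.0]),
                                   np.array([10, 20, 30]), 100)])
        t = bq.simulate_f2(m, 300, seed=4)
        assert np.array_equal(t.diplotypes[0], t.diplotypes[1])

    def test_crossovers_inside_group_bounds(self, thin_map, f2_population):
        for rec in f2_population.crossovers[:50]:
            for x in rec:
                assert 0 <= x["pos_cm"] <= thin_map.group(x["group"]).length_cm


class TestVariantCalls:
    def test_noiseless_high_depth_recovers_truth(self):
        m = _two_site_map(10.0)
        t = bq.simulate_f2(m, 200, seed=5)
        calls, _ = bq.simulate_variant_calls(t.diplotypes, mean_depth=200,
                                             error_rate=0.0, missing_rate=0.0, seed=6)
        assert np.array_equal(calls, t.diplotypes)

    def test_all_missing_at_rate_one(self):
        m = _two_site_map(10.0)
        t = bq.simulate_f2(m, 50, seed=7)
        calls, ad = bq.simulate_variant_calls(t.diplotypes, missing_rate=0.999999,
                                              seed=8)
        assert np.all(calls == bq.MISSING)

    def test_het_undercall_rate_matches_analytic(self):
        """A heterozygote is called homozygous when all k sampled reads carry
        one allele: rate = E_k[2 (1/2)^k · 1{k>=1}] under Poisson depth."""
        depth = 4.8
        m = _two_site_map(10.0)
        rng = np.random.default_rng(9)
        diplo = np.full((1, 60_000), 1, dtype=np.int8)
        calls, _ = bq.simulate_variant_calls(diplo, mean_depth=depth,
                                             error_rate=0.0, missing_rate=0.0, seed=10)
        k = np.arange(1, 60)
        pk = stats.poisson.pmf(k, depth)
        expected = float((pk * 2 * 0.5 ** k).sum())
        observed = float(((calls == bq.AA) | (calls == bq.BB)).mean())
        se = np.sqrt(expected * (1 - expected) / 60_000)
        assert abs(observed - expected) < 4 * se

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            bq.simulate_variant_calls(np.zeros((2, 2), dtype=np.int8), mean_depth=-1)


class TestPhenotypes:
    def test_variance_share_recovered(self, full_map):
        """The planted QTL's genetic variance share matches its h2."""
        t = bq.simulate_f2(full_map, 10_000, seed=12)
        cfg = bq.SimConfig(n_individuals=10_000, seed=13)
        ph = bq.simulate_phenotypes(full_map, t, [bq.TruthQTL("A09", 81.91, 0.2095)],
                                    cfg)
        share = np.var(t.genetic_values) / np.var(ph["R"])
        assert share == pytest.approx(0.2095, abs=0.02)

    def test_no_qtl_pure_noise(self, thin_map):
        t = bq.simulate_f2(thin_map, 500, seed=14)
        ph = bq.simulate_phenotypes(thin_map, t, [], bq.SimConfig(n_individuals=500, seed=15))
        assert np.allclose(t.genetic_values, t.genetic_values[0])

    def test_excessive_h2_rejected(self, thin_map, f2_population):
        with pytest.raises(ValueError):
            bq.simulate_phenotypes(thin_map, f2_population,
                                   [bq.TruthQTL("A09", 10.0, 0.6),
                                    bq.TruthQTL("C03", 10.0, 0.5)],
                                   bq.SimConfig(seed=0))

    def test_trait_correlations_and_visual_score(self, thin_map, f2_population):
        """Colour channels are strongly correlated; with partial dominance
        toward yellow ~3/4 of the F2 score visual=1 (threshold at the
        black-homozygote mean)."""
        ph = bq.simulate_phenotypes(thin_map, f2_population,
                                    [bq.TruthQTL("A09", 81.91, 0.2095, 0.5)],
                                    bq.SimConfig(seed=16))
        cors = ph[["R", "G", "B", "l", "a", "b"]].corr()["R"]
        assert (cors.drop("R").abs() >= 0.9).all()
        assert (cors[["a", "b"]] < 0).all()
        # genotype-class separation in the planted direction
        assert 0.55 < ph["visual"].mean() < 0.9


class TestExpression:
    def test_zero_noise_perfect_module_correlation(self):
        expr, truth = bq.simulate_expression(60, [20, 20], noise_sd=0.0, seed=17)
        X = np.log2(expr.to_numpy())
        mod = X[truth["module_labels"] == 0]
        c = np.corrcoef(mod)
        assert np.allclose(np.abs(c), 1.0, atol=1e-8)

    def test_replicate_correlation_floor(self):
        expr, truth = bq.simulate_expression(300, [100, 100], seed=18)
        X = np.log2(expr.to_numpy() + 1)
        mod = X[truth["module_labels"] >= 0]
        design = ExpressionDesign()
        cols = list(expr.columns)
        for c1, c2 in [(0, 1), (1, 2), (9, 10)]:
            assert np.corrcoef(mod[:, c1], mod[:, c2])[0, 1] >= 0.96

    def test_planted_degs_detected(self):
        # 3 replicates resolve a -2 log2FC only when replicate noise is
        # small relative to the shift
        expr, truth = bq.simulate_expression(200, [50, 50], n_flavonoid=10,
                                             flavonoid_log2fc=-2.0,
                                             noise_sd=0.1, seed=19)
        groups = {c: c.split("_")[0] for c in expr.columns}
        stages = {c: int(c.split("_")[1][:-3]) for c in expr.columns}
        de = bq.standin_de_test(expr, groups, stages)
        degs = bq.deg_filter(de, stages=[25, 35])
        flagged = set(degs["gene"])
        assert set(truth["flavonoid_genes"]) <= flagged

    def test_bad_module_spec_rejected(self):
        with pytest.raises(ValueError):
            bq.simulate_expression(50, [50])
        with pytest.raises(ValueError):
            bq.simulate_expression(10, [2, 2])


class TestFixtures:
    def test_round_trip(self, tmp_path):
        cfg = bq.SimConfig(n_individuals=24, seed=21)
        paths = bq.write_fixtures(tmp_path, config=cfg, n_sites=120, seed=21)
        vm = bq.read_vcf(paths["vcf"])
        assert vm.n_individuals == 24
        assert vm.n_sites >= 120   # thinning rounds per group
        ph = pd.read_csv(paths["phenotypes"], sep="\t", index_col=0)
        assert list(ph.columns) == ["R", "G", "B", "l", "a", "b", "visual"]
        assert len(ph) == 24
        ann = bq.read_gff3_genes(paths["gff3"])
        assert (ann["start"] >= 1).all()
        assert ann.groupby("chrom")["start"].apply(lambda s: s.is_monotonic_increasing).all()
        import json
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["seed"] == 21
        assert len(truth["crossovers"]) == 24

    def test_vcf_round_trip_exact(self, tmp_path):
        """Writing and re-reading a VCF preserves calls and depths."""
        m = bq.default_map(n_sites=60)
        t = bq.simulate_f2(m, 10, seed=22)
        calls, ad = bq.simulate_variant_calls(t.diplotypes, seed=23)
        vm = bq.VariantMatrix.from_simulation(m, calls, ad,
                                              [f"F2_{i}" for i in range(10)])
        bq.write_vcf(vm, tmp_path / "x.vcf")
        back = bq.read_vcf(tmp_path / "x.vcf")
        assert np.array_equal(back.calls, vm.calls)
        assert np.array_equal(back.allele_depths, vm.allele_depths)
        assert np.array_equal(back.parent_calls, vm.parent_calls)
        assert back.samples == vm.samples
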