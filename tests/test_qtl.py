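"""Haley-Knott scanning: map function, HMM, LOD, permutations, CIs, fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import combqtl as cq
from combqtl.cross import CrossData, GeneticMap
from combqtl.qtl import (ScanResult, genotype_probabilities, haldane_recomb,
                         lod_drop_interval, permutation_thresholds, qtl_fit,
                         scanone_hk)


def tiny_cross(genotypes, positions=(0.0, 20.0), phen=None, cov=None):
    markers = [f"m{i + 1}" for i in range(len(positions))]
    gmap = GeneticMap(pd.DataFrame({"marker": markers, "chrom": "1",
                                    "cM": positions}))
    geno = pd.DataFrame(genotypes, columns=markers)
    n = len(geno)
    phen = pd.DataFrame(phen if phen is not None else {"y": np.zeros(n)},
                        index=geno.index)
    cov = pd.DataFrame(cov or {}, index=geno.index)
    return CrossData(gmap=gmap, genotypes=geno, phenotypes=phen, covariates=cov)


class TestHaldane:
    def test_known_values(self):
        assert haldane_recomb(0.0) == 0.0
        assert abs(haldane_recomb(16.0) - 0.13693) < 1e-5
        assert abs(haldane_recomb(500.0) - 0.5) < 1e-4

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            haldane_recomb(-1.0)

    @given(st.floats(0.0, 1000.0))
    def test_range_and_monotone(self, d):
        r = haldane_recomb(d)
        assert 0.0 <= r < 0.5
        assert haldane_recomb(d + 1.0) > r or d > 900


class TestGenotypeProbabilities:
    def test_typed_marker_is_indicator(self):
        cross = tiny_cross([["RW", "RR"]])
        probs = genotype_probabilities(cross, error_prob=0.0)
        np.testing.assert_allclose(probs.chrom_probs["1"][0, 0], [0, 1, 0])
        np.testing.assert_allclose(probs.chrom_probs["1"][1, 0], [1, 0, 0])

    def test_midpoint_matches_enumeration_oracle(self):
        # typed RR at both flanking markers 20 cM apart; the midpoint
        # posterior follows from enumerating the 3 midpoint states
        cross = tiny_cross([["RR", "RR"]])
        probs = genotype_probabilities(cross, step=10.0)
        mid = probs.chrom_probs["1"][1, 0]
        r = haldane_recomb(10.0)
        t_rr = np.array([(1 - r) ** 2, 2 * r * (1 - r), r**2])
        t_to_rr = np.array([(1 - r) ** 2, r * (1 - r), r**2])
        oracle = t_rr * t_to_rr
        oracle /= oracle.sum()
        np.testing.assert_allclose(mid, oracle, atol=1e-12)
        assert mid[0] > 0.93
        assert abs(mid.sum() - 1.0) < 1e-9

    def test_all_missing_gives_f2_prior(self):
        cross = tiny_cross([[np.nan, np.nan]], positions=(0.0, 30.0))
        probs = genotype_probabilities(cross, step=15.0)
        for k in range(3):
            np.testing.assert_allclose(probs.chrom_probs["1"][k, 0],
                                       [0.25, 0.5, 0.25], atol=1e-12)

    def test_triples_sum_to_one(self, qtl_cross, qtl_probs):
        for chrom in qtl_probs.chromosomes:
            s = qtl_probs.chrom_probs[chrom].sum(axis=2)
            np.testing.assert_allclose(s, 1.0, atol=1e-9)

    def test_dosage_definition(self, qtl_probs):
        p = qtl_probs.chrom_probs["1"]
        d = qtl_probs.dosages("1")
        np.testing.assert_allclose(d[..., 0], p[..., 2] - p[..., 0])
        np.testing.assert_allclose(d[..., 1], p[..., 1])


def ols_lod_oracle(y, X0, X1):
    """(n/2) log10(RSS0/RSS1) via independent normal-equation solves."""
    b0 = np.linalg.lstsq(X0, y, rcond=None)[0]
    b1 = np.linalg.lstsq(X1, y, rcond=None)[0]
    rss0 = float(((y - X0 @ b0) ** 2).sum())
    rss1 = float(((y - X1 @ b1) ** 2).sum())
    return (len(y) / 2.0) * np.log10(rss0 / rss1)


class TestScanoneHK:
    def test_matches_ols_oracle_with_covariates(self, qtl_cross, qtl_probs):
        scan = scanone_hk(qtl_cross, "area", ["sex", "weight"], probs=qtl_probs)
        cov = qtl_cross.covariates
        X0 = np.column_stack([np.ones(qtl_cross.n_individuals),
                              cov["sex"].to_numpy(float),
                              cov["weight"].to_numpy(float)])
        y = qtl_cross.phenotypes["area"].to_numpy(float)
        worst = 0.0
        for chrom in qtl_probs.chromosomes:
            D = qtl_probs.dosages(chrom)
            lods = scan.chrom(chrom)["lod"].to_numpy()
            for k in range(D.shape[0]):
                lod = ols_lod_oracle(y, X0, np.column_stack([X0, D[k]]))
                worst = max(worst, abs(lod - lods[k]))
        assert worst < 1e-8

    def test_perfect_fit_capped_lod(self, qtl_cross, qtl_probs):
        mk = qtl_cross.gmap.marker_names[5]
        dose = {"RR": -1.0, "RW": 0.0, "WW": 1.0}
        y = qtl_cross.genotypes[mk].map(dose).astype(float) + 3.0
        cross2 = CrossData(qtl_cross.gmap, qtl_cross.genotypes,
                           pd.DataFrame({"exact": y}), qtl_cross.covariates)
        scan = scanone_hk(cross2, "exact", probs=qtl_probs)
        assert scan.table.set_index("name").loc[mk, "lod"] > 100

    def test_affine_invariance(self, qtl_cross, qtl_probs):
        s1 = scanone_hk(qtl_cross, "area", ["sex"], probs=qtl_probs)
        ph = qtl_cross.phenotypes.assign(scaled=qtl_cross.phenotypes["area"] * 7.5 - 100)
        cross2 = CrossData(qtl_cross.gmap, qtl_cross.genotypes, ph,
                           qtl_cross.covariates)
        s2 = scanone_hk(cross2, "scaled", ["sex"], probs=qtl_probs)
        np.testing.assert_allclose(s2.table["lod"], s1.table["lod"], atol=1e-9)

    def test_orthogonal_covariate_barely_changes_lod(self, small_geno, small_map):
        # a balanced covariate independent of genotype should not move LOD
        q = cq.QTLSpec(chromosome="2", position=50.0, additive_effect=0.7,
                       trait_name="t")
        tab = cq.simulate_quantitative_trait(small_geno, small_map, [q],
                                             noise_sd=1.0, seed=77)
        cross = cq.to_cross(small_geno, tab)
        probs = genotype_probabilities(cross)
        s1 = scanone_hk(cross, "t", probs=probs)
        s2 = scanone_hk(cross, "t", ["sex"], probs=probs)
        assert np.abs(s2.table["lod"] - s1.table["lod"]).max() < 0.05 * (
            1 + s1.max_lod())

    def test_zero_variance_trait_rejected(self, qtl_cross):
        ph = qtl_cross.phenotypes.assign(flat=1.0)
        cross2 = CrossData(qtl_cross.gmap, qtl_cross.genotypes, ph,
                           qtl_cross.covariates)
        with pytest.raises(ValueError, match="variance"):
            scanone_hk(cross2, "flat")

    def test_collinear_covariates_named(self, qtl_cross):
        cov = qtl_cross.covariates.assign(dup=qtl_cross.covariates["sex"] * 2.0)
        cross2 = CrossData(qtl_cross.gmap, qtl_cross.genotypes,
                           qtl_cross.phenotypes, cov)
        with pytest.raises(ValueError, match="dup"):
            scanone_hk(cross2, "area", ["sex", "dup"])

    def test_interactive_covariate_lod_at_least_additive(self, qtl_cross, qtl_probs):
        s_add = scanone_hk(qtl_cross, "area", ["sex"], probs=qtl_probs)
        s_int = scanone_hk(qtl_cross, "area", ["sex"],
                           interactive_covariate="sex", probs=qtl_probs)
        assert np.all(s_int.table["lod"] >= s_add.table["lod"] - 1e-9)

    def test_missing_phenotypes_dropped(self, qtl_cross, qtl_probs):
        ph = qtl_cross.phenotypes.copy()
        ph.iloc[:10, ph.columns.get_loc("area")] = np.nan
        cross2 = CrossData(qtl_cross.gmap, qtl_cross.genotypes, ph,
                           qtl_cross.covariates)
        scan = scanone_hk(cross2, "area", probs=None)
        assert scan.n == qtl_cross.n_individuals - 10


class TestPermutations:
    def test_threshold_ordering_and_determinism(self, qtl_cross, qtl_probs):
        p1 = permutation_thresholds(qtl_cross, "area", ["sex"], n_perm=300,
                                    seed=9, probs=qtl_probs)
        p2 = permutation_thresholds(qtl_cross, "area", ["sex"], n_perm=300,
                                    seed=9, probs=qtl_probs)
        assert p1.threshold(0.95) >= p1.threshold(0.80)
        np.testing.assert_array_equal(p1.maxima, p2.maxima)

    def test_seed_to_seed_envelope(self, qtl_cross, qtl_probs):
        thr = [permutation_thresholds(qtl_cross, "area", ["sex"], n_perm=1000,
                                      seed=s, probs=qtl_probs).threshold(0.95)
               for s in (1, 2, 3)]
        assert max(thr) - min(thr) < 0.3

    def test_pvalue_of_huge_lod_is_zero_and_tiny_is_one(self, qtl_cross, qtl_probs):
        p = permutation_thresholds(qtl_cross, "area", n_perm=200, seed=4,
                                   probs=qtl_probs)
        assert p.pvalue(1e6) == 0.0
        assert p.pvalue(0.0) == 1.0

    def test_invalid_inputs(self, qtl_cross):
        with pytest.raises(ValueError):
            permutation_thresholds(qtl_cross, "area", n_perm=10)
        with pytest.raises(ValueError):
            permutation_thresholds(qtl_cross, "area", n_perm=200,
                                   quantiles=(1.5,))


class TestLodDropInterval:
    def triangle_scan(self):
        pos = np.arange(0.0, 101.0, 2.0)
        lod = 10.0 - 0.1 * np.abs(pos - 50.0)
        table = pd.DataFrame({"chrom": "1", "name": [f"m{p:g}" for p in pos],
                              "cM": pos, "lod": lod})
        gmap = GeneticMap(pd.DataFrame({"marker": [f"m{p:g}" for p in pos],
                                        "chrom": "1", "cM": pos}))
        return ScanResult(table, "t", (), None, 100), gmap

    def test_triangular_curve(self):
        scan, gmap = self.triangle_scan()
        ci = lod_drop_interval(scan, "1", 50.0, drop=1.8, gmap=gmap)
        assert ci == (32.0, 68.0)

    def test_flat_curve_spans_chromosome(self):
        pos = np.arange(0.0, 101.0, 10.0)
        table = pd.DataFrame({"chrom": "1", "name": [f"m{p:g}" for p in pos],
                              "cM": pos, "lod": 3.0})
        scan = ScanResult(table, "t", (), None, 100)
        assert lod_drop_interval(scan, "1", 50.0) == (0.0, 100.0)

    def test_off_grid_peak_rejected(self):
        scan, _ = self.triangle_scan()
        with pytest.raises(ValueError, match="grid"):
            lod_drop_interval(scan, "1", 51.0)


class TestQTLFit:
    def test_noise_free_exact_recovery(self, small_geno, small_map):
        q = cq.QTLSpec(chromosome="2", position=50.0, additive_effect=1.0,
                       dominance_effect=0.5, trait_name="t")
        tab = cq.simulate_quantitative_trait(small_geno, small_map, [q],
                                             noise_sd=0.0, seed=3)
        cross = cq.to_cross(small_geno, tab)
        peak = qtl_fit(cross, "t", (), "2", 50.0)
        assert abs(peak.additive_effect - 1.0) < 1e-8
        assert abs(peak.dominance_effect - 0.5) < 1e-8
        assert 0.0 <= peak.pct_var <= 100.0

    def test_unbiased_additive_estimate(self):
        ests = []
        for rep in range(30):
            cfg = cq.SimConfig(n_chromosomes=2, chr_length=100,
                               marker_spacing=10, n_individuals=300,
                               seed=600 + rep)
            gmap = cq.simulate_map(cfg)
            geno = cq.simulate_ail_genotypes(gmap, cfg)
            q = cq.QTLSpec(chromosome="1", position=50.0, additive_effect=0.5,
                           trait_name="t")
            tab = cq.simulate_quantitative_trait(geno, gmap, [q], noise_sd=1.0,
                                                 seed=rep)
            cross = cq.to_cross(geno, tab)
            ests.append(qtl_fit(cross, "t", (), "1", 50.0).additive_effect)
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.5) < 3 * sem + 1e-9

    def test_pct_var_bounds(self, qtl_cross, qtl_probs):
        peak = qtl_fit(qtl_cross, "area", ["sex", "weight"], "2", 50.0,
                       probs=qtl_probs)
        assert 0.0 <= peak.pct_var <= 100.0
        assert peak.additive_se > 0 and peak.dominance_se > 0
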