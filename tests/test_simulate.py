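"""Synthetic intercross generator: map, breeding, traits, outlines, expression."""

import numpy as np
import pytest

import combqtl as cq
from combqtl.morphometrics import (EFACoefficients, Outline, efa_decompose,
                                   efa_reconstruct, interpolate_outline,
                                   smooth_outline, trace_outline)
from combqtl.simulate import (ExpressionSpec, QTLSpec, SimConfig,
                              noise_sd_for_pve, render_outline_mask,
                              simulate_ail_genotypes,
                              simulate_expression_matrix, simulate_map,
                              simulate_outline_population,
                              simulate_quantitative_trait)


class TestSimulateMap:
    def test_single_chromosome_grid(self):
        cfg = SimConfig(n_chromosomes=1, chr_length=100, marker_spacing=20)
        gmap = simulate_map(cfg)
        np.testing.assert_allclose(gmap.positions("1"), [0, 20, 40, 60, 80, 100])

    def test_study_scale_marker_count(self):
        cfg = SimConfig(n_chromosomes=10, chr_length=920, marker_spacing=16,
                        n_individuals=326)
        gmap = simulate_map(cfg)
        assert gmap.n_markers == 10 * (int(920 // 16) + 1) == 580

    def test_bp_positions_affine(self):
        gmap = simulate_map(SimConfig(n_chromosomes=1, chr_length=50,
                                      marker_spacing=25, bp_per_cm=1e5))
        np.testing.assert_allclose(gmap.chrom_table("1")["bp"], [0, 2.5e6, 5e6])

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(marker_spacing=0)

    def test_unique_increasing(self, small_map):
        assert len(set(small_map.marker_names)) == small_map.n_markers
        for chrom in small_map.chromosomes:
            assert np.all(np.diff(small_map.positions(chrom)) > 0)


class TestBreeding:
    def test_f1_fully_heterozygous(self, small_map):
        cfg = SimConfig(n_chromosomes=3, chr_length=100, marker_spacing=10,
                        n_individuals=50, n_generations=2, seed=3)
        geno = simulate_ail_genotypes(small_map, cfg)
        assert np.all(geno.codes == 1)

    def test_f8_allele_frequencies_bounded_by_drift(self):
        # differentially fixed founders start at 0.5; drift at the breeding
        # population size keeps >95% of markers within [0.35, 0.65]
        cfg = SimConfig(seed=5)
        gmap = simulate_map(cfg)
        geno = simulate_ail_genotypes(gmap, cfg)
        freq_r = 1.0 - geno.codes.mean(axis=0) / 2.0
        assert np.mean((freq_r >= 0.35) & (freq_r <= 0.65)) > 0.95

    def test_map_expansion_f8_vs_f2(self):
        # recombinant fraction between adjacent markers grows with the
        # number of intercross generations
        def adj_recomb(n_gen, seed):
            cfg = SimConfig(n_chromosomes=4, chr_length=96, marker_spacing=16,
                            n_individuals=200, n_generations=n_gen, seed=seed)
            gmap = simulate_map(cfg)
            geno = simulate_ail_genotypes(gmap, cfg)
            fracs = []
            col = 0
            for chrom in gmap.chromosomes:
                m = len(gmap.positions(chrom))
                sub = geno.codes[:, col:col + m].astype(float)
                col += m
                # opposite-homozygote adjacency signals recombination
                diff = np.abs(np.diff(sub, axis=1))
                fracs.append(diff.mean() / 2.0)
            return float(np.mean(fracs))

        f2 = np.mean([adj_recomb(3, s) for s in range(8)])
        f8 = np.mean([adj_recomb(9, s) for s in range(8)])
        assert f8 > f2 * 1.5

    def test_seeded_runs_reproducible(self, small_map, small_cfg):
        g1 = simulate_ail_genotypes(small_map, small_cfg)
        g2 = simulate_ail_genotypes(small_map, small_cfg)
        assert np.array_equal(g1.codes, g2.codes)
        assert np.array_equal(g1.family, g2.family)

    def test_overbreeding_rejected(self):
        with pytest.raises(ValueError, match="selfing"):
            SimConfig(n_founder_pairs=2, n_individuals=300)


class TestQuantitativeTrait:
    def test_pure_noise_variance(self, small_geno, small_map):
        tab = simulate_quantitative_trait(small_geno, small_map, [],
                                          noise_sd=1.0, seed=1)
        v = float(tab.phenotypes["trait"].var())
        assert 0.85 < v < 1.15 or abs(v - 1) < 0.3  # n=120: generous band

    def test_noise_free_three_genotype_values(self, small_geno, small_map):
        q = QTLSpec(chromosome="1", position=50.0, additive_effect=1.0,
                    trait_name="t")
        tab = simulate_quantitative_trait(small_geno, small_map, [q],
                                          noise_sd=0.0, seed=2)
        vals = np.unique(np.round(tab.phenotypes["t"].to_numpy(), 9))
        np.testing.assert_allclose(vals, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_pve_targeting_monte_carlo(self):
        r2 = []
        for rep in range(25):
            cfg = SimConfig(n_chromosomes=2, chr_length=100, marker_spacing=10,
                            n_individuals=300, seed=400 + rep)
            gmap = simulate_map(cfg)
            geno = simulate_ail_genotypes(gmap, cfg)
            q = QTLSpec(chromosome="1", position=50.0, additive_effect=0.5,
                        trait_name="t")
            pilot = simulate_quantitative_trait(geno, gmap, [q], noise_sd=1.0,
                                                seed=rep)
            sd = noise_sd_for_pve(pilot.genetic_values["t"], 0.10)
            tab = simulate_quantitative_trait(geno, gmap, [q], noise_sd=sd,
                                              seed=rep)
            g = tab.genetic_values["t"].to_numpy()
            y = tab.phenotypes["t"].to_numpy()
            r2.append(np.corrcoef(g, y)[0, 1] ** 2)
        assert 0.05 < float(np.mean(r2)) < 0.15

    def test_pve_converges_at_large_n(self):
        r2 = []
        for rep in range(10):
            cfg = SimConfig(n_chromosomes=1, chr_length=100, marker_spacing=10,
                            n_individuals=1000, n_founder_pairs=50,
                            n_breeding_pairs=50, seed=900 + rep)
            gmap = simulate_map(cfg)
            geno = simulate_ail_genotypes(gmap, cfg)
            q = QTLSpec(chromosome="1", position=50.0, additive_effect=0.5,
                        trait_name="t")
            pilot = simulate_quantitative_trait(geno, gmap, [q], noise_sd=1.0,
                                                seed=rep)
            sd = noise_sd_for_pve(pilot.genetic_values["t"], 0.10)
            tab = simulate_quantitative_trait(geno, gmap, [q], noise_sd=sd,
                                              seed=rep)
            g = tab.genetic_values["t"].to_numpy()
            y = tab.phenotypes["t"].to_numpy()
            r2.append(np.corrcoef(g, y)[0, 1] ** 2)
        assert abs(float(np.mean(r2)) - 0.10) < 0.03

    def test_qtl_off_map_rejected(self, small_geno, small_map):
        q = QTLSpec(chromosome="9", position=10.0, trait_name="t")
        with pytest.raises(ValueError, match="chromosome"):
            simulate_quantitative_trait(small_geno, small_map, [q], seed=1)
        q2 = QTLSpec(chromosome="1", position=1e4, trait_name="t")
        with pytest.raises(ValueError, match="position"):
            simulate_quantitative_trait(small_geno, small_map, [q2], seed=1)


class TestOutlinePopulation:
    mean = EFACoefficients([2, 0, 0.05], [0, 0.08, 0], [0, 0.1, 0], [1, 0, 0.04])

    def test_zero_effect_zero_noise_identical(self, small_geno):
        q = QTLSpec(chromosome="1", position=30.0, trait_name="s")
        outs = simulate_outline_population(small_geno, q, self.mean,
                                           np.zeros(12), noise_sd=0.0,
                                           n_points=100, seed=1)
        ref = efa_reconstruct(self.mean, 100)
        for o in outs[:10]:
            np.testing.assert_allclose(o.points, ref.points, atol=1e-12)

    def test_ellipse_mean_aspect_ratio(self, small_geno):
        q = QTLSpec(chromosome="1", position=30.0, trait_name="s")
        mean = EFACoefficients([2], [0], [0], [1])
        outs = simulate_outline_population(small_geno, q, mean, np.zeros(4),
                                           noise_sd=0.0, n_points=200, seed=1)
        ext = np.ptp(outs[0].points, axis=0)
        assert abs(ext[0] / ext[1] - 2.0) < 1e-6

    def test_planted_shape_axis_recovered_by_pca(self, small_geno, small_map):
        from combqtl.morphometrics import align_outlines, shape_pca

        q = QTLSpec(chromosome="2", position=50.0, additive_effect=1.0,
                    trait_name="s")
        eff = np.zeros(12)
        eff[0] = 0.08
        outs = simulate_outline_population(small_geno, q, self.mean, eff,
                                           noise_sd=0.0, n_points=150, seed=2)
        aligned = align_outlines([interpolate_outline(o, 150) for o in outs])
        mat = np.stack([efa_decompose(o, 3).flatten() for o in aligned.outlines])
        pca = shape_pca(mat)
        mk = small_map.nearest_marker("2", 50.0)["marker"]
        dose = small_geno.additive_dosage(mk)
        assert abs(np.corrcoef(pca.scores[:, 0], dose)[0, 1]) > 0.99

    def test_zero_harmonics_rejected(self, small_geno):
        q = QTLSpec(chromosome="1", position=30.0, trait_name="s")
        bad = EFACoefficients([0], [0], [0], [0])
        with pytest.raises(ValueError):
            simulate_outline_population(small_geno, q, bad, np.zeros(4), seed=1)


class TestExpression:
    def probe_spec(self, **kw):
        pos = {f"p{i}": (str(1 + i % 3), 10.0 * (i % 9)) for i in range(12)}
        base = dict(probe_positions=pos, noise_sd=0.5)
        base.update(kw)
        return ExpressionSpec(**base)

    def test_null_variance_decomposition(self, small_geno, small_map):
        pos = {f"p{i}": ("1", 50.0) for i in range(100)}
        spec = ExpressionSpec(probe_positions=pos, noise_sd=0.7,
                              batch_effect_sd=0.4, n_batches=4)
        sim = simulate_expression_matrix(small_geno, small_map, spec, seed=4)
        per_probe_var = sim.values.var(axis=1, ddof=1)
        expect = 0.7**2 + 0.4**2
        assert abs(per_probe_var.mean() / expect - 1.0) < 0.15

    def test_trans_regulator_on_other_chromosome_labeled(self, small_geno, small_map):
        spec = self.probe_spec(trans_pairs=(("p0", "3", 40.0, 2.0),))
        sim = simulate_expression_matrix(small_geno, small_map, spec, seed=5)
        assert sim.truth.set_index("probe").loc["p0", "label"] == "trans"
        assert sim.truth.set_index("probe").loc["p1", "label"] == "none"

    def test_unknown_probe_chromosome_rejected(self, small_geno, small_map):
        spec = ExpressionSpec(probe_positions={"p": ("77", 10.0)})
        with pytest.raises(ValueError, match="chromosome"):
            simulate_expression_matrix(small_geno, small_map, spec, seed=1)

    def test_cis_effect_shifts_expression_with_dose(self, small_geno, small_map):
        spec = self.probe_spec(cis_probes=("p0",), cis_effect_size=2.0,
                               noise_sd=0.1)
        sim = simulate_expression_matrix(small_geno, small_map, spec, seed=6)
        chrom, cm = spec.probe_positions["p0"]
        mk = small_map.nearest_marker(chrom, cm)["marker"]
        dose = small_geno.additive_dosage(mk)
        r = np.corrcoef(sim.values.loc["p0"].to_numpy(), dose)[0, 1]
        assert r > 0.95


class TestRenderMask:
    def test_circle_area(self):
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        circ = Outline(np.column_stack([np.cos(t), np.sin(t)]))
        mask = render_outline_mask(circ, 512)
        scale = 0.45 * 512
        assert abs(mask.sum() / (np.pi * scale**2) - 1.0) < 0.02

    def test_single_component(self, rng):
        from skimage import measure

        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        blob = Outline(np.column_stack([(2 + 0.2 * np.cos(3 * t)) * np.cos(t),
                                        (1 + 0.1 * np.sin(2 * t)) * np.sin(t)]))
        mask = render_outline_mask(blob, 256)
        assert measure.label(mask).max() == 1

    def test_mask_trace_efa_roundtrip(self):
        src_co = EFACoefficients([2, 0.1, 0.05, 0, 0], [0, 0.08, 0, 0.02, 0],
                                 [0, 0.1, 0.02, 0, 0.01], [1, 0, 0.04, 0, 0])
        src = efa_reconstruct(src_co, 2000)
        ref = efa_decompose(interpolate_outline(src, 600), 5)
        traced = trace_outline(render_outline_mask(src, 512))
        rec = efa_decompose(interpolate_outline(smooth_outline(traced, 20), 600), 5)
        amp_ref = np.sqrt(ref.power()); amp_ref /= amp_ref[0]
        amp_rec = np.sqrt(rec.power()); amp_rec /= amp_rec[0]
        np.testing.assert_allclose(amp_rec, amp_ref, rtol=0.01, atol=1e-4)

    def test_degenerate_outline_rejected(self):
        line = Outline(np.array([[0, 0], [1, 0], [2, 0], [3, 0.0]]))
        with pytest.raises(ValueError, match="area"):
            render_outline_mask(line, 128)

    def test_low_resolution_rejected(self):
        t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        circ = Outline(np.column_stack([np.cos(t), np.sin(t)]))
        with pytest.raises(ValueError):
            render_outline_mask(circ, 8)
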