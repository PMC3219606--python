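"""Simulator checks: map construction, founder panels, meiosis/selfing
expectations, trait architectures and phenotype generation."""

import numpy as np
import pandas as pd
import pytest

import namqtl as nq
from namqtl.simulate import founder_at


class TestGeneticMap:
    def test_deterministic_and_sorted(self):
        a = nq.make_genetic_map(1, 100.0, 1e6, 10, seed=1)
        b = nq.make_genetic_map(1, 100.0, 1e6, 10, seed=1)
        pos = a.markers["cm"].to_numpy()
        assert np.all(np.diff(pos) > 0)
        assert pos.min() >= 0 and pos.max() <= 100
        pd.testing.assert_frame_equal(a.markers, b.markers)

    def test_mean_spacing_matches_nam_scale(self):
        # 836 markers over a 1400 cM genome: mean gap ~1.3 cM
        counts = [84] * 6 + [83] * 4
        g = nq.make_genetic_map(10, 140.0, 2e8, counts, seed=2)
        assert g.n_markers == 836
        gaps = np.concatenate([
            np.diff(grp["cm"].to_numpy()) for _, grp in g.markers.groupby("chrom")])
        expected = 10 * 140.0 / (836 - 10)
        assert gaps.mean() == pytest.approx(expected, rel=0.2)
        assert expected == pytest.approx(1.3, abs=0.45)

    def test_two_marker_chromosome_within_bounds(self):
        g = nq.make_genetic_map(1, 50.0, 1e6, 2, seed=3)
        assert ((g.markers["cm"] >= 0) & (g.markers["cm"] <= 50)).all()

    @pytest.mark.parametrize("bad", [
        dict(n_chrom=1, cm_lengths=-5.0, bp_lengths=1e6, n_markers=5),
        dict(n_chrom=1, cm_lengths=100.0, bp_lengths=1e6, n_markers=1),
    ])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            nq.make_genetic_map(seed=1, **bad)

    def test_cm_bp_interpolation_monotone(self, gmap):
        for chrom in gmap.chromosomes.index:
            cm = np.linspace(0, gmap.chromosomes.loc[chrom, "length_cm"], 50)
            bp = gmap.cm_to_bp(chrom, cm)
            assert np.all(np.diff(bp) >= 0)
            back = gmap.bp_to_cm(chrom, bp)
            assert np.allclose(back, cm, atol=1e-6)


class TestFounderPanel:
    def test_every_snp_segregates(self, panel):
        assert (panel.family_frequency() >= 1).all()
        assert (panel.alleles[:, 0] == 0).all()

    def test_maf_half_gives_binomial_mean(self):
        g = nq.make_genetic_map(2, 100.0, 1e6, 10, seed=4)
        p = nq.simulate_founders(g, 27, 4000, maf_spectrum=0.5, seed=5)
        # E[#alt carriers | >=1] = 13 / (1 - 2^-26) ~ 13 of 26
        assert p.family_frequency().mean() == pytest.approx(13.0, rel=0.03)

    def test_deterministic(self):
        g = nq.make_genetic_map(2, 100.0, 1e6, 10, seed=4)
        a = nq.simulate_founders(g, 6, 200, seed=6)
        b = nq.simulate_founders(g, 6, 200, seed=6)
        assert np.array_equal(a.alleles, b.alleles)
        pd.testing.assert_frame_equal(a.snps, b.snps)

    def test_bad_maf_rejected(self):
        g = nq.make_genetic_map(1, 100.0, 1e6, 5, seed=1)
        with pytest.raises(ValueError):
            nq.simulate_founders(g, 4, 10, maf_spectrum=1.5, seed=1)


class TestRILSimulation:
    def test_f2_heterozygosity_half(self):
        g = nq.make_genetic_map(2, 120.0, 1e6, 15, seed=7)
        r = nq.simulate_ril_family((0, 1), g, 800, n_selfing=1, seed=8)
        assert 1 - r.homozygosity() == pytest.approx(0.5, abs=0.03)

    def test_ssd_residual_heterozygosity(self):
        # five selfing generations from the F1: het = 2^-5, ~97% homozygous
        g = nq.make_genetic_map(3, 150.0, 1e6, 20, seed=9)
        r = nq.simulate_ril_family((0, 1), g, 1200, n_selfing=5, seed=10)
        hom = np.mean((r.genotypes == 0) | (r.genotypes == 1), axis=1)
        se = hom.std(ddof=1) / np.sqrt(len(hom))
        assert abs(hom.mean() - (1 - 0.5 ** 5)) < 3 * se + 1e-9

    def test_zero_length_chromosome_never_recombines(self):
        from namqtl.simulate import _meiosis
        rng = np.random.default_rng(2)
        hap_a = (np.array([0.0]), np.array([0]))
        hap_b = (np.array([0.0]), np.array([1]))
        for _ in range(200):
            breaks, founders = _meiosis(hap_a, hap_b, 0.0, rng)
            assert len(founders) == 1  # Poisson(0) crossovers: intact gamete

    def test_identical_founders_rejected(self, gmap):
        with pytest.raises(ValueError, match="degenerate"):
            nq.simulate_ril_family((1, 1), gmap, 5, seed=1)

    def test_mosaic_oracle_reproduces_genotypes(self, rils):
        assert np.array_equal(rils.genotypes_from_mosaics(), rils.genotypes)

    def test_two_founders_per_family(self, rils):
        for i in range(0, rils.n_rils, 97):
            fam = rils.lines["family"].iat[i]
            labels = set()
            for chrom in rils.mosaics[i]:
                for hap in rils.mosaics[i][chrom]:
                    labels |= set(hap[1].tolist())
            assert labels <= set(rils.family_parents[fam])

    def test_haldane_recombination_fraction(self):
        """F2-gamete recombinant fractions follow r = (1 - exp(-2d/100))/2."""
        g = nq.make_genetic_map(1, 100.0, 1e6, 6, seed=20)
        r = nq.simulate_ril_family((0, 1), g, 4000, n_selfing=1, seed=21)
        cm = g.markers["cm"].to_numpy()
        # score recombination between adjacent markers on single gametes
        h0_states = np.array([
            [founder_at(m[1][0], c) for c in cm] for m in r.mosaics])
        for j in range(len(cm) - 1):
            d = cm[j + 1] - cm[j]
            expected = (1 - np.exp(-2 * d / 100)) / 2
            obs = np.mean(h0_states[:, j] != h0_states[:, j + 1])
            se = np.sqrt(expected * (1 - expected) / len(h0_states))
            assert abs(obs - expected) < 4 * se + 1e-9


class TestTraitArchitecture:
    def test_common_parent_effect_zero(self, arch):
        assert np.all(arch.effects["A"][:, 0] == 0)

    def test_full_correlation_gives_proportional_vectors(self, panel, gmap):
        a = nq.simulate_trait_architecture(
            panel, gmap,
            {"A": {"n_qtl": 2, "category": "x"}, "B": {"n_qtl": 2, "category": "y"}},
            pleiotropy_spec=[{"traits": ("A", "B"), "n_shared": 2,
                              "correlation": 1.0}],
            category_scales={"x": 1.0, "y": 3.0}, seed=30)
        shared_a = a.qtl["A"].merge(a.qtl["B"], on=["chrom", "cm"])
        assert len(shared_a) == 2
        for q in range(2):
            ea, eb = a.effects["A"][:, 1:], a.effects["B"][:, 1:]
            # positions sorted identically, so shared QTL align by position
            r = np.corrcoef(ea[q], eb[q])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_undeclared_trait_rejected(self, panel, gmap):
        with pytest.raises(ValueError, match="undeclared"):
            nq.simulate_trait_architecture(
                panel, gmap, {"A": {"n_qtl": 1, "category": "x"}},
                pleiotropy_spec=[{"traits": ("A", "Z"), "n_shared": 1}], seed=1)

    def test_category_scale_ratio(self, panel, gmap):
        a = nq.simulate_trait_architecture(
            panel, gmap,
            {"A": {"n_qtl": 40, "category": "small"},
             "B": {"n_qtl": 40, "category": "big"}},
            category_scales={"small": 1.0, "big": 2.0}, seed=31)
        ratio = (np.abs(a.effects["B"][:, 1:]).mean()
                 / np.abs(a.effects["A"][:, 1:]).mean())
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestPhenotypes:
    def test_balanced_and_finite(self, pheno, rils):
        counts = pheno.groupby(["line", "environment"]).size()
        assert (counts == 1).all()
        assert len(pheno) == rils.n_rils * 8
        assert np.isfinite(pheno["value"]).all()

    def test_h2_target_recovered(self, pheno):
        vc = nq.estimate_variance_components(pheno)
        assert nq.broad_sense_H2(vc, 8) == pytest.approx(0.9, abs=0.05)

    def test_invalid_h2_rejected(self, rils, arch):
        with pytest.raises(ValueError):
            nq.simulate_phenotypes(rils, arch, n_env=2, H2_target=1.5, seed=1)

    def test_null_architecture_pure_noise(self, rils, panel, gmap):
        a0 = nq.simulate_trait_architecture(
            panel, gmap, {"N": {"n_qtl": 0, "category": "x"}}, seed=32)
        ph = nq.simulate_phenotypes(rils, a0, n_env=2, H2_target=0.9, seed=33)
        g = nq.genetic_values(rils, a0, "N")
        assert np.all(g == 0)
        assert ph["value"].std() > 0
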