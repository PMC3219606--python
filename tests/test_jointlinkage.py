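"""Stepwise joint-linkage mapping: permutation thresholds, selection
behaviour, effect recovery and refitting."""

import numpy as np
import pandas as pd
import pytest

import namqtl as nq
from namqtl.jointlinkage import center_within_family, family_codes


class TestPermutationThreshold:
    def test_threshold_in_unit_interval(self, jl_threshold):
        assert 0 < jl_threshold.p_enter < 1
        assert jl_threshold.p_enter <= jl_threshold.p_exit

    def test_alpha_one_is_max_minimum(self, rils, blups_y):
        _, _, y = blups_y
        thr = nq.jl_permutation_threshold(rils.genotypes, y, rils.families,
                                          n_perm=120, alpha=0.9999, seed=70)
        assert thr.p_enter == pytest.approx(thr.minima.max())

    def test_deterministic_given_seed(self, rils, blups_y):
        _, _, y = blups_y
        a = nq.jl_permutation_threshold(rils.genotypes, y, rils.families,
                                        n_perm=120, alpha=0.05, seed=71)
        b = nq.jl_permutation_threshold(rils.genotypes, y, rils.families,
                                        n_perm=120, alpha=0.05, seed=71)
        assert a.p_enter == b.p_enter

    def test_threshold_stable_under_more_permutations(self, rils, blups_y):
        _, _, y = blups_y
        small = nq.jl_permutation_threshold(rils.genotypes, y, rils.families,
                                            n_perm=300, alpha=0.05, seed=72)
        big = nq.jl_permutation_threshold(rils.genotypes, y, rils.families,
                                          n_perm=600, alpha=0.05, seed=73)
        # thresholds are tiny numbers; compare on log scale within MC spread
        assert abs(np.log10(small.p_enter) - np.log10(big.p_enter)) < 1.0

    def test_too_few_permutations_rejected(self, rils, blups_y):
        _, _, y = blups_y
        with pytest.raises(ValueError):
            nq.jl_permutation_threshold(rils.genotypes, y, rils.families,
                                        n_perm=50, seed=1)

    def test_within_family_permutation_preserves_family_means(self):
        rng = np.random.default_rng(74)
        fams = np.repeat([1, 2, 3], 30)
        y = rng.normal(size=90) + fams
        ids, codes = family_codes(fams)
        yc = center_within_family(y, codes, 3)
        for f in range(3):
            assert yc[codes == f].mean() == pytest.approx(0.0, abs=1e-12)


class TestStepwise:
    def test_null_phenotype_rarely_selects(self, rils, gmap):
        """With pure-noise phenotypes the familywise selection rate stays
        near alpha (full calibration is exercised at larger scale in the
        acceptance suite)."""
        rng = np.random.default_rng(75)
        y0 = rng.normal(size=rils.n_rils)
        thr = nq.jl_permutation_threshold(rils.genotypes, y0, rils.families,
                                          n_perm=300, alpha=0.05, seed=76)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            y = rng.normal(size=rils.n_rils)
            m = nq.jl_stepwise(rils.genotypes, y, rils.families, rils.markers,
                               thr)
            hits += m.n_qtl > 0
        # Binomial(40, .05): P(hits > 7) < 1e-3
        assert hits <= 7

    def test_single_huge_qtl_found_at_marker(self, rils, gmap):
        rng = np.random.default_rng(77)
        j = 25  # a marker on chromosome 1
        g = rils.genotypes[:, j]
        y = 5.0 * g + rng.normal(0, 1.0, rils.n_rils)
        thr = nq.jl_permutation_threshold(rils.genotypes, y, rils.families,
                                          n_perm=150, alpha=0.05, seed=78)
        m = nq.jl_stepwise(rils.genotypes, y, rils.families, rils.markers, thr)
        assert any(abs(int(k) - j) <= 1 for k in m.marker_idx)

    def test_duplicate_marker_never_coselected(self, rils, blups_y):
        _, _, y = blups_y
        G = np.concatenate([rils.genotypes, rils.genotypes[:, [25]]], axis=1)
        rng = np.random.default_rng(79)
        ysig = 4.0 * rils.genotypes[:, 25] + rng.normal(0, 1, rils.n_rils)
        thr = nq.jl_permutation_threshold(G, ysig, rils.families, n_perm=150,
                                          alpha=0.05, seed=80)
        markers2 = pd.concat([rils.markers,
                              rils.markers.iloc[[25]].assign(id="dup25")],
                             ignore_index=True)
        m = nq.jl_stepwise(G, ysig, rils.families, markers2, thr)
        picked = set(m.marker_idx.tolist())
        assert not {25, rils.genotypes.shape[1]} <= picked

    def test_r2_non_decreasing_with_model_size(self, rils, blups_y, jl_model):
        _, _, y = blups_y
        if jl_model.n_qtl < 2:
            pytest.skip("model too small for nesting check")
        sub = nq.fit_jl_model(rils.genotypes, y, rils.families, rils.markers,
                              jl_model.marker_idx[:1])
        assert jl_model.r2 >= sub.r2 - 1e-9

    def test_effects_near_truth_single_qtl(self, gmap):
        """Per-family effect estimates are unbiased at a simulated QTL."""
        panel = nq.simulate_founders(gmap, 6, 50, seed=81)
        rils = nq.simulate_nam(gmap, panel, 150, n_selfing=5, seed=82)
        rng = np.random.default_rng(83)
        true_eff = np.array([2.0, -1.0, 0.0, 1.5, 3.0])  # per family
        j = 20
        fam = rils.families
        y = np.array([true_eff[f - 1] * rils.genotypes[i, j]
                      for i, f in enumerate(fam)]) + rng.normal(0, 0.5, rils.n_rils)
        m = nq.fit_jl_model(rils.genotypes, y, fam, rils.markers, [j])
        assert np.allclose(m.effects[0], true_eff, atol=0.35)

    def test_nonsegregating_family_effect_zero(self, rils, blups_y):
        _, _, y = blups_y
        G = rils.genotypes.copy()
        rows = rils.families == 3
        G[rows, 10] = 0.0  # marker 10 non-informative in family 3
        m = nq.fit_jl_model(G, y, rils.families, rils.markers, [10])
        f3 = list(m.family_ids).index(3)
        assert m.effects[0, f3] == pytest.approx(0.0, abs=1e-9)


class TestRefit:
    def test_idempotent_at_current_size(self, rils, blups_y, jl_model):
        _, _, y = blups_y
        if jl_model.n_qtl == 0:
            pytest.skip("empty model")
        re = nq.jl_refit_fixed_size(rils.genotypes, y, rils.families,
                                    rils.markers, jl_model, jl_model.n_qtl)
        assert np.allclose(re.effects, jl_model.effects, atol=1e-8)

    def test_truncates_to_k(self, rils, blups_y, jl_model):
        _, _, y = blups_y
        if jl_model.n_qtl < 2:
            pytest.skip("model too small")
        re = nq.jl_refit_fixed_size(rils.genotypes, y, rils.families,
                                    rils.markers, jl_model, 1)
        assert re.n_qtl == 1
        assert re.marker_idx[0] == jl_model.marker_idx[np.argmin(jl_model.pvalues)]

    def test_invalid_k(self, rils, blups_y, jl_model):
        _, _, y = blups_y
        with pytest.raises(ValueError):
            nq.jl_refit_fixed_size(rils.genotypes, y, rils.families,
                                   rils.markers, jl_model, 0)

    def test_orthogonal_qtl_keep_single_fit(self, gmap):
        panel = nq.simulate_founders(gmap, 6, 50, seed=84)
        rils = nq.simulate_nam(gmap, panel, 120, n_selfing=5, seed=85)
        rng = np.random.default_rng(86)
        j1, j2 = 5, 150  # different chromosomes: nearly orthogonal
        y = (3.0 * rils.genotypes[:, j1] - 2.0 * rils.genotypes[:, j2]
             + rng.normal(0, 0.5, rils.n_rils))
        both = nq.fit_jl_model(rils.genotypes, y, rils.families, rils.markers,
                               [j1, j2])
        single = nq.fit_jl_model(rils.genotypes, y, rils.families,
                                 rils.markers, [j1])
        assert np.allclose(both.effects[0], single.effects[0], atol=0.4)
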