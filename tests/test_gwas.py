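"""Residual construction, GWAS thresholds, subsampled forward regression
and RMIP behaviour."""

import numpy as np
import pandas as pd
import pytest

import namqtl as nq
from namqtl.gwas import subsample_forward_gwas
from namqtl.jointlinkage import JLThreshold


def _snps_frame(n, chrom=1):
    return pd.DataFrame({"chrom": chrom, "id": [f"s{j}" for j in range(n)],
                         "cm": np.linspace(0, 100, n),
                         "bp": np.linspace(1, 1e6, n).astype(int)})


class TestChromosomeResiduals:
    def test_zero_qtl_model_gives_centered_blups(self, rils, blups_y):
        _, _, y = blups_y
        empty = nq.fit_jl_model(rils.genotypes, y, rils.families,
                                rils.markers, [])
        r = nq.chromosome_residuals(rils.genotypes, y, rils.families, empty, 1)
        assert np.allclose(r, y - y.mean())

    def test_focal_chromosome_qtl_excluded(self, rils, blups_y, jl_model):
        _, _, y = blups_y
        chroms = set(jl_model.markers["chrom"])
        if not chroms:
            pytest.skip("no QTL found")
        c = next(iter(chroms))
        r_with = nq.chromosome_residuals(rils.genotypes, y, rils.families,
                                         jl_model, c)
        # removing real non-focal QTL shrinks variance vs raw centered blups
        assert r_with.var() <= np.var(y - y.mean()) + 1e-9

    def test_unknown_chromosome_ok_means_no_exclusion(self, rils, blups_y,
                                                      jl_model):
        _, _, y = blups_y
        r99 = nq.chromosome_residuals(rils.genotypes, y, rils.families,
                                      jl_model, 99)
        # chromosome 99 holds no QTL, so the full non-family model is used
        assert len(r99) == rils.n_rils


class TestGwasThreshold:
    def test_null_calibration_and_determinism(self, dosages, rils):
        rng = np.random.default_rng(90)
        resid = rng.normal(size=rils.n_rils)
        a = nq.gwas_permutation_threshold(dosages.dosages, resid,
                                          rils.families, n_perm=150, seed=91)
        b = nq.gwas_permutation_threshold(dosages.dosages, resid,
                                          rils.families, n_perm=150, seed=91)
        assert a.p_enter == b.p_enter
        assert 0 < a.p_enter < 0.05

    def test_smaller_alpha_smaller_threshold(self, dosages, rils):
        rng = np.random.default_rng(92)
        resid = rng.normal(size=rils.n_rils)
        hi = nq.gwas_permutation_threshold(dosages.dosages, resid,
                                           rils.families, n_perm=150,
                                           alpha=0.5, seed=93)
        lo = nq.gwas_permutation_threshold(dosages.dosages, resid,
                                           rils.families, n_perm=150,
                                           alpha=0.01, seed=93)
        assert lo.p_enter <= hi.p_enter


class TestSubsampleForward:
    def test_rmip_is_selection_fraction(self, dosages, rils):
        """A strong causal SNP is selected in essentially every subsample and
        its median effect lands near the simulated value."""
        rng = np.random.default_rng(94)
        j = int(np.argmax(dosages.dosages.var(axis=0)))
        x = dosages.dosages[:, j]
        resid = 2.0 * x + rng.normal(0, 1.0, rils.n_rils)
        thr = nq.gwas_permutation_threshold(dosages.dosages, resid,
                                            rils.families, n_perm=150, seed=95)
        out = nq.subsample_forward_gwas(dosages.dosages, resid, rils.families,
                                        thr, snps=dosages.snps, n_sub=40,
                                        seed=96)
        row = out[out["snp"] == dosages.snps["id"].iat[j]]
        assert len(row) == 1
        assert row["rmip"].iat[0] >= 0.95
        assert row["median_effect"].iat[0] == pytest.approx(2.0, rel=0.15)
        assert ((out["rmip"] * out["n_subsamples"]) % 1 < 1e-9).all()

    def test_rmip_min_filter(self, dosages, rils):
        rng = np.random.default_rng(97)
        resid = rng.normal(size=rils.n_rils)
        thr = JLThreshold(0.05, 0.5, 0.5, 100)  # permissive: many weak picks
        out = nq.subsample_forward_gwas(dosages.dosages[:, :50], resid,
                                        rils.families, thr,
                                        snps=dosages.snps.iloc[:50],
                                        n_sub=30, seed=98, rmip_min=0.05)
        assert (out["rmip"] >= 0.05).all()

    def test_empty_candidate_set_warns(self, rils):
        rng = np.random.default_rng(99)
        resid = rng.normal(size=rils.n_rils)
        thr = JLThreshold(0.05, 1e-4, 1e-4, 100)
        with pytest.warns(UserWarning, match="empty"):
            out = nq.subsample_forward_gwas(np.empty((rils.n_rils, 0)), resid,
                                            rils.families, thr,
                                            snps=_snps_frame(0), n_sub=5,
                                            seed=1)
        assert len(out) == 0

    def test_deterministic(self, dosages, rils):
        rng = np.random.default_rng(100)
        resid = rng.normal(size=rils.n_rils)
        thr = JLThreshold(0.05, 1e-3, 1e-3, 100)
        kw = dict(snps=dosages.snps, n_sub=10, seed=101)
        a = nq.subsample_forward_gwas(dosages.dosages, resid, rils.families,
                                      thr, **kw)
        b = nq.subsample_forward_gwas(dosages.dosages, resid, rils.families,
                                      thr, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_arguments(self, dosages, rils):
        thr = JLThreshold(0.05, 1e-3, 1e-3, 100)
        with pytest.raises(ValueError):
            nq.subsample_forward_gwas(dosages.dosages, np.zeros(rils.n_rils),
                                      rils.families, thr, frac=1.5)
        with pytest.raises(ValueError):
            nq.subsample_forward_gwas(dosages.dosages, np.zeros(rils.n_rils),
                                      rils.families, thr, n_sub=0)


class TestRmipProperties:
    def test_rmip_monotone_in_effect_size(self, dosages, rils):
        """Causal-SNP RMIP increases with simulated effect size."""
        rng = np.random.default_rng(102)
        j = int(np.argmax(dosages.dosages.var(axis=0)))
        x = dosages.dosages[:, j]
        chrom_j = dosages.snps["chrom"].iat[j]
        cm_j = dosages.snps["cm"].iat[j]
        near = ((dosages.snps["chrom"] == chrom_j)
                & (dosages.snps["cm"].sub(cm_j).abs() <= 5.0)).to_numpy()
        local_rmip = []
        for beta in (0.0, 0.4, 0.8, 1.6):
            resid = beta * x + rng.normal(0, 1.0, rils.n_rils)
            thr = nq.gwas_permutation_threshold(
                dosages.dosages, resid, rils.families, n_perm=120,
                seed=103)
            out = nq.subsample_forward_gwas(
                dosages.dosages, resid, rils.families, thr,
                snps=dosages.snps, n_sub=30, seed=104, rmip_min=0.0)
            sel = out["snp"].isin(dosages.snps["id"][near])
            # RMIP mass may split over SNPs in tight LD with the causal one,
            # so score the mass within 5 cM of the causal position
            local_rmip.append(float(out.loc[sel, "rmip"].sum()))
        from scipy import stats as st
        rho = st.spearmanr([0.0, 0.4, 0.8, 1.6], local_rmip).statistic
        assert rho > 0
        assert local_rmip[-1] >= 0.9
        assert local_rmip[-1] > local_rmip[0]

    def test_correlated_snps_split_rmip(self, rils):
        """Two identical causal candidates share the RMIP mass that either
        would receive alone (linked 'synthetic' effect behaviour)."""
        rng = np.random.default_rng(105)
        x = rng.binomial(1, 0.5, rils.n_rils).astype(float)
        noise = rng.normal(0, 1.0, rils.n_rils)
        resid = 1.2 * x + noise
        thr = JLThreshold(0.05, 1e-4, 1e-4, 100)
        solo = nq.subsample_forward_gwas(
            x[:, None], resid, rils.families, thr, snps=_snps_frame(1),
            n_sub=40, seed=106, rmip_min=0.0)
        # jitter breaks exact collinearity so both stay candidates
        x2 = np.column_stack([x, np.clip(x + rng.normal(0, 1e-3, len(x)), 0, 1)])
        duo = nq.subsample_forward_gwas(
            x2, resid, rils.families, thr, snps=_snps_frame(2), n_sub=40,
            seed=106, rmip_min=0.0)
        assert duo["rmip"].sum() == pytest.approx(solo["rmip"].sum(), abs=0.15)
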