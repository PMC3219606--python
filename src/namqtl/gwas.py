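"""Subsampled forward-regression GWAS with resample model inclusion
probabilities (RMIP).

Each chromosome is analysed separately.  The phenotype for a chromosome is
the vector of residuals from a joint-linkage model that excludes both the
family term and every QTL on that chromosome, so projected-SNP associations
are tested against variation not already explained elsewhere in the genome.
In each of ``n_sub`` subsamples, 80% of the RILs of every family are drawn
without replacement and single-df SNP dosage terms are forward-selected in
the presence of the family term until no candidate beats a
permutation-derived threshold.  A SNP's RMIP is the fraction of subsamples
that selected it; its effect is summarised as the median fitted coefficient
over those subsamples, oriented to the alternate (non-reference) allele.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .jointlinkage import (JLModel, JLThreshold, _TOL, _family_rows,
                           _marker_block_raw, center_within_family,
                           family_codes)
from .projection import ProjectedDosage


# ---------------------------------------------------------------------------
# Chromosome residuals
# ---------------------------------------------------------------------------

def chromosome_residuals(genotypes: np.ndarray, blups, families,
                         model: JLModel, chrom) -> np.ndarray:
    """Residuals from the joint-linkage model refit without the family term
    and without the QTL on the focal chromosome.

    With a zero-QTL model this reduces to mean-centered BLUPs.
    """
    y = np.asarray(blups, float)
    ids, codes = family_codes(families)
    n, n_fam = len(y), len(ids)
    rows_by_fam = _family_rows(codes, n_fam)
    keep = [int(j) for j, c in zip(model.marker_idx, model.markers["chrom"])
            if c != chrom]
    X = [np.ones((n, 1))]
    X += [_marker_block_raw(genotypes, j, rows_by_fam, n) for j in keep]
    X = np.concatenate(X, axis=1)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


# ---------------------------------------------------------------------------
# Permutation threshold for single-df SNP terms
# ---------------------------------------------------------------------------

def _snp_scan_min_p(Xc: np.ndarray, y_c: np.ndarray, den: np.ndarray,
                    n: int, n_fam: int) -> float:
    num = Xc.T @ y_c
    ok = den > _TOL
    sse0 = float(y_c @ y_c)
    dfden = n - n_fam - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ssr = np.where(ok, num ** 2 / np.where(ok, den, 1.0), 0.0)
        fstat = ssr * dfden / np.maximum(sse0 - ssr, 1e-300)
    if not ok.any():
        return 1.0
    return float(stats.f.sf(fstat[ok], 1, dfden).min())


def gwas_permutation_threshold(dosages: np.ndarray, residuals, families,
                               n_perm: int = 1000, alpha: float = 0.05,
                               seed: int | None = None) -> JLThreshold:
    """Entry threshold for forward SNP selection: alpha-quantile of null
    minimum p-values over within-family permutations of the residuals."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(residuals, float)
    ids, codes = family_codes(families)
    n_fam = len(ids)
    n = len(y)
    rng = np.random.default_rng(seed)
    Xc = center_within_family(dosages, codes, n_fam)
    den = np.einsum("ij,ij->j", Xc, Xc)
    rows_by_fam = _family_rows(codes, n_fam)
    minima = np.empty(n_perm)
    for b in range(n_perm):
        yp = y.copy()
        for rows in rows_by_fam:
            yp[rows] = yp[rows[rng.permutation(len(rows))]]
        y_c = center_within_family(yp, codes, n_fam)
        minima[b] = _snp_scan_min_p(Xc, y_c, den, n, n_fam)
    thr = float(np.quantile(minima, alpha, method="inverted_cdf"))
    return JLThreshold(alpha, thr, thr, n_perm, minima)


# ---------------------------------------------------------------------------
# Subsampled forward regression
# ---------------------------------------------------------------------------

def _forward_select(X: np.ndarray, y: np.ndarray, codes: np.ndarray,
                    n_fam: int, p_enter: float, max_terms: int) -> list[int]:
    """Vectorised forward selection of single-df columns with the family
    term in the model; returns selected column indices in entry order."""
    n, m = X.shape
    Xr = center_within_family(X, codes, n_fam)
    yr = center_within_family(y, codes, n_fam)
    den0 = np.einsum("ij,ij->j", Xr, Xr)
    den = den0.copy()
    sse = float(yr @ yr)
    sel: list[int] = []
    active = den > _TOL * np.maximum(den0.max(initial=1.0), 1.0)
    while len(sel) < max_terms:
        dfden = n - n_fam - len(sel) - 1
        if dfden <= 0 or sse <= 0 or not active.any():
            break
        num = Xr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            ssr = np.where(active, num ** 2 / np.where(active, den, 1.0), 0.0)
            fstat = ssr * dfden / np.maximum(sse - ssr, 1e-300)
            pvals = np.where(active, stats.f.sf(fstat, 1, dfden), 1.0)
        j = int(np.argmin(pvals))  # ties: first index = genome order
        if pvals[j] >= p_enter:
            break
        sel.append(j)
        q = Xr[:, j] / np.sqrt(den[j])
        proj = q @ Xr
        Xr -= np.outer(q, proj)
        den -= proj ** 2
        yr -= q * (q @ yr)
        sse = float(yr @ yr)
        active = (den > _TOL * np.maximum(den0.max(initial=1.0), 1.0))
        active[sel] = False
    return sel


def subsample_forward_gwas(dosages: ProjectedDosage | np.ndarray, residuals,
                           families, threshold: JLThreshold,
                           snps: pd.DataFrame | None = None,
                           n_sub: int = 100, frac: float = 0.8,
                           seed: int | None = None, rmip_min: float = 0.05,
                           family_frequency: np.ndarray | None = None,
                           max_terms: int | None = None) -> pd.DataFrame:
    """Forward-select SNPs in repeated family-stratified subsamples and
    aggregate to RMIP values and median effects.

    Returns one row per SNP with ``rmip >= rmip_min``: snp, chrom, cm, bp,
    rmip, median_effect, family_frequency, n_subsamples, plus the full list
    of per-subsample effects in the ``effects`` column.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    if isinstance(dosages, ProjectedDosage):
        snps = dosages.snps if snps is None else snps
        X = dosages.dosages
    else:
        X = np.asarray(dosages, float)
    if X.shape[1] == 0:
        warnings.warn("empty candidate SNP set")
        return _empty_assoc_frame()

    y = np.asarray(residuals, float)
    ids, codes = family_codes(families)
    n_fam = len(ids)
    rows_by_fam = _family_rows(codes, n_fam)
    rng = np.random.default_rng(seed)
    if max_terms is None:
        max_terms = max(1, min(X.shape[0] // 10, 60))

    counts = np.zeros(X.shape[1], dtype=int)
    effects: dict[int, list] = {}
    for s in range(n_sub):
        idx = np.concatenate([
            rows[rng.permutation(len(rows))[:max(2, int(len(rows) * frac))]]
            for rows in rows_by_fam
        ])
        Xs, ys, cs = X[idx], y[idx], codes[idx]
        sel = _forward_select(Xs, ys, cs, n_fam, threshold.p_enter, max_terms)
        if not sel:
            continue
        # joint refit on this subsample: family dummies + selected SNP columns
        F = np.zeros((len(idx), n_fam))
        F[np.arange(len(idx)), cs] = 1.0
        D = np.concatenate([F, Xs[:, sel]], axis=1)
        coef, _, _, _ = np.linalg.lstsq(D, ys, rcond=None)
        for k, j in enumerate(sel):
            counts[j] += 1
            effects.setdefault(j, []).append(float(coef[n_fam + k]))

    rmip = counts / n_sub
    keep = np.where(rmip >= rmip_min)[0]
    if snps is None:
        snps = pd.DataFrame({"chrom": 0, "id": [f"snp{j}" for j in range(X.shape[1])],
                             "cm": np.nan, "bp": np.nan})
    if family_frequency is None:
        family_frequency = np.full(X.shape[1], np.nan)
    rows = []
    for j in keep:
        e = effects.get(j, [])
        rows.append({
            "snp": snps["id"].iat[j], "chrom": snps["chrom"].iat[j],
            "cm": snps["cm"].iat[j], "bp": snps["bp"].iat[j],
            "rmip": rmip[j], "median_effect": float(np.median(e)) if e else np.nan,
            "family_frequency": family_frequency[j], "n_subsamples": n_sub,
            "effects": e,
        })
    out = pd.DataFrame(rows, columns=["snp", "chrom", "cm", "bp", "rmip",
                                      "median_effect", "family_frequency",
                                      "n_subsamples", "effects"])
    return out.sort_values(["chrom", "cm"], ignore_index=True) if len(out) else out


def _empty_assoc_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["snp", "chrom", "cm", "bp", "rmip",
                                 "median_effect", "family_frequency",
                                 "n_subsamples", "effects"])


def run_gwas(dosages: ProjectedDosage, genotypes: np.ndarray, blups, families,
             model: JLModel, panel=None, n_perm: int = 1000,
             alpha: float = 0.05, n_sub: int = 100, frac: float = 0.8,
             rmip_min: float = 0.05, seed: int | None = None) -> pd.DataFrame:
    """Chromosome-by-chromosome GWAS: residuals, threshold, subsampled
    forward regression; results concatenated across chromosomes."""
    rng = np.random.default_rng(seed)
    pieces = []
    fam_freq_all = panel.family_frequency() if panel is not None else None
    for chrom in dosages.snps["chrom"].unique():
        mask = (dosages.snps["chrom"] == chrom).to_numpy()
        Xc = dosages.dosages[:, mask]
        snps_c = dosages.snps[mask].reset_index(drop=True)
        resid = chromosome_residuals(genotypes, blups, families, model, chrom)
        thr = gwas_permutation_threshold(Xc, resid, families, n_perm, alpha,
                                         seed=int(rng.integers(2 ** 31)))
        ff = fam_freq_all[mask] if fam_freq_all is not None else None
        pieces.append(subsample_forward_gwas(
            Xc, resid, families, thr, snps=snps_c, n_sub=n_sub, frac=frac,
            seed=int(rng.integers(2 ** 31)), rmip_min=rmip_min,
            family_frequency=ff))
    pieces = [p for p in pieces if len(p)]
    return pd.concat(pieces, ignore_index=True) if pieces else _empty_assoc_frame()


def write_associations_tsv(assocs: pd.DataFrame, path) -> None:
    assocs.drop(columns=["effects"], errors="ignore").to_csv(path, sep="\t", index=False)
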