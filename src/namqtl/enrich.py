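"""Candidate-gene enrichment near top GWAS SNPs.

For each trait only the ten SNPs with the highest RMIP values are used, on
the assumption that these are most tightly linked to causal variants.  The
observed statistic is the number of those SNPs falling within 0.5, 1 and 2
cM of any candidate gene; the null distribution comes from 1000 random gene
sets of the same size drawn from the annotation (random *genes*, not random
positions — genes cluster along the genome, and random positions would be a
much weaker null).  Empirical p-values use the add-one correction
p = (1 + #null >= observed) / (1 + n_null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import select_top_snps


def top_snp_distances(genes: pd.DataFrame, assocs: pd.DataFrame,
                      n_top: int = 10) -> pd.Series:
    """Genetic distance (cM) from each gene to the nearest top-RMIP SNP on
    the same chromosome; infinity when the chromosome has no top SNP."""
    top = select_top_snps(assocs, min(n_top, len(assocs))) if len(assocs) else assocs
    genes = genes.reset_index(drop=True)
    out = np.full(len(genes), np.inf)
    for chrom, grp in genes.groupby("chrom"):
        snps = top[top["chrom"] == chrom] if len(top) else top
        if len(snps) == 0:
            continue
        d = np.abs(grp["cm"].to_numpy()[:, None] - snps["cm"].to_numpy()[None, :])
        out[grp.index.to_numpy()] = d.min(axis=1)
    return pd.Series(out, index=genes["gene"].to_numpy(), name="distance_cm")


def _count_snps_near(cands: pd.DataFrame, top: pd.DataFrame, radius: float) -> int:
    """Number of top SNPs within ``radius`` cM of any candidate gene."""
    n = 0
    for _, snp in top.iterrows():
        near = cands[cands["chrom"] == snp["chrom"]]
        if len(near) and (np.abs(near["cm"].to_numpy() - snp["cm"]) <= radius).any():
            n += 1
    return n


def _count_genes_near(cands: pd.DataFrame, top: pd.DataFrame, radius: float) -> int:
    n = 0
    for _, g in cands.iterrows():
        near = top[top["chrom"] == g["chrom"]]
        if len(near) and (np.abs(near["cm"].to_numpy() - g["cm"]) <= radius).any():
            n += 1
    return n


@dataclass
class EnrichmentResult:
    candidate_set: str
    radii: tuple
    observed: dict                 # radius -> count
    pvalues: dict                  # radius -> empirical p
    n_null: int
    null_counts: dict = field(repr=False, default_factory=dict)


def enrichment_test(candidates, annotation: pd.DataFrame, assocs: pd.DataFrame,
                    n_null: int = 1000, radii=(0.5, 1.0, 2.0),
                    seed: int | None = None, n_top: int = 10,
                    count: str = "snps", exclude_candidates_from_null: bool = False,
                    label: str = "candidates") -> EnrichmentResult:
    """Permutation enrichment of candidate genes near top GWAS SNPs.

    ``candidates`` is a list of gene ids present in ``annotation`` (columns
    gene, chrom, cm).  ``count='snps'`` counts top SNPs near any candidate
    (default); ``count='genes'`` counts candidate genes near any top SNP.
    """
    candidates = list(candidates)
    known = set(annotation["gene"])
    missing = [c for c in candidates if c not in known]
    if missing:
        raise ValueError(f"candidates absent from annotation: {missing}")
    counter = {"snps": _count_snps_near, "genes": _count_genes_near}[count]
    rng = np.random.default_rng(seed)
    top = select_top_snps(assocs, min(n_top, len(assocs))) if len(assocs) else assocs

    cand_df = annotation[annotation["gene"].isin(candidates)]
    observed = {r: counter(cand_df, top, r) for r in radii}

    pool = annotation if not exclude_candidates_from_null else \
        annotation[~annotation["gene"].isin(candidates)]
    if len(pool) < len(candidates):
        raise ValueError("annotation too small for null gene sets")
    null_counts = {r: np.empty(n_null, dtype=int) for r in radii}
    pool_idx = pool.index.to_numpy()
    for b in range(n_null):
        pick = annotation.loc[rng.choice(pool_idx, size=len(candidates),
                                         replace=False)]
        for r in radii:
            null_counts[r][b] = counter(pick, top, r)
    pvalues = {r: float((1 + (null_counts[r] >= observed[r]).sum()) / (1 + n_null))
               for r in radii}
    return EnrichmentResult(label, tuple(radii), observed, pvalues, n_null,
                            null_counts)


def rmip_sum_near_gene(assocs: pd.DataFrame, gene: pd.Series | dict,
                       radius: float = 1.0, percent: bool = True) -> float:
    """Sum of RMIP values of SNPs within ``radius`` cM of a gene, times 100
    by default (percent-like; can exceed 100 where SNPs cluster)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    sub = assocs[assocs["chrom"] == gene["chrom"]]
    if len(sub) == 0:
        return 0.0
    near = np.abs(sub["cm"].to_numpy(float) - float(gene["cm"])) <= radius
    total = float(sub["rmip"].to_numpy(float)[near].sum())
    return total * 100.0 if percent else total
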