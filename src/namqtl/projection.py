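"""Marker imputation and founder-SNP projection.

RIL marker genotypes are dosages of alternate-founder ancestry (0, 0.5, 1,
or missing).  Missing marker calls are imputed from the flanking informative
markers: agreeing flanks propagate their value, disagreeing flanks give the
expected dosage by linear interpolation on genetic (cM) distance, and
chromosome-end gaps copy the single flank.

High-density founder SNPs are then *projected* into every RIL through its
marker-interval ancestry: within a non-recombinant interval the RIL simply
inherits the interval parent's SNP allele, while within a recombinant
interval the SNP receives a fractional dosage by linear interpolation on
physical (bp) position between the two flanking-marker ancestries.
Heterozygous flanks contribute expected dosage 0.5.  A SNP that does not
segregate in a family (the alternate parent carries the reference allele)
projects to dosage 0 for the whole family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FounderPanel, GeneticMap, RILPopulation


@dataclass
class ProjectedDosage:
    """RIL x SNP matrix of alternate-allele dosages in [0, 1]."""
    lines: pd.DataFrame      # line, family (row order of ``dosages``)
    snps: pd.DataFrame       # chrom, id, cm, bp (column order of ``dosages``)
    dosages: np.ndarray

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.snps["id"])
        df.insert(0, "family", self.lines["family"].to_numpy())
        df.insert(0, "line", self.lines["line"].to_numpy())
        return df


def impute_markers(rils: RILPopulation, gmap: GeneticMap) -> RILPopulation:
    """Fill missing marker genotypes by flanking interpolation on cM.

    Returns a new population with the same mosaics and a fully observed
    genotype matrix.  A RIL missing every marker on some chromosome cannot
    be imputed and raises an error naming the offending lines.
    """
    geno = rils.genotypes.astype(float).copy()
    if not np.isnan(geno).any():
        return RILPopulation(rils.lines, rils.markers, geno, rils.mosaics,
                             rils.family_parents)
    bad_lines: list = []
    for chrom, grp in rils.markers.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        cm = grp["cm"].to_numpy()
        block = geno[:, cols]
        miss = np.isnan(block)
        for i in np.where(miss.any(axis=1))[0]:
            obs = ~miss[i]
            if not obs.any():
                bad_lines.append((rils.lines["line"].iat[i], chrom))
                continue
            block[i, miss[i]] = np.interp(cm[miss[i]], cm[obs], block[i, obs])
        geno[:, cols] = block
    if bad_lines:
        raise ValueError(f"entire chromosome missing for lines: {bad_lines}")
    return RILPopulation(rils.lines, rils.markers, geno, rils.mosaics,
                         rils.family_parents)


def project_snps(rils: RILPopulation, panel: FounderPanel,
                 gmap: GeneticMap) -> ProjectedDosage:
    """Project founder SNPs into RILs through marker-interval ancestry.

    Within each marker interval the RIL's alternate-ancestry dosage is
    interpolated linearly on bp between the flanking marker genotypes
    (identical flanks reduce to the parental assignment; SNPs outside the
    terminal markers take the terminal marker's value), then multiplied by
    the family's alternate-parent allele at the SNP.
    """
    missing_chroms = set(panel.snps["chrom"]) - set(gmap.chromosomes.index)
    if missing_chroms:
        raise ValueError(f"SNPs on chromosomes absent from the map: {sorted(missing_chroms)}")
    geno = rils.genotypes
    if np.isnan(geno.astype(float)).any():
        geno = impute_markers(rils, gmap).genotypes

    n_rils, n_snps = rils.n_rils, len(panel.snps)
    ancestry = np.empty((n_rils, n_snps))
    for chrom, sgrp in panel.snps.groupby("chrom", sort=False):
        scols = sgrp.index.to_numpy()
        snp_bp = sgrp["bp"].to_numpy(float)
        mgrp = rils.markers[rils.markers["chrom"] == chrom]
        if len(mgrp) == 0:
            raise ValueError(f"no markers on chromosome {chrom}")
        mcols = mgrp.index.to_numpy()
        marker_bp = mgrp["bp"].to_numpy(float)
        for i in range(n_rils):
            ancestry[i, scols] = np.interp(snp_bp, marker_bp, geno[i, mcols])

    fam = rils.families
    alt_of = {f: alt for f, (_, alt) in rils.family_parents.items()}
    dosages = np.empty_like(ancestry)
    for f in np.unique(fam):
        rows = fam == f
        dosages[rows] = ancestry[rows] * panel.alleles[:, alt_of[f]][None, :]
    return ProjectedDosage(rils.lines.copy(), panel.snps.copy(), dosages)


def project_snps_from_mosaics(rils: RILPopulation, panel: FounderPanel) -> ProjectedDosage:
    """Oracle projection using the simulator's exact founder mosaics.

    The true alternate-ancestry dosage at each SNP position is read off the
    stored breakpoint mosaics instead of being interpolated from markers.
    Intended for testing: marker projection must agree with this wherever
    the enclosing marker interval is non-recombinant.
    """
    n_snps = len(panel.snps)
    dos = np.empty((rils.n_rils, n_snps))
    fam = rils.families
    alt_of = {f: alt for f, (_, alt) in rils.family_parents.items()}
    for j in range(n_snps):
        chrom = panel.snps["chrom"].iat[j]
        cm = panel.snps["cm"].iat[j]
        anc = rils.founder_dosage_at(chrom, cm)
        dos[:, j] = anc * panel.alleles[j, [alt_of[f] for f in fam]]
    return ProjectedDosage(rils.lines.copy(), panel.snps.copy(), dos)


def write_dosages_tsv(pd_: ProjectedDosage, path) -> None:
    pd_.frame().to_csv(path, sep="\t", index=False, float_format="%.4f")
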