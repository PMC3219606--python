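"""Readers for the plain-text interchange formats the pipeline writes.

Stage subcommands run against a directory of TSV/JSON outputs, so every
writer in the package has a matching reader here.  Founder mosaics are a
simulator-internal oracle and are not round-tripped; populations loaded
from disk carry ``mosaics=None``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import FounderPanel, GeneticMap, RILPopulation


def read_map_tsv(path) -> GeneticMap:
    lengths = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#chromosome\t"):
                break
            _, chrom, lcm, lbp = line.rstrip("\n").split("\t")
            lengths[int(chrom)] = (float(lcm), int(lbp))
    markers = pd.read_csv(path, sep="\t", comment="#")
    if lengths:
        chroms = pd.DataFrame(
            {"length_cm": [v[0] for v in lengths.values()],
             "length_bp": [v[1] for v in lengths.values()]},
            index=pd.Index(lengths.keys(), name="chrom"))
    else:  # fall back to marker extents
        chroms = markers.groupby("chrom").agg(length_cm=("cm", "max"),
                                              length_bp=("bp", "max"))
        chroms["length_cm"] += 1e-9
    return GeneticMap(chroms, markers.sort_values(["chrom", "cm"],
                                                  ignore_index=True))


def read_founders_tsv(path) -> FounderPanel:
    df = pd.read_csv(path, sep="\t")
    parents = [c for c in df.columns if c not in ("chrom", "id", "cm", "bp")]
    snps = df[["chrom", "id", "cm", "bp"]].reset_index(drop=True)
    alleles = df[parents].to_numpy(dtype=np.int8)
    return FounderPanel(parents, snps, alleles)


def read_genotypes_tsv(path, gmap: GeneticMap) -> RILPopulation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    lines = pd.DataFrame({"line": df["line"],
                          "family": df["family"].astype(int)})
    marker_ids = list(gmap.markers["id"])
    geno = (df[marker_ids].replace({"H": "0.5", "NA": ""})
            .apply(pd.to_numeric, errors="coerce").to_numpy(float))
    fams = sorted(lines["family"].unique())
    return RILPopulation(lines, gmap.markers.copy(), geno, None,
                         {f: (0, f) for f in fams})


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_blups_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_dosages_tsv(path, snps: pd.DataFrame):
    from .projection import ProjectedDosage

    df = pd.read_csv(path, sep="\t")
    lines = df[["line", "family"]].copy()
    dos = df[list(snps["id"])].to_numpy(float)
    return ProjectedDosage(lines, snps.reset_index(drop=True), dos)


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
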