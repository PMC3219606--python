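"""Synthetic nested association mapping (NAM) populations.

A NAM design crosses one common reference parent to a set of diverse founders
and derives a recombinant inbred line (RIL) family from each cross by repeated
self-fertilisation with single-seed descent.  This module generates every
input the analysis stack consumes: a genetic map with a monotone cM<->bp
relation, a founder SNP panel coded relative to the common parent, RIL marker
genotypes together with their underlying founder mosaics (retained as an
internal oracle), multi-QTL trait architectures with configurable pleiotropy,
and balanced multi-environment phenotypes with a target line-mean
heritability.

Meiosis uses a Haldane model: crossover counts are Poisson with mean
(length in cM)/100 and breakpoints are placed uniformly, with no
interference.  Residual heterozygosity after ``n`` selfing generations from
the F1 is therefore (1/2)**n in expectation, which puts the default of five
generations at ~97% homozygosity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

# Genotype codes: 0 = common-parent homozygote, 1 = alternate homozygote,
# 0.5 = heterozygote, NaN = missing.
COMMON, ALT, HET = 0.0, 1.0, 0.5


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker positions on a per-chromosome genetic (cM) and physical (bp) map.

    Attributes
    ----------
    chromosomes : pd.DataFrame
        Indexed by chromosome id, columns ``length_cm`` and ``length_bp``.
    markers : pd.DataFrame
        Columns ``chrom``, ``id``, ``cm``, ``bp``; sorted by (chrom, cm) with
        strictly increasing positions within each chromosome.
    anchors : dict
        Per chromosome, the (cm, bp) anchor arrays of the monotone
        piecewise-linear cM<->bp interpolation backbone.
    """

    chromosomes: pd.DataFrame
    markers: pd.DataFrame
    anchors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, grp in self.markers.groupby("chrom"):
            cm = grp["cm"].to_numpy()
            bp = grp["bp"].to_numpy()
            if not (np.all(np.diff(cm) > 0) and np.all(np.diff(bp) > 0)):
                raise ValueError(f"marker positions not strictly increasing on chrom {chrom}")
            length_cm = self.chromosomes.loc[chrom, "length_cm"]
            length_bp = self.chromosomes.loc[chrom, "length_bp"]
            if cm[0] < 0 or cm[-1] > length_cm or bp[-1] > length_bp:
                raise ValueError(f"marker positions outside chrom {chrom} bounds")
            if chrom not in self.anchors:
                self.anchors[chrom] = (
                    np.concatenate([[0.0], cm, [length_cm]]),
                    np.concatenate([[0.0], bp.astype(float), [float(length_bp)]]),
                )

    def cm_to_bp(self, chrom, cm):
        acm, abp = self.anchors[chrom]
        return np.interp(cm, acm, abp)

    def bp_to_cm(self, chrom, bp):
        acm, abp = self.anchors[chrom]
        return np.interp(bp, abp, acm)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_markers(self, chrom) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom]


def make_genetic_map(n_chrom: int,
                     cm_lengths: Sequence[float] | float,
                     bp_lengths: Sequence[float] | float,
                     n_markers: Sequence[int] | int,
                     seed: int | None = None) -> GeneticMap:
    """Draw a random genetic map with markers placed uniformly per chromosome.

    ``n_markers`` is per chromosome (scalar or one value per chromosome) and
    must be >= 2 everywhere so each chromosome has a usable marker interval.
    The cM->bp relation is a random monotone piecewise-linear warp, so
    physical and genetic distance are locally but not globally proportional.
    """
    rng = np.random.default_rng(seed)
    cm_lengths = np.broadcast_to(np.asarray(cm_lengths, float), (n_chrom,))
    bp_lengths = np.broadcast_to(np.asarray(bp_lengths, float), (n_chrom,))
    n_markers = np.broadcast_to(np.asarray(n_markers, int), (n_chrom,))
    if np.any(cm_lengths <= 0) or np.any(bp_lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    if np.any(n_markers < 2):
        raise ValueError("need at least 2 markers per chromosome")

    chroms = pd.DataFrame(
        {"length_cm": cm_lengths, "length_bp": bp_lengths.astype(int)},
        index=pd.Index(range(1, n_chrom + 1), name="chrom"),
    )
    anchors = {}
    rows = []
    for c, (lcm, lbp, m) in enumerate(zip(cm_lengths, bp_lengths, n_markers), start=1):
        # random monotone warp on 8 interior anchor points
        acm = np.concatenate([[0.0], np.sort(rng.uniform(0, lcm, 8)), [lcm]])
        abp = np.concatenate([[0.0], np.sort(rng.uniform(0, lbp, 8)), [lbp]])
        anchors[c] = (acm, abp)
        while True:
            cm = np.sort(rng.uniform(0, lcm, m))
            if np.all(np.diff(cm) > 1e-9):
                break
        bp = np.interp(cm, acm, abp).astype(int)
        bp = np.maximum.accumulate(bp) + np.arange(m)  # enforce strict bp order
        for j, (p_cm, p_bp) in enumerate(zip(cm, bp)):
            rows.append((c, f"m{c}_{j:03d}", p_cm, int(p_bp)))
    markers = pd.DataFrame(rows, columns=["chrom", "id", "cm", "bp"])
    return GeneticMap(chroms, markers, anchors)


# ---------------------------------------------------------------------------
# Founder panel
# ---------------------------------------------------------------------------

@dataclass
class FounderPanel:
    """Founder SNP genotypes coded relative to the common parent.

    ``alleles`` is an (n_snps, n_parents) 0/1 matrix; column 0 is the common
    parent and is identically 0 (its allele defines the reference state).
    Family ``f`` (1-based) is the cross common x parents[f]; a SNP segregates
    in family ``f`` iff ``alleles[snp, f] == 1``.
    """

    parents: list
    snps: pd.DataFrame  # chrom, id, cm, bp (sorted by chrom, cm)
    alleles: np.ndarray

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def n_families(self) -> int:
        return self.n_parents - 1

    def family_frequency(self) -> np.ndarray:
        """Number of families in which each SNP segregates."""
        return self.alleles[:, 1:].sum(axis=1)


def simulate_founders(gmap: GeneticMap, n_parents: int, n_snps: int,
                      maf_spectrum: float | Callable | None = None,
                      seed: int | None = None) -> FounderPanel:
    """Draw founder SNP alleles with per-SNP frequencies from ``maf_spectrum``.

    ``maf_spectrum`` may be a fixed frequency in (0,1), a callable
    ``f(rng, size) -> frequencies``, or None for the default Uniform(0.05,
    0.5) spectrum.  Alternate-parent alleles are Bernoulli draws at the SNP's
    frequency; SNPs monomorphic across the alternate parents are redrawn so
    every SNP segregates in at least one family.
    """
    if n_parents < 2 or n_snps < 1:
        raise ValueError("need n_parents >= 2 and n_snps >= 1")
    rng = np.random.default_rng(seed)
    if maf_spectrum is None:
        draw = lambda size: rng.uniform(0.05, 0.5, size)
    elif callable(maf_spectrum):
        draw = lambda size: np.asarray(maf_spectrum(rng, size), float)
    else:
        p = float(maf_spectrum)
        if not 0 < p < 1:
            raise ValueError("maf must be in (0, 1)")
        draw = lambda size: np.full(size, p)

    freqs = draw(n_snps)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("maf_spectrum produced frequencies outside (0, 1)")
    alleles = np.zeros((n_snps, n_parents), dtype=np.int8)
    alleles[:, 1:] = rng.random((n_snps, n_parents - 1)) < freqs[:, None]
    # redraw monomorphic SNPs until each segregates somewhere
    while True:
        mono = alleles[:, 1:].sum(axis=1) == 0
        if not mono.any():
            break
        k = int(mono.sum())
        f = draw(k)
        alleles[mono, 1:] = rng.random((k, n_parents - 1)) < f[:, None]

    # positions uniform on physical coordinates, chromosome picked by bp share
    lbp = gmap.chromosomes["length_bp"].to_numpy(float)
    chrom_ids = gmap.chromosomes.index.to_numpy()
    chrom = rng.choice(chrom_ids, size=n_snps, p=lbp / lbp.sum())
    bp = np.array([rng.integers(1, gmap.chromosomes.loc[c, "length_bp"]) for c in chrom])
    snps = pd.DataFrame({"chrom": chrom, "bp": bp})
    snps["cm"] = [gmap.bp_to_cm(c, b) for c, b in zip(chrom, bp)]
    order = np.lexsort((snps["bp"].to_numpy(), snps["chrom"].to_numpy()))
    snps = snps.iloc[order].reset_index(drop=True)
    alleles = alleles[order]
    snps["id"] = [f"s{c}_{b}_{i}" for i, (c, b) in enumerate(zip(snps["chrom"], snps["bp"]))]
    snps = snps[["chrom", "id", "cm", "bp"]]
    parents = [f"P{i:02d}" for i in range(n_parents)]
    return FounderPanel(parents, snps, alleles)


# ---------------------------------------------------------------------------
# Meiosis and RIL simulation
# ---------------------------------------------------------------------------
# A haplotype along one chromosome is (breaks, founders): segment i covers
# [breaks[i], breaks[i+1]) with founder label founders[i]; the last segment
# runs to the chromosome end.  breaks[0] == 0.

def founder_at(hap, pos):
    """Founder label(s) of a haplotype at genetic position(s) ``pos`` (cM)."""
    breaks, founders = hap
    idx = np.searchsorted(breaks, np.atleast_1d(pos), side="right") - 1
    out = founders[idx]
    return out if np.ndim(pos) else out[0]


def _meiosis(hap_a, hap_b, length_cm: float, rng) -> tuple:
    """One gamete from a diploid: Poisson(L/100) crossovers, uniform placement."""
    n_co = rng.poisson(length_cm / 100.0)
    start = int(rng.integers(2))
    if n_co == 0:
        hap = (hap_a, hap_b)[start]
        return (hap[0].copy(), hap[1].copy())
    xpts = np.sort(rng.uniform(0.0, length_cm, n_co))
    bounds = np.concatenate([[0.0], xpts, [length_cm]])
    breaks, founders = [], []
    active = start
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        b, f = (hap_a, hap_b)[active]
        j0 = np.searchsorted(b, lo, side="right") - 1
        j1 = np.searchsorted(b, hi, side="left")
        segs = np.concatenate([[lo], b[j0 + 1:j1]])
        for s, lab in zip(segs, f[j0:j1]):
            if founders and founders[-1] == lab:
                continue  # merge with previous segment
            breaks.append(s)
            founders.append(lab)
        active = 1 - active
    return (np.asarray(breaks), np.asarray(founders))


@dataclass
class RILPopulation:
    """Family-structured RIL marker genotypes plus founder mosaics.

    ``genotypes`` is (n_rils, n_markers) with codes 0 / 0.5 / 1 / NaN.
    ``mosaics[i][chrom]`` is the pair of haplotypes of RIL ``i`` on that
    chromosome, kept so projection and genetic values can be checked against
    the exact simulated ancestry.  ``family_parents`` maps family id to the
    (common, alternate) founder indices of its cross.
    """

    lines: pd.DataFrame            # line, family
    markers: pd.DataFrame          # chrom, id, cm, bp (same order as columns)
    genotypes: np.ndarray
    mosaics: list
    family_parents: dict

    @property
    def n_rils(self) -> int:
        return len(self.lines)

    @property
    def families(self) -> np.ndarray:
        return self.lines["family"].to_numpy()

    def heterozygosity(self) -> float:
        g = self.genotypes
        return float(np.nanmean(g == HET))

    def homozygosity(self) -> float:
        g = self.genotypes
        return float(np.nanmean((g == COMMON) | (g == ALT)))

    def genotypes_from_mosaics(self) -> np.ndarray:
        """Recompute the marker genotype matrix from the stored mosaics."""
        out = np.empty((self.n_rils, len(self.markers)))
        for i in range(self.n_rils):
            out[i] = _genotype_row(self.mosaics[i], self.markers,
                                   self.family_parents[self.lines["family"].iat[i]][0])
        return out

    def founder_dosage_at(self, chrom, cm) -> np.ndarray:
        """Fraction of alternate-founder ancestry of every RIL at one locus."""
        out = np.empty(self.n_rils)
        for i in range(self.n_rils):
            common = self.family_parents[self.lines["family"].iat[i]][0]
            h0, h1 = self.mosaics[i][chrom]
            out[i] = (int(founder_at(h0, cm) != common)
                      + int(founder_at(h1, cm) != common)) / 2.0
        return out


def _genotype_row(mosaic, markers: pd.DataFrame, common) -> np.ndarray:
    row = np.empty(len(markers))
    pos = 0
    for chrom, grp in markers.groupby("chrom", sort=False):
        cm = grp["cm"].to_numpy()
        h0, h1 = mosaic[chrom]
        a = (founder_at(h0, cm) != common).astype(float)
        b = (founder_at(h1, cm) != common).astype(float)
        row[pos:pos + len(cm)] = (a + b) / 2.0
        pos += len(cm)
    return row


def simulate_ril_family(founder_pair: tuple, gmap: GeneticMap, n_rils: int,
                        n_selfing: int = 5, seed: int | None = None,
                        family: int = 1, missing_rate: float = 0.0) -> RILPopulation:
    """Simulate one biparental RIL family by single-seed descent.

    The F1 carries one intact haplotype from each founder; each of the
    ``n_selfing`` generations draws two independent gametes from the current
    plant (so ``n_selfing=1`` is the F2 with expected heterozygosity 0.5, and
    ``n_selfing=5`` leaves (1/2)**5 ~ 3.1% residual heterozygosity).
    """
    common, alt = founder_pair
    if common == alt:
        raise ValueError("degenerate family: founders are identical")
    if n_selfing < 0:
        raise ValueError("n_selfing must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = gmap.chromosomes["length_cm"]
    mosaics, rows = [], []
    for i in range(n_rils):
        plant = {
            c: ((np.array([0.0]), np.array([common])),
                (np.array([0.0]), np.array([alt])))
            for c in gmap.chromosomes.index
        }
        for _ in range(n_selfing):
            plant = {
                c: (_meiosis(*plant[c], lengths[c], rng),
                    _meiosis(*plant[c], lengths[c], rng))
                for c in plant
            }
        mosaics.append(plant)
        rows.append((f"F{family:02d}_R{i:04d}", family))
    lines = pd.DataFrame(rows, columns=["line", "family"])
    geno = np.vstack([_genotype_row(m, gmap.markers, common) for m in mosaics]) \
        if n_rils else np.empty((0, gmap.n_markers))
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = np.nan
    return RILPopulation(lines, gmap.markers.copy(), geno, mosaics,
                         {family: (common, alt)})


def simulate_nam(gmap: GeneticMap, panel: FounderPanel, n_rils_per_family: int,
                 n_selfing: int = 5, seed: int | None = None,
                 missing_rate: float = 0.0) -> RILPopulation:
    """Simulate the full NAM design: one RIL family per alternate founder."""
    rng = np.random.default_rng(seed)
    pops = [
        simulate_ril_family((0, f), gmap, n_rils_per_family, n_selfing,
                            seed=int(rng.integers(2 ** 31)), family=f,
                            missing_rate=missing_rate)
        for f in range(1, panel.n_parents)
    ]
    lines = pd.concat([p.lines for p in pops], ignore_index=True)
    geno = np.vstack([p.genotypes for p in pops])
    mosaics = [m for p in pops for m in p.mosaics]
    fparents = {}
    for p in pops:
        fparents.update(p.family_parents)
    return RILPopulation(lines, gmap.markers.copy(), geno, mosaics, fparents)


# ---------------------------------------------------------------------------
# Trait architectures and phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    """Per-trait QTL positions and per-founder allelic effects.

    ``qtl[trait]`` is a DataFrame (chrom, cm) and ``effects[trait]`` the
    matching (n_qtl, n_parents) effect matrix with column 0 (the common
    parent) fixed at 0 — all effects are deviations from the reference
    allele.  ``categories`` carries the trait-category label used to give,
    e.g., ear-like traits systematically larger effects than tassel-like
    ones.
    """

    qtl: dict
    effects: dict
    categories: dict

    @property
    def traits(self) -> list:
        return list(self.qtl)


def simulate_trait_architecture(panel: FounderPanel, gmap: GeneticMap,
                                traits_spec: Mapping,
                                pleiotropy_spec: Sequence[Mapping] = (),
                                category_scales: Mapping | None = None,
                                seed: int | None = None) -> TraitArchitecture:
    """Draw QTL positions and founder effects for a set of traits.

    ``traits_spec`` maps trait name -> {"n_qtl": int, "category": str}.
    ``category_scales`` maps category -> effect SD (default 1.0).
    ``pleiotropy_spec`` entries {"traits": (a, b), "n_shared": k,
    "correlation": rho} force ``k`` QTL to sit at identical positions in both
    traits with founder-effect vectors correlated at ``rho`` (rho=1 makes
    them proportional).
    """
    rng = np.random.default_rng(seed)
    scales = dict(category_scales or {})
    for spec in pleiotropy_spec:
        a, b = spec["traits"]
        if a not in traits_spec or b not in traits_spec:
            raise ValueError(f"pleiotropy requested between undeclared traits {a!r}, {b!r}")

    n_par = panel.n_parents

    def draw_positions(k):
        lcm = gmap.chromosomes["length_cm"].to_numpy()
        chrom = rng.choice(gmap.chromosomes.index.to_numpy(), size=k, p=lcm / lcm.sum())
        cm = np.array([rng.uniform(0, gmap.chromosomes.loc[c, "length_cm"]) for c in chrom])
        return pd.DataFrame({"chrom": chrom, "cm": cm})

    def draw_effects(k, category):
        e = rng.normal(0.0, scales.get(category, 1.0), (k, n_par))
        e[:, 0] = 0.0
        return e

    qtl = {t: draw_positions(s["n_qtl"]) for t, s in traits_spec.items()}
    effects = {t: draw_effects(s["n_qtl"], s["category"]) for t, s in traits_spec.items()}
    cats = {t: s["category"] for t, s in traits_spec.items()}

    for spec in pleiotropy_spec:
        a, b = spec["traits"]
        k = int(spec["n_shared"])
        rho = float(spec.get("correlation", 1.0))
        if k > min(len(qtl[a]), len(qtl[b])):
            raise ValueError("n_shared exceeds a trait's QTL count")
        shared = draw_positions(k)
        qtl[a].iloc[:k] = shared.values
        qtl[b].iloc[:k] = shared.values
        ea = effects[a][:k, 1:]
        noise = rng.normal(0.0, 1.0, ea.shape)
        noise = (noise - noise.mean(axis=1, keepdims=True))
        sb = scales.get(cats[b], 1.0)
        sa = ea.std(axis=1, keepdims=True)
        sa[sa == 0] = 1.0
        eb = rho * ea / sa + np.sqrt(max(0.0, 1 - rho ** 2)) * noise / np.maximum(noise.std(axis=1, keepdims=True), 1e-12)
        effects[b][:k, 1:] = eb * sb
        effects[b][:k, 0] = 0.0

    for t in qtl:  # keep QTL in genome order
        order = np.lexsort((qtl[t]["cm"].to_numpy(), qtl[t]["chrom"].to_numpy()))
        qtl[t] = qtl[t].iloc[order].reset_index(drop=True)
        effects[t] = effects[t][order]
    return TraitArchitecture(qtl, effects, cats)


def genetic_values(rils: RILPopulation, arch: TraitArchitecture,
                   trait: str) -> np.ndarray:
    """True genetic value of every RIL: sum of mean haplotype effects per QTL."""
    g = np.zeros(rils.n_rils)
    qtl = arch.qtl[trait]
    eff = arch.effects[trait]
    for q in range(len(qtl)):
        chrom, cm = qtl["chrom"].iat[q], qtl["cm"].iat[q]
        for i in range(rils.n_rils):
            h0, h1 = rils.mosaics[i][chrom]
            f0, f1 = founder_at(h0, cm), founder_at(h1, cm)
            g[i] += (eff[q, f0] + eff[q, f1]) / 2.0
    return g


def founder_genetic_values(arch: TraitArchitecture, trait: str) -> np.ndarray:
    """Genetic value of each (fully inbred) founder: column sums of the QTL
    effect matrix.  The common parent sits at 0 by construction."""
    return arch.effects[trait].sum(axis=0)


def simulate_phenotypes(rils: RILPopulation, arch: TraitArchitecture,
                        n_env: int = 8, H2_target: float = 0.90,
                        seed: int | None = None, fe_share: float = 0.2,
                        env_var_ratio: float = 0.5) -> pd.DataFrame:
    """Balanced multi-environment phenotypes at a target line-mean H².

    For each trait, variances of the family-by-environment and residual terms
    are solved so that Vg / (Vg + Vfe/E + Vres/E) equals ``H2_target``, with
    ``fe_share`` of the noise allotted to family-by-environment interaction.
    Environment main effects (variance ``env_var_ratio * Vg``) shift whole
    environments and cancel from line means.  With no QTL the phenotype is
    pure noise at unit residual variance.
    """
    if n_env < 1:
        raise ValueError("n_env must be >= 1")
    if not 0 < H2_target < 1:
        raise ValueError("H2_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    fam = rils.families
    fam_ids = np.unique(fam)
    records = []
    envs = [f"env{e + 1}" for e in range(n_env)]
    for trait in arch.traits:
        g = genetic_values(rils, arch, trait)
        # line-mean H2 is defined against line-within-family variance, so the
        # noise is solved against the within-family genetic variance
        g_dev = g.copy()
        for f in fam_ids:
            rows = fam == f
            g_dev[rows] -= g[rows].mean()
        vg = float(np.var(g_dev))
        noise_total = (vg * (1 - H2_target) / H2_target * n_env) if vg > 0 else float(n_env)
        v_fe = fe_share * noise_total
        v_res = (1 - fe_share) * noise_total
        v_env = env_var_ratio * vg
        env_eff = rng.normal(0, np.sqrt(v_env), n_env) if v_env > 0 else np.zeros(n_env)
        fe = rng.normal(0, np.sqrt(v_fe), (len(fam_ids), n_env))
        fe_idx = {f: i for i, f in enumerate(fam_ids)}
        for e, env in enumerate(envs):
            vals = (g + env_eff[e]
                    + fe[[fe_idx[f] for f in fam], e]
                    + rng.normal(0, np.sqrt(v_res), rils.n_rils))
            for line, f, v in zip(rils.lines["line"], fam, vals):
                records.append((line, f, env, trait, v))
    return pd.DataFrame(records, columns=["line", "family", "environment", "trait", "value"])


def simulate_gene_annotation(gmap: GeneticMap, n_genes: int,
                             seed: int | None = None) -> pd.DataFrame:
    """Random gene annotation: transcript midpoints uniform on physical maps."""
    rng = np.random.default_rng(seed)
    lbp = gmap.chromosomes["length_bp"].to_numpy(float)
    chrom = rng.choice(gmap.chromosomes.index.to_numpy(), size=n_genes, p=lbp / lbp.sum())
    bp = np.array([rng.integers(1, gmap.chromosomes.loc[c, "length_bp"]) for c in chrom])
    cm = np.array([gmap.bp_to_cm(c, b) for c, b in zip(chrom, bp)])
    genes = pd.DataFrame({
        "gene": [f"g{i:05d}" for i in range(n_genes)],
        "chrom": chrom, "cm": cm, "bp": bp,
    })
    return genes.sort_values(["chrom", "cm"], ignore_index=True)


# ---------------------------------------------------------------------------
# Writers (plain-text interchange formats)
# ---------------------------------------------------------------------------

def write_map_tsv(gmap: GeneticMap, path) -> None:
    # chromosome lengths ride along as comment lines so the map round-trips
    with open(path, "w") as fh:
        for chrom, row in gmap.chromosomes.iterrows():
            fh.write(f"#chromosome\t{chrom}\t{row.length_cm}\t{int(row.length_bp)}\n")
        gmap.markers.to_csv(fh, sep="\t", index=False)


def write_genotypes_tsv(rils: RILPopulation, path) -> None:
    codes = np.empty(rils.genotypes.shape, dtype=object)
    codes[rils.genotypes == COMMON] = "0"
    codes[rils.genotypes == ALT] = "1"
    codes[rils.genotypes == HET] = "H"
    codes[np.isnan(rils.genotypes.astype(float))] = "NA"
    frac = ~((rils.genotypes == COMMON) | (rils.genotypes == ALT) |
             (rils.genotypes == HET) | np.isnan(rils.genotypes.astype(float)))
    if frac.any():  # imputed fractional dosages
        codes[frac] = [f"{v:.4f}" for v in rils.genotypes[frac]]
    df = pd.DataFrame(codes, columns=rils.markers["id"])
    df.insert(0, "family", rils.lines["family"].to_numpy())
    df.insert(0, "line", rils.lines["line"].to_numpy())
    df.to_csv(path, sep="\t", index=False)


def write_founders_tsv(panel: FounderPanel, path) -> None:
    df = panel.snps.copy()
    for j, p in enumerate(panel.parents):
        df[p] = panel.alleles[:, j]
    df.to_csv(path, sep="\t", index=False)


def write_founders_vcf(panel: FounderPanel, path) -> None:
    """Minimal VCF 4.2 with the common parent as the reference sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=namqtl-simulated\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.parents) + "\n")
        for i, row in panel.snps.iterrows():
            gts = "\t".join(f"{a}/{a}" for a in panel.alleles[i])
            fh.write(f"{row.chrom}\t{row.bp}\t{row.id}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_phenotypes_tsv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def write_architecture_json(arch: TraitArchitecture, path) -> None:
    payload = {
        t: {
            "category": arch.categories[t],
            "qtl": [
                {"chrom": int(arch.qtl[t]["chrom"].iat[q]),
                 "cm": float(arch.qtl[t]["cm"].iat[q]),
                 "effects": [float(x) for x in arch.effects[t][q]]}
                for q in range(len(arch.qtl[t]))
            ],
        }
        for t in arch.traits
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
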