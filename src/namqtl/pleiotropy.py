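"""Pleiotropy between trait pairs from per-family effect vectors.

A locus is called pleiotropic for two traits when the Pearson correlation
between their per-family allelic-effect vectors exceeds the two-tailed
Student-t critical value on n_families - 2 degrees of freedom (r > 0.495 at
p < 0.01 with 26 families).  Two routes produce the vectors:

* joint linkage — the QTL model of trait A is refit against trait B's
  BLUPs, and at each of A's QTL the two 26-length family-effect vectors are
  correlated; the trait-pair "percent shared QTL" is the sum of the two
  directional fractions of significant QTL (so it lies in [0, 2]);
* GWAS — SNP effects are RMIP-weighted and averaged per family in sliding
  genomic windows (5 cM window, 2.5 cM step by default); windows where
  either trait's RMIP sum falls below a floor are excluded, and qualifying
  windows are tested with the same correlation criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .jointlinkage import JLModel, fit_jl_model
from .simulate import FounderPanel, GeneticMap


def critical_r(df: int, alpha: float) -> float:
    """Two-tailed critical Pearson correlation: r* = t*/sqrt(t*^2 + df)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(t / np.sqrt(t * t + df))


@dataclass
class PleiotropyTest:
    locus: str            # marker id or "chrom:start-end" window label
    trait_a: str
    trait_b: str
    r: float
    significant: bool
    sign: int             # +1 / -1 for significant tests, 0 otherwise


@dataclass
class PleiotropyEdge:
    trait_a: str
    trait_b: str
    percent_shared: float   # in [0, 2] for JL (sum of fractions); [0, 1] for GWAS
    signs: str              # "positive" | "negative" | "both" | "none"
    n_tests: int

    @property
    def display(self) -> bool:
        return self.percent_shared >= 0.10


def _signs_label(signs: set) -> str:
    if {1, -1} <= signs:
        return "both"
    if 1 in signs:
        return "positive"
    if -1 in signs:
        return "negative"
    return "none"


def _correlate(ea: np.ndarray, eb: np.ndarray, r_crit: float):
    if np.std(ea) == 0 or np.std(eb) == 0:
        return None
    r = float(np.corrcoef(ea, eb)[0, 1])
    return r, abs(r) > r_crit


# ---------------------------------------------------------------------------
# Joint-linkage route
# ---------------------------------------------------------------------------

def jl_pleiotropy(genotypes: np.ndarray, markers: pd.DataFrame, families,
                  model_a: JLModel, model_b: JLModel, blups_a, blups_b,
                  alpha: float = 0.01):
    """Cross-apply two traits' QTL models and correlate family-effect vectors.

    Returns ``(tests, edge)``: one test per QTL per direction, and the edge
    with percent shared = fraction(A model on B significant) +
    fraction(B model on A significant).  Zero-variance effect vectors are
    skipped and count as non-significant.
    """
    n_fam = len(model_a.family_ids)
    r_crit = critical_r(n_fam - 2, alpha)
    tests: list[PleiotropyTest] = []
    signs: set = set()
    fracs = []
    for mod, other_y, ta, tb in ((model_a, blups_b, model_a.trait, model_b.trait),
                                 (model_b, blups_a, model_b.trait, model_a.trait)):
        if mod.n_qtl == 0:
            fracs.append(0.0)
            continue
        refit = fit_jl_model(genotypes, other_y, families, markers,
                             mod.marker_idx, trait=tb)
        n_sig = 0
        for q in range(mod.n_qtl):
            res = _correlate(mod.effects[q], refit.effects[q], r_crit)
            if res is None:
                tests.append(PleiotropyTest(mod.markers["id"].iat[q], ta, tb,
                                            np.nan, False, 0))
                continue
            r, sig = res
            sign = int(np.sign(r)) if sig else 0
            if sig:
                n_sig += 1
                signs.add(sign)
            tests.append(PleiotropyTest(mod.markers["id"].iat[q], ta, tb, r,
                                        sig, sign))
        fracs.append(n_sig / mod.n_qtl)
    edge = PleiotropyEdge(model_a.trait, model_b.trait, float(sum(fracs)),
                          _signs_label(signs), len(tests))
    return tests, edge


# ---------------------------------------------------------------------------
# GWAS sliding-window route
# ---------------------------------------------------------------------------

@dataclass
class WindowEffectVector:
    chrom: object
    start: float
    end: float
    trait: str
    vector: np.ndarray     # per-family RMIP-weighted mean effect
    rmip_sum: float

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start:g}-{self.end:g}"


def window_effect_vectors(assocs: pd.DataFrame, panel: FounderPanel,
                          gmap: GeneticMap, trait: str = "trait",
                          window: float = 5.0, step: float = 2.5) -> list:
    """Per-family RMIP-weighted mean SNP effects in sliding genomic windows.

    A SNP contributes its median effect in the families where it segregates
    and 0 elsewhere, weighted by its RMIP; the window vector is the weighted
    mean over SNPs whose cM position falls in [start, start + window).
    Windows tile each chromosome from 0 with the given step; windows with no
    SNPs are omitted.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if len(assocs) == 0:
        return []
    seg = {panel.snps["id"].iat[i]: panel.alleles[i, 1:].astype(float)
           for i in range(len(panel.snps))}
    n_fam = panel.n_families
    out = []
    for chrom, grp in assocs.groupby("chrom"):
        length = float(gmap.chromosomes.loc[chrom, "length_cm"])
        starts = np.arange(0.0, max(length - window, 0.0) + 1e-9, step)
        if len(starts) == 0:
            starts = np.array([0.0])
        cm = grp["cm"].to_numpy(float)
        for s in starts:
            inwin = (cm >= s) & (cm < s + window)
            if not inwin.any():
                continue
            sub = grp[inwin]
            w = sub["rmip"].to_numpy(float)
            eff = sub["median_effect"].to_numpy(float)
            M = np.vstack([seg[sid] for sid in sub["snp"]])  # (k, n_fam)
            vec = (w[:, None] * eff[:, None] * M).sum(axis=0) / w.sum()
            out.append(WindowEffectVector(chrom, float(s), float(s + window),
                                          trait, vec, float(w.sum())))
    return out


def gwas_pleiotropy(windows_a: list, windows_b: list, alpha: float = 0.01,
                    rmip_sum_min: float = 0.1):
    """Correlate two traits' window effect vectors on a common window grid.

    Only windows where *both* traits' RMIP sums reach ``rmip_sum_min`` are
    tested.  Returns ``(tests, edge)`` with percent shared = fraction of
    qualifying windows significant.
    """
    index_b = {(w.chrom, w.start): w for w in windows_b}
    tests: list[PleiotropyTest] = []
    signs: set = set()
    n_sig = 0
    trait_a = windows_a[0].trait if windows_a else "A"
    trait_b = windows_b[0].trait if windows_b else "B"
    for wa in windows_a:
        wb = index_b.get((wa.chrom, wa.start))
        if wb is None or wa.rmip_sum < rmip_sum_min or wb.rmip_sum < rmip_sum_min:
            continue
        n_fam = len(wa.vector)
        res = _correlate(wa.vector, wb.vector, critical_r(n_fam - 2, alpha))
        if res is None:
            tests.append(PleiotropyTest(wa.label, wa.trait, wb.trait, np.nan,
                                        False, 0))
            continue
        r, sig = res
        sign = int(np.sign(r)) if sig else 0
        if sig:
            n_sig += 1
            signs.add(sign)
        tests.append(PleiotropyTest(wa.label, wa.trait, wb.trait, r, sig, sign))
    pct = n_sig / len(tests) if tests else 0.0
    edge = PleiotropyEdge(trait_a, trait_b, float(pct), _signs_label(signs),
                          len(tests))
    return tests, edge


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def edges_to_graph(edges: list, min_percent: float = 0.10):
    """Trait-pleiotropy graph (networkx) keeping edges above the display
    floor; edge weight is percent shared, edge sign class is an attribute."""
    import networkx as nx

    G = nx.Graph()
    for e in edges:
        G.add_node(e.trait_a)
        G.add_node(e.trait_b)
        if e.percent_shared >= min_percent:
            G.add_edge(e.trait_a, e.trait_b, weight=e.percent_shared,
                       sign=e.signs)
    return G


def edges_to_frame(edges: list) -> pd.DataFrame:
    return pd.DataFrame([
        {"trait_a": e.trait_a, "trait_b": e.trait_b,
         "percent_shared": e.percent_shared, "signs": e.signs,
         "n_tests": e.n_tests}
        for e in edges
    ])
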