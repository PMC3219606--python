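"""Effect-size architecture: scaling, reference-design bias correction,
frequency classification, and distribution comparison.

Raw allelic effects are in trait units and are not comparable across
traits.  Effects are therefore scaled by the *total heritable variation* of
the trait: the standard deviation of the trait's BLUPs across a diversity
panel multiplied by the broad-sense heritability (a "divide by SD, then by
H2" variant is available for comparison).

A reference design (every founder crossed to one common parent) inflates
effects for traits where the common parent is phenotypically extreme, since
all effects are deviations from its allele.  The correction replaces the
n-vector of effects-vs-reference by the C(n,2) absolute pairwise differences
between alternate founders — the predicted QTL effect in every possible
biparental cross — which is invariant to shifting the reference point.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import FounderPanel


@dataclass
class ScalingFactors:
    """Per-trait scaling: scaled effect = |effect| / (blup_sd * H2)."""
    blup_sd: float
    H2: float

    @property
    def total_heritable_variation(self) -> float:
        return self.blup_sd * self.H2


def scaling_factors(panel_blups, H2: float, variant: str = "sd_times_h2") -> ScalingFactors:
    """Scaling denominator from a diversity panel's BLUPs and heritability.

    ``variant='sd_times_h2'`` (default) scales effects by SD * H2;
    ``variant='sd_only'`` divides by the SD alone and the caller multiplies
    by H2 afterwards (kept for comparison; the two differ by H2**2).
    """
    panel_blups = np.asarray(panel_blups, float)
    if len(panel_blups) < 2:
        raise ValueError("diversity panel needs >= 2 lines")
    sd = float(np.std(panel_blups, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance diversity panel")
    if variant not in ("sd_times_h2", "sd_only"):
        raise ValueError(f"unknown scaling variant {variant!r}")
    return ScalingFactors(sd, float(H2) if variant == "sd_times_h2" else 1.0)


def scale_effects(effects, sf: ScalingFactors) -> np.ndarray:
    """Dimensionless |effect| / total heritable variation."""
    return np.abs(np.asarray(effects, float)) / sf.total_heritable_variation


def pairwise_effects(effect_vector) -> np.ndarray:
    """All C(n,2) absolute pairwise effect differences between alternate
    parents — the predicted QTL effect sizes in every pairwise mating.

    For two parents with effects +1 and -1 relative to the common parent the
    predicted effect in their cross is 2.  With 26 alternate parents this
    yields 325 values per QTL.
    """
    e = np.asarray(effect_vector, float)
    if len(e) < 2:
        raise ValueError("need effects for >= 2 parents")
    i, j = np.triu_indices(len(e), k=1)
    return np.abs(e[i] - e[j])


def snp_family_frequency(panel: FounderPanel, snp_id: str) -> int:
    """Number of families whose alternate parent carries the SNP's
    alternate allele (SNPs in <= 4 families are the low-frequency class)."""
    idx = panel.snps.index[panel.snps["id"] == snp_id]
    if len(idx) == 0:
        raise KeyError(f"SNP {snp_id!r} not in panel")
    return int(panel.alleles[idx[0], 1:].sum())


def jl_family_frequency(effect_vector, rel_threshold: float = 0.25) -> int:
    """Number of families carrying an appreciable effect at a joint-linkage
    QTL: |effect| above ``rel_threshold`` times the largest family effect."""
    e = np.abs(np.asarray(effect_vector, float))
    if e.max() == 0:
        return 0
    return int((e > rel_threshold * e.max()).sum())


def select_top_snps(assocs: pd.DataFrame, n: int) -> pd.DataFrame:
    """First ``n`` associations by decreasing RMIP; ties broken by larger
    |median effect|, then genome order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(assocs) < n:
        import warnings
        warnings.warn(f"only {len(assocs)} associations available (< {n})")
    key = assocs.assign(_abs=assocs["median_effect"].abs())
    key = key.sort_values(["rmip", "_abs", "chrom", "cm"],
                          ascending=[False, False, True, True],
                          kind="stable").drop(columns="_abs")
    return key.head(n).reset_index(drop=True)


@dataclass
class DistributionComparison:
    statistic: float   # KS sup-distance D
    pvalue: float
    n_a: int
    n_b: int


def ks_compare(effects_a, effects_b) -> DistributionComparison:
    """Two-sample Kolmogorov-Smirnov comparison of effect distributions."""
    a = np.asarray(effects_a, float)
    b = np.asarray(effects_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return DistributionComparison(float(res.statistic), float(res.pvalue),
                                  len(a), len(b))
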