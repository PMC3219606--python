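"""Additive phenotype prediction from RMIP-weighted GWAS models.

Predicted value = sum over retained SNPs of RMIP * median effect * dosage,
optionally plus the cohort's family mean.  Predictive ability is the squared
Pearson correlation between predictions and observed values, evaluated
either in the RILs (projected dosages) or in the founders themselves
(0/1 SNP genotypes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PredictionReport:
    trait: str
    cohort: str            # "parents" | "rils"
    with_family: bool
    r2: float
    degenerate: bool = False


def additive_prediction(assocs: pd.DataFrame, dosages: pd.DataFrame | np.ndarray,
                        snp_ids=None, family_means: pd.Series | dict | None = None,
                        families=None, include_family: bool = False) -> np.ndarray:
    """Sum of RMIP-weighted median SNP effects over a dosage matrix.

    ``dosages`` is (n_individuals, n_snps) with columns named by SNP id (a
    DataFrame) or accompanied by ``snp_ids``.  SNPs in ``assocs`` missing
    from the dosage matrix contribute nothing (logged).  With
    ``include_family`` each individual also receives its family's mean
    (requires ``family_means`` and ``families``).
    """
    if isinstance(dosages, pd.DataFrame):
        snp_ids = list(dosages.columns)
        D = dosages.to_numpy(float)
    else:
        D = np.asarray(dosages, float)
        snp_ids = list(snp_ids)
    col = {s: j for j, s in enumerate(snp_ids)}
    w = np.zeros(D.shape[1])
    missing = []
    for _, row in assocs.iterrows():
        j = col.get(row["snp"])
        if j is None:
            missing.append(row["snp"])
            continue
        w[j] += row["rmip"] * row["median_effect"]
    if missing:
        warnings.warn(f"{len(missing)} association SNPs missing from dosage matrix")
    pred = D @ w
    if include_family:
        if family_means is None or families is None:
            raise ValueError("include_family requires family_means and families")
        fm = dict(family_means)
        pred = pred + np.array([fm[f] for f in families])
    return pred


def predictive_ability(predictions, observed, trait: str = "trait",
                       cohort: str = "rils", with_family: bool = False) -> PredictionReport:
    """Squared Pearson correlation of predicted vs observed values.

    Degenerate inputs (zero variance on either side, e.g. an empty SNP
    model without a family term) report r2 = 0 with a flag.
    """
    p = np.asarray(predictions, float)
    o = np.asarray(observed, float)
    if len(p) != len(o) or len(p) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(p) == 0 or np.std(o) == 0:
        return PredictionReport(trait, cohort, with_family, 0.0, degenerate=True)
    r = float(np.corrcoef(p, o)[0, 1])
    return PredictionReport(trait, cohort, with_family, r * r)


def prediction_grid(reports: list) -> pd.DataFrame:
    """Tidy trait x cohort x family-term table of predictive abilities."""
    return pd.DataFrame([
        {"trait": r.trait, "cohort": r.cohort, "with_family": r.with_family,
         "r2": r.r2, "degenerate": r.degenerate}
        for r in reports
    ])
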