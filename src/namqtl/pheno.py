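"""Phenotype preparation: Box-Cox transformation, variance components,
line BLUPs, and broad-sense heritability on a line-mean basis.

The random-effects model is

    y_{lfe} = mu + E_e + F_f + (FE)_{fe} + L_{l(f)} + eps_{lfe}

with environment, family, family-by-environment, line-within-family and
residual terms.  Components are estimated by equating balanced-layout
expected mean squares (method of moments) and truncating negative estimates
at zero; the simulator emits exactly balanced tables, for which this matches
REML in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxFit:
    """Grid-search Box-Cox fit: (y**lam - 1)/lam, with lam=0 meaning log."""
    lam: float
    grid: np.ndarray
    loglik: np.ndarray
    transformed: np.ndarray


def boxcox_transform(values: np.ndarray, lam: float) -> np.ndarray:
    values = np.asarray(values, float)
    if lam == 0:
        return np.log(values)
    return (values ** lam - 1.0) / lam


def boxcox_fit(values, lambda_min: float = -10.0, lambda_max: float = 10.0,
               step: float = 0.1) -> BoxCoxFit:
    """Profile-likelihood Box-Cox fit over a fixed lambda grid.

    The grid runs from ``lambda_min`` to ``lambda_max`` in increments of
    ``step``; lambda values of 0 and 1 correspond to log and (affine-) linear
    transformations.  Values must be strictly positive; shift before calling
    if they are not.
    """
    values = np.asarray(values, float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-d sample of length >= 2")
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values; shift first")
    if np.ptp(values) == 0:
        raise ValueError("constant sample: Box-Cox lambda is undefined")
    n = int(round((lambda_max - lambda_min) / step))
    grid = lambda_min + step * np.arange(n + 1)
    loglik = np.array([stats.boxcox_llf(l, values) for l in grid])
    lam = float(grid[int(np.argmax(loglik))])
    return BoxCoxFit(lam, grid, loglik, boxcox_transform(values, lam))


# ---------------------------------------------------------------------------
# Variance components (balanced EMS)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    line: float
    family: float
    environment: float
    family_env: float
    residual: float
    confounded: bool = False  # single environment: fam_env folded into residual

    def as_dict(self) -> dict:
        return {
            "line": self.line, "family": self.family,
            "environment": self.environment, "family_env": self.family_env,
            "residual": self.residual, "confounded": self.confounded,
        }


def _check_single_trait(pheno: pd.DataFrame) -> pd.DataFrame:
    if "trait" in pheno.columns and pheno["trait"].nunique() > 1:
        raise ValueError("pass a single trait's records (filter the trait column)")
    return pheno


def estimate_variance_components(pheno: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments variance components from a balanced long table.

    ``pheno`` needs columns line, family, environment, value (one trait).
    With a single environment the family-by-environment and residual
    components are confounded; both collapse into the residual and the
    result is flagged.
    """
    pheno = _check_single_trait(pheno)
    wide = pheno.pivot_table(index=["family", "line"], columns="environment",
                             values="value")
    if wide.isna().any().any():
        raise ValueError("unbalanced table: every line x environment cell is required")
    y = wide.to_numpy()
    fam = wide.index.get_level_values("family").to_numpy()
    fam_ids, fam_inv = np.unique(fam, return_inverse=True)
    n_fam, n_env = len(fam_ids), y.shape[1]
    n_per = len(y) / n_fam  # lines per family (balanced designs: integer)

    grand = y.mean()
    line_means = y.mean(axis=1)
    fam_means = np.array([line_means[fam_inv == i].mean() for i in range(n_fam)])
    env_means = y.mean(axis=0)
    fe_means = np.vstack([y[fam_inv == i].mean(axis=0) for i in range(n_fam)])

    # mean squares on the per-observation scale
    ms_line = n_env * np.sum((line_means - fam_means[fam_inv]) ** 2) / (len(y) - n_fam)
    if n_env > 1:
        resid = y - line_means[:, None] - fe_means[fam_inv] + fam_means[fam_inv, None]
        ms_res = np.sum(resid ** 2) / ((len(y) - n_fam) * (n_env - 1))
        ms_fe = (n_per * np.sum((fe_means - fam_means[:, None] - env_means[None, :] + grand) ** 2)
                 / ((n_fam - 1) * (n_env - 1))) if n_fam > 1 else ms_res
        ms_env = len(y) * np.sum((env_means - grand) ** 2) / (n_env - 1)
    else:
        ms_res = ms_fe = ms_env = np.nan
    ms_fam = (n_per * n_env * np.sum((fam_means - grand) ** 2) / (n_fam - 1)) if n_fam > 1 else 0.0

    if n_env == 1:
        # with one env, sigma2_line, sigma2_fe and sigma2_res are confounded in
        # the between-line spread; report it as a single line component
        return VarianceComponents(line=max(ms_line, 0.0), family=max(ms_fam, 0.0),
                                  environment=0.0, family_env=0.0,
                                  residual=0.0, confounded=True)

    v_res = ms_res
    v_line = (ms_line - ms_res) / n_env
    v_fe = (ms_fe - ms_res) / n_per
    v_env = (ms_env - ms_res - max(v_fe, 0.0) * n_per) / len(y)
    v_fam = (ms_fam - ms_res - max(v_fe, 0.0) * n_per - max(v_line, 0.0) * n_env) / (n_per * n_env)
    return VarianceComponents(
        line=max(float(v_line), 0.0), family=max(float(v_fam), 0.0),
        environment=max(float(v_env), 0.0), family_env=max(float(v_fe), 0.0),
        residual=max(float(v_res), 0.0),
    )


# ---------------------------------------------------------------------------
# BLUPs and heritability
# ---------------------------------------------------------------------------

def compute_blups(pheno: pd.DataFrame, vc: VarianceComponents) -> pd.DataFrame:
    """Shrunken line genetic values on the balanced design.

    BLUP(line) = family mean + k * (line mean - family mean) with
    k = s2_line / (s2_line + s2_res / n_env): the within-family deviation is
    shrunk by its reliability while the family effect is carried through
    (the joint-linkage model refits family explicitly).  Lines with no
    observations are dropped.
    """
    pheno = _check_single_trait(pheno).dropna(subset=["value"])
    n_env = pheno["environment"].nunique()
    denom = vc.line + vc.residual / n_env
    k = 1.0 if denom == 0 else vc.line / denom
    line_means = pheno.groupby(["family", "line"], sort=False)["value"].mean()
    fam_means = pheno.groupby("family")["value"].mean()
    out = line_means.reset_index(name="line_mean")
    out["blup"] = (fam_means[out["family"]].to_numpy()
                   + k * (out["line_mean"] - fam_means[out["family"]].to_numpy()))
    return out[["line", "family", "blup", "line_mean"]]


def broad_sense_H2(vc: VarianceComponents, n_env: int) -> float:
    """Broad-sense heritability of line means:
    H2 = s2_line / (s2_line + s2_fe/n_env + s2_res/n_env)."""
    if n_env < 1:
        raise ValueError("n_env must be >= 1")
    denom = vc.line + vc.family_env / n_env + vc.residual / n_env
    if denom == 0:
        raise ValueError("all variance components are zero: H2 undefined")
    return float(vc.line / denom)
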