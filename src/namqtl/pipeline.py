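"""End-to-end pipeline: simulate -> prep -> project -> jl -> gwas ->
effects -> pleio -> predict -> enrich, driven by one YAML-able config.

Every stage reads its inputs from, and writes its outputs to, a single run
directory, so stages can be re-run individually from the CLI.  All
stochastic stages draw their seeds deterministically from the master seed,
making a rerun with the same config bit-identical.
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrich as enrich_mod
from . import io as nio
from . import pleiotropy as pleio_mod
from . import predict as predict_mod
from .effects import ks_compare, pairwise_effects, scale_effects, scaling_factors
from .gwas import run_gwas, write_associations_tsv
from .jointlinkage import (fit_jl_model, jl_permutation_threshold,
                           jl_refit_fixed_size, jl_stepwise)
from .pheno import (boxcox_fit, broad_sense_H2, compute_blups,
                    estimate_variance_components)
from .projection import impute_markers, project_snps, write_dosages_tsv
from .simulate import (make_genetic_map,
                       simulate_founders, simulate_gene_annotation,
                       simulate_nam, simulate_phenotypes,
                       simulate_trait_architecture, write_architecture_json,
                       write_founders_tsv, write_genotypes_tsv, write_map_tsv,
                       write_phenotypes_tsv)

# Stage parameter defaults: thresholds and filters follow the published
# analysis (1000 permutations at alpha .05; 100 subsamples of 80%; RMIP
# floor 0.05; 5/2.5 cM windows; 0.5/1/2 cM radii; top-10 SNPs).
DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_families": 26, "n_rils_per_family": 200,
        "n_chrom": 10, "cm_length": 140.0, "bp_length": 2.0e8,
        "n_markers_per_chrom": 84, "n_snps": 5000,
        "n_selfing": 5, "missing_rate": 0.02,
        "n_env": 8, "H2_target": 0.90,
        "traits": {
            "T1": {"n_qtl": 4, "category": "tassel"},
            "E1": {"n_qtl": 4, "category": "ear"},
        },
        "category_scales": {"tassel": 1.0, "ear": 2.0},
        "pleiotropy": [],
        "n_genes": 400,
    },
    "prep": {"boxcox_traits": []},
    "jl": {"n_perm": 1000, "alpha": 0.05, "refit_k": 26},
    "gwas": {"n_perm": 1000, "alpha": 0.05, "n_sub": 100, "frac": 0.8,
             "rmip_min": 0.05},
    "effects": {"scaling_variant": "sd_times_h2", "n_top": 200},
    "pleio": {"window": 5.0, "step": 2.5, "alpha": 0.01,
              "rmip_sum_min": 0.1, "display_min": 0.10},
    "predict": {},
    "enrich": {"n_top": 10, "n_null": 1000, "radii": [0.5, 1.0, 2.0],
               "n_candidates": 15, "candidate_mode": "near_qtl"},
}


def small_preset() -> dict:
    """Desk-scale configuration: 5 families x 100 RILs, 200 markers."""
    cfg = default_config()
    cfg["simulate"].update(n_families=5, n_rils_per_family=100,
                           n_markers_per_chrom=20, n_snps=600, n_genes=150)
    cfg["jl"].update(n_perm=150, refit_k=6)
    cfg["gwas"].update(n_perm=150, n_sub=25)
    cfg["enrich"].update(n_null=200)
    return cfg


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def merge_config(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if k in out and isinstance(out[k], dict) and isinstance(v, dict):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict) -> dict:
    cfg = merge_config(default_config(), cfg)
    for section in DEFAULT_CONFIG:
        unknown = set(cfg[section]) - set(DEFAULT_CONFIG[section])
        if unknown:
            raise ValueError(f"unknown config fields in {section}: {sorted(unknown)}")
    if not 0 < cfg["simulate"]["H2_target"] < 1:
        raise ValueError("simulate.H2_target must be in (0, 1)")
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    import zlib
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _log(run_dir: Path, stage: str, t0: float, **info) -> None:
    entry = {"stage": stage, "wall_s": round(time.time() - t0, 2), **info}
    with open(run_dir / "pipeline.log", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


# ---------------------------------------------------------------------------
# Stages (file based: each reads prior outputs from run_dir)
# ---------------------------------------------------------------------------

def stage_simulate(run_dir: Path, cfg: dict, seed: int) -> None:
    t0 = time.time()
    sc = cfg["simulate"]
    gmap = make_genetic_map(sc["n_chrom"], sc["cm_length"], sc["bp_length"],
                            sc["n_markers_per_chrom"],
                            seed=_stage_seed(seed, "map"))
    panel = simulate_founders(gmap, sc["n_families"] + 1, sc["n_snps"],
                              seed=_stage_seed(seed, "founders"))
    rils = simulate_nam(gmap, panel, sc["n_rils_per_family"], sc["n_selfing"],
                        seed=_stage_seed(seed, "rils"),
                        missing_rate=sc["missing_rate"])
    arch = simulate_trait_architecture(panel, gmap, sc["traits"],
                                       sc.get("pleiotropy", []),
                                       sc.get("category_scales"),
                                       seed=_stage_seed(seed, "arch"))
    pheno = simulate_phenotypes(rils, arch, sc["n_env"], sc["H2_target"],
                                seed=_stage_seed(seed, "pheno"))
    genes = simulate_gene_annotation(gmap, sc["n_genes"],
                                     seed=_stage_seed(seed, "genes"))
    write_map_tsv(gmap, run_dir / "map.tsv")
    write_founders_tsv(panel, run_dir / "founders.tsv")
    write_genotypes_tsv(rils, run_dir / "genotypes.tsv")
    write_phenotypes_tsv(pheno, run_dir / "phenotypes.tsv")
    write_architecture_json(arch, run_dir / "architecture.json")
    genes.to_csv(run_dir / "annotation.tsv", sep="\t", index=False)
    _log(run_dir, "simulate", t0, n_rils=rils.n_rils, n_markers=gmap.n_markers,
         n_snps=len(panel.snps))


def stage_prep(run_dir: Path, cfg: dict, seed: int) -> None:
    t0 = time.time()
    pheno = nio.read_phenotypes_tsv(run_dir / "phenotypes.tsv")
    blup_rows, vcs = [], {}
    for trait, sub in pheno.groupby("trait"):
        sub = sub.copy()
        if trait in cfg["prep"]["boxcox_traits"]:
            shift = max(0.0, 1e-6 - sub["value"].min())
            sub["value"] = boxcox_fit(sub["value"].to_numpy() + shift).transformed
        vc = estimate_variance_components(sub)
        n_env = sub["environment"].nunique()
        vcs[trait] = {**vc.as_dict(), "H2": broad_sense_H2(vc, n_env),
                      "n_env": n_env}
        b = compute_blups(sub, vc)
        b["trait"] = trait
        blup_rows.append(b)
    pd.concat(blup_rows, ignore_index=True).to_csv(
        run_dir / "blups.tsv", sep="\t", index=False)
    with open(run_dir / "varcomp.json", "w") as fh:
        json.dump(vcs, fh, indent=1)
    _log(run_dir, "prep", t0, traits=list(vcs))


def stage_project(run_dir: Path, cfg: dict, seed: int) -> None:
    t0 = time.time()
    gmap = nio.read_map_tsv(run_dir / "map.tsv")
    panel = nio.read_founders_tsv(run_dir / "founders.tsv")
    rils = nio.read_genotypes_tsv(run_dir / "genotypes.tsv", gmap)
    rils = impute_markers(rils, gmap)
    write_genotypes_tsv(rils, run_dir / "genotypes_imputed.tsv")
    dos = project_snps(rils, panel, gmap)
    write_dosages_tsv(dos, run_dir / "dosages.tsv")
    _log(run_dir, "project", t0, n_snps=len(dos.snps))


def _load_jl_inputs(run_dir: Path):
    gmap = nio.read_map_tsv(run_dir / "map.tsv")
    geno_path = run_dir / "genotypes_imputed.tsv"
    if not geno_path.exists():
        geno_path = run_dir / "genotypes.tsv"
    rils = nio.read_genotypes_tsv(geno_path, gmap)
    blups = nio.read_blups_tsv(run_dir / "blups.tsv")
    return gmap, rils, blups


def _trait_blups(blups: pd.DataFrame, rils, trait: str) -> np.ndarray:
    sub = blups[blups["trait"] == trait].set_index("line")["blup"]
    return sub.loc[rils.lines["line"]].to_numpy(float)


def stage_jl(run_dir: Path, cfg: dict, seed: int) -> None:
    t0 = time.time()
    gmap, rils, blups = _load_jl_inputs(run_dir)
    thresholds = {}
    for trait in blups["trait"].unique():
        y = _trait_blups(blups, rils, trait)
        thr = jl_permutation_threshold(rils.genotypes, y, rils.families,
                                       cfg["jl"]["n_perm"], cfg["jl"]["alpha"],
                                       seed=_stage_seed(seed, f"jl-{trait}"))
        model = jl_stepwise(rils.genotypes, y, rils.families, rils.markers,
                            thr, trait=trait)
        if model.n_qtl > cfg["jl"]["refit_k"]:
            model = jl_refit_fixed_size(rils.genotypes, y, rils.families,
                                        rils.markers, model, cfg["jl"]["refit_k"])
        model.to_frame().to_csv(run_dir / f"jl_model_{trait}.tsv", sep="\t",
                                index=False)
        thresholds[trait] = {**thr.as_dict(), "n_qtl": model.n_qtl,
                             "r2": model.r2}
    with open(run_dir / "jl_thresholds.json", "w") as fh:
        json.dump(thresholds, fh, indent=1)
    _log(run_dir, "jl", t0, **{t: thresholds[t]["n_qtl"] for t in thresholds})


def _load_jl_model(run_dir: Path, rils, trait: str, blups):
    df = pd.read_csv(run_dir / f"jl_model_{trait}.tsv", sep="\t")
    ids = list(dict.fromkeys(df["marker"]))
    idx = [int(rils.markers.index[rils.markers["id"] == m][0]) for m in ids]
    y = _trait_blups(blups, rils, trait)
    return fit_jl_model(rils.genotypes, y, rils.families, rils.markers, idx,
                        trait=trait)


def stage_gwas(run_dir: Path, cfg: dict, seed: int) -> None:
    t0 = time.time()
    gmap, rils, blups = _load_jl_inputs(run_dir)
    panel = nio.read_founders_tsv(run_dir / "founders.tsv")
    dos = nio.read_dosages_tsv(run_dir / "dosages.tsv", panel.snps)
    gc = cfg["gwas"]
    for trait in blups["trait"].unique():
        y = _trait_blups(blups, rils, trait)
        model = _load_jl_model(run_dir, rils, trait, blups)
        assoc = run_gwas(dos, rils.genotypes, y, rils.families, model,
                         panel=panel, n_perm=gc["n_perm"], alpha=gc["alpha"],
                         n_sub=gc["n_sub"], frac=gc["frac"],
                         rmip_min=gc["rmip_min"],
                         seed=_stage_seed(seed, f"gwas-{trait}"))
        write_associations_tsv(assoc, run_dir / f"gwas_{trait}.tsv")
    _log(run_dir, "gwas", t0)


def stage_effects(run_dir: Path, cfg: dict, seed: int) -> None:
    t0 = time.time()
    gmap, rils, blups = _load_jl_inputs(run_dir)
    with open(run_dir / "varcomp.json") as fh:
        vcs = json.load(fh)
    with open(run_dir / "architecture.json") as fh:
        arch = json.load(fh)
    ec = cfg["effects"]
    scaled_rows, by_category = [], {}
    for trait in blups["trait"].unique():
        model = _load_jl_model(run_dir, rils, trait, blups)
        # diversity panel analogue: founder genetic values from ground truth
        founder_vals = np.array([q["effects"] for q in arch[trait]["qtl"]]).sum(axis=0) \
            if arch[trait]["qtl"] else np.zeros(2)
        if np.std(founder_vals) == 0:
            continue
        sf = scaling_factors(founder_vals, vcs[trait]["H2"], ec["scaling_variant"])
        cat = arch[trait]["category"]
        for q in range(model.n_qtl):
            pw = scale_effects(pairwise_effects(model.effects[q]), sf)
            jl_scaled = scale_effects(model.effects[q], sf)
            by_category.setdefault(cat, []).extend(pw.tolist())
            for f, v in zip(model.family_ids, jl_scaled):
                scaled_rows.append((trait, cat, model.markers["id"].iat[q],
                                    f, v, "jl"))
        gpath = run_dir / f"gwas_{trait}.tsv"
        if gpath.exists():
            assoc = pd.read_csv(gpath, sep="\t")
            top = assoc.sort_values("rmip", ascending=False).head(ec["n_top"])
            for _, row in top.iterrows():
                scaled_rows.append((trait, cat, row["snp"], np.nan,
                                    float(scale_effects([row["median_effect"]], sf)[0]),
                                    "gwas"))
    pd.DataFrame(scaled_rows, columns=["trait", "category", "locus", "family",
                                       "scaled_effect", "method"]).to_csv(
        run_dir / "effects_scaled.tsv", sep="\t", index=False)
    cats = list(by_category)
    comparisons = {}
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            a, b = by_category[cats[i]], by_category[cats[j]]
            if len(a) >= 2 and len(b) >= 2:
                ks = ks_compare(a, b)
                comparisons[f"{cats[i]}_vs_{cats[j]}"] = {
                    "D": ks.statistic, "p": ks.pvalue,
                    "n": [ks.n_a, ks.n_b]}
    with open(run_dir / "ks_comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=1)
    _log(run_dir, "effects", t0)


def stage_pleio(run_dir: Path, cfg: dict, seed: int) -> None:
    t0 = time.time()
    gmap, rils, blups = _load_jl_inputs(run_dir)
    panel = nio.read_founders_tsv(run_dir / "founders.tsv")
    pc = cfg["pleio"]
    traits = list(blups["trait"].unique())
    models = {t: _load_jl_model(run_dir, rils, t, blups) for t in traits}
    ys = {t: _trait_blups(blups, rils, t) for t in traits}
    windows = {}
    for t in traits:
        gpath = run_dir / f"gwas_{t}.tsv"
        assoc = pd.read_csv(gpath, sep="\t") if gpath.exists() else pd.DataFrame()
        windows[t] = pleio_mod.window_effect_vectors(
            assoc, panel, gmap, trait=t, window=pc["window"], step=pc["step"]) \
            if len(assoc) else []
    edges = []
    for i in range(len(traits)):
        for j in range(i + 1, len(traits)):
            a, b = traits[i], traits[j]
            _, e_jl = pleio_mod.jl_pleiotropy(
                rils.genotypes, rils.markers, rils.families, models[a],
                models[b], ys[a], ys[b], alpha=pc["alpha"])
            e_jl = pleio_mod.PleiotropyEdge(a, b, e_jl.percent_shared,
                                            e_jl.signs, e_jl.n_tests)
            _, e_gw = pleio_mod.gwas_pleiotropy(windows[a], windows[b],
                                                alpha=pc["alpha"],
                                                rmip_sum_min=pc["rmip_sum_min"])
            edges.append({"trait_a": a, "trait_b": b, "method": "jl",
                          "percent_shared": e_jl.percent_shared,
                          "signs": e_jl.signs, "n_tests": e_jl.n_tests})
            edges.append({"trait_a": a, "trait_b": b, "method": "gwas",
                          "percent_shared": e_gw.percent_shared,
                          "signs": e_gw.signs, "n_tests": e_gw.n_tests})
    edf = pd.DataFrame(edges)
    edf.to_csv(run_dir / "pleio_edges.tsv", sep="\t", index=False)
    try:
        import networkx as nx
        G = nx.Graph()
        for t in traits:
            G.add_node(t)
        for _, r in edf[edf["percent_shared"] >= pc["display_min"]].iterrows():
            G.add_edge(r["trait_a"], r["trait_b"], weight=r["percent_shared"],
                       sign=r["signs"], method=r["method"])
        nx.write_graphml(G, run_dir / "pleio_graph.graphml")
    except ImportError:
        pass
    _log(run_dir, "pleio", t0, n_edges=len(edf))


def stage_predict(run_dir: Path, cfg: dict, seed: int) -> None:
    t0 = time.time()
    gmap, rils, blups = _load_jl_inputs(run_dir)
    panel = nio.read_founders_tsv(run_dir / "founders.tsv")
    dos = nio.read_dosages_tsv(run_dir / "dosages.tsv", panel.snps)
    with open(run_dir / "architecture.json") as fh:
        arch = json.load(fh)
    reports = []
    parent_dos = pd.DataFrame(panel.alleles.T.astype(float),
                              columns=panel.snps["id"])
    ril_dos = pd.DataFrame(dos.dosages, columns=dos.snps["id"])
    for trait in blups["trait"].unique():
        gpath = run_dir / f"gwas_{trait}.tsv"
        if not gpath.exists():
            continue
        assoc = pd.read_csv(gpath, sep="\t")
        yr = _trait_blups(blups, rils, trait)
        fam_means = blups[blups["trait"] == trait].groupby("family")["blup"].mean()
        parent_obs = np.array([q["effects"] for q in arch[trait]["qtl"]]).sum(axis=0) \
            if arch[trait]["qtl"] else np.zeros(panel.n_parents)
        # alternate parent f carries family f's mean; the common parent, shared
        # by every family, carries the grand mean of family means (key 0)
        fm = fam_means.to_dict()
        fm[0] = float(fam_means.mean())
        parent_fams = [0] + list(range(1, panel.n_parents))
        for cohort, D, obs, fams in (
                ("rils", ril_dos, yr, rils.families),
                ("parents", parent_dos, parent_obs, parent_fams)):
            for with_fam in (False, True):
                pred = predict_mod.additive_prediction(
                    assoc, D, family_means=fm, families=fams,
                    include_family=with_fam)
                reports.append(predict_mod.predictive_ability(
                    pred, obs, trait=trait, cohort=cohort, with_family=with_fam))
    predict_mod.prediction_grid(reports).to_csv(run_dir / "predictions.tsv",
                                                sep="\t", index=False)
    _log(run_dir, "predict", t0, n_reports=len(reports))


def stage_enrich(run_dir: Path, cfg: dict, seed: int) -> None:
    t0 = time.time()
    genes = nio.read_annotation_tsv(run_dir / "annotation.tsv")
    with open(run_dir / "architecture.json") as fh:
        arch = json.load(fh)
    ec = cfg["enrich"]
    rng = np.random.default_rng(_stage_seed(seed, "enrich"))
    results = {}
    for trait in arch:
        gpath = run_dir / f"gwas_{trait}.tsv"
        if not gpath.exists():
            continue
        assoc = pd.read_csv(gpath, sep="\t")
        if len(assoc) == 0:
            continue
        if ec["candidate_mode"] == "near_qtl" and arch[trait]["qtl"]:
            cands = []
            for q in arch[trait]["qtl"]:
                sub = genes[genes["chrom"] == q["chrom"]]
                if len(sub):
                    cands.append(sub.iloc[(sub["cm"] - q["cm"]).abs().argmin()]["gene"])
            cands = list(dict.fromkeys(cands))
        else:
            cands = list(rng.choice(genes["gene"], size=min(ec["n_candidates"],
                                                            len(genes)),
                                    replace=False))
        res = enrich_mod.enrichment_test(
            cands, genes, assoc, n_null=ec["n_null"], radii=tuple(ec["radii"]),
            seed=_stage_seed(seed, f"enrich-{trait}"), n_top=ec["n_top"],
            label=f"{trait}:{ec['candidate_mode']}")
        rmip_sums = {g: enrich_mod.rmip_sum_near_gene(
            assoc, genes[genes["gene"] == g].iloc[0])
            for g in cands}
        results[trait] = {"candidates": cands,
                          "observed": {str(r): res.observed[r] for r in res.radii},
                          "p": {str(r): res.pvalues[r] for r in res.radii},
                          "rmip_sum_within_1cM": rmip_sums}
    with open(run_dir / "enrichment.json", "w") as fh:
        json.dump(results, fh, indent=1)
    _log(run_dir, "enrich", t0)


STAGES = [("simulate", stage_simulate), ("prep", stage_prep),
          ("project", stage_project), ("jl", stage_jl), ("gwas", stage_gwas),
          ("effects", stage_effects), ("pleio", stage_pleio),
          ("predict", stage_predict), ("enrich", stage_enrich)]


def run_pipeline(config: dict | None, out_dir, seed: int = 1,
                 stages=None) -> Path:
    """Run the pipeline (or a subset of stages) into ``out_dir``.

    Writes a ``manifest.json`` recording the merged config, master seed and
    per-stage seeds; identical config + seed reproduce identical outputs.
    """
    cfg = validate_config(config or {})
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    wanted = set(stages) if stages else {name for name, _ in STAGES}
    for name, fn in STAGES:
        if name in wanted:
            fn(run_dir, cfg, seed)
    manifest = {
        "seed": seed,
        "stage_seeds": {name: _stage_seed(seed, name) for name, _ in STAGES},
        "config": cfg,
        "stages_run": [name for name, _ in STAGES if name in wanted],
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return run_dir
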