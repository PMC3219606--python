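"""Shared fixtures: one reduced NAM design (5 families x 100 RILs on a
5-chromosome, 200-marker map) reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import namqtl as nq


@pytest.fixture(scope="session")
def gmap():
    return nq.make_genetic_map(5, 120.0, 1.0e7, 40, seed=11)


@pytest.fixture(scope="session")
def panel(gmap):
    return nq.simulate_founders(gmap, 6, 400, seed=12)


@pytest.fixture(scope="session")
def rils(gmap, panel):
    return nq.simulate_nam(gmap, panel, 100, n_selfing=5, seed=13)


@pytest.fixture(scope="session")
def arch(gmap, panel):
    return nq.simulate_trait_architecture(
        panel, gmap, {"A": {"n_qtl": 3, "category": "ear"}},
        category_scales={"ear": 1.5}, seed=14)


@pytest.fixture(scope="session")
def pheno(rils, arch):
    return nq.simulate_phenotypes(rils, arch, n_env=8, H2_target=0.9, seed=15)


@pytest.fixture(scope="session")
def blups_y(pheno, rils):
    vc = nq.estimate_variance_components(pheno)
    b = nq.compute_blups(pheno, vc)
    y = b.set_index("line")["blup"].loc[rils.lines["line"]].to_numpy()
    return vc, b, y


@pytest.fixture(scope="session")
def jl_threshold(rils, blups_y):
    _, _, y = blups_y
    return nq.jl_permutation_threshold(rils.genotypes, y, rils.families,
                                       n_perm=200, alpha=0.05, seed=16)


@pytest.fixture(scope="session")
def jl_model(rils, blups_y, jl_threshold):
    _, _, y = blups_y
    return nq.jl_stepwise(rils.genotypes, y, rils.families, rils.markers,
                          jl_threshold, trait="A")


@pytest.fixture(scope="session")
def dosages(rils, panel, gmap):
    return nq.project_snps(rils, panel, gmap)


def make_null_y(rng, n):
    return rng.normal(0.0, 1.0, n)
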